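"""Cross-sample comparison: library-size proration, ratio tables,
two-proportion significance, and external target/pathway filtering with
Venn-style set overlaps.

Samples follow the ``REGION_SEX`` naming convention (e.g. ``FC_M`` for male
frontal cortex).  Counts from libraries of different depth are made
comparable by prorating to a reference sample:
``prorated(s, c) = raw(s, c) * library_size(reference) / library_size(s)``.
The comparison table then reports, per fragment class and sample, the share
of the class total, the ratio to the same-sex reference region, and the
male:female ratio per region.

Ratios are rounded half-away-from-zero at display time (two decimals for
ratios, one for percentages), matching how such tables are conventionally
printed; the returned frames keep full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

NCRF_CLASS_ORDER = ["tRF", "rRF", "snRF", "snoRF"]


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed ratio tables,
    unlike banker's rounding)."""
    if value != value:  # NaN
        return value
    quant = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quant, rounding=ROUND_HALF_UP))


def prorate(
    counts: pd.DataFrame,
    library_sizes: dict[str, float],
    reference_sample: str,
) -> pd.DataFrame:
    """Scale per-class counts (classes x samples) to the reference library.

    The reference sample's counts are unchanged; every other sample's counts
    are multiplied by ``library_size(reference) / library_size(sample)``.
    """
    if reference_sample not in counts.columns:
        raise ValueError(f"reference sample {reference_sample!r} not in counts")
    for sample in counts.columns:
        if sample not in library_sizes:
            raise ValueError(f"no library size for sample {sample!r}")
        if library_sizes[sample] <= 0:
            raise ValueError(f"library size for sample {sample!r} must be > 0")
    ref_size = library_sizes[reference_sample]
    scaled = counts.astype(float).copy()
    for sample in counts.columns:
        scaled[sample] = counts[sample] * (ref_size / library_sizes[sample])
    return scaled


def _split_sample(sample: str) -> tuple[str, str]:
    region, _, sex = sample.rpartition("_")
    if not region or sex not in {"M", "F"}:
        raise ValueError(
            f"sample {sample!r} does not follow the REGION_SEX convention"
        )
    return region, sex


def ratio_table(
    prorated: pd.DataFrame, reference_region: str = "FC"
) -> pd.DataFrame:
    """Comparison table from prorated per-class counts (classes x samples).

    Returns a frame indexed by (ncrf_class, metric) with the sample columns,
    where metric is one of ``reads``, ``pct_of_total`` (percent of the
    per-sample class total), ``ratio_to_reference`` (same-sex reference
    region taken as 1), ``ratio_m_to_f`` (per region, reported in the male
    column), plus a ("Total", "reads") row.  Values are unrounded; see
    :func:`format_ratio_table` for printed precision.
    """
    samples = list(prorated.columns)
    meta = {s: _split_sample(s) for s in samples}
    totals = prorated.sum(axis=0)

    rows: dict[tuple[str, str], dict[str, float]] = {}
    for cls in prorated.index:
        reads = prorated.loc[cls]
        rows[(cls, "reads")] = dict(reads)
        rows[(cls, "pct_of_total")] = {
            s: 100.0 * reads[s] / totals[s] if totals[s] else float("nan")
            for s in samples
        }
        ratio_ref: dict[str, float] = {}
        for s in samples:
            region, sex = meta[s]
            ref_sample = f"{reference_region}_{sex}"
            if ref_sample not in prorated.columns:
                ratio_ref[s] = float("nan")
            else:
                denom = reads[ref_sample]
                ratio_ref[s] = reads[s] / denom if denom else float("nan")
        rows[(cls, "ratio_to_reference")] = ratio_ref
        mf: dict[str, float] = {s: float("nan") for s in samples}
        for s in samples:
            region, sex = meta[s]
            if sex != "M":
                continue
            female = f"{region}_F"
            if female in prorated.columns and reads[female]:
                mf[s] = reads[s] / reads[female]
        rows[(cls, "ratio_m_to_f")] = mf
    rows[("Total", "reads")] = dict(totals)

    table = pd.DataFrame.from_dict(rows, orient="index")[samples]
    table.index = pd.MultiIndex.from_tuples(table.index,
                                            names=["ncrf_class", "metric"])
    return table


def format_ratio_table(table: pd.DataFrame) -> pd.DataFrame:
    """Printed-precision view: ratios to 2 decimals, percentages to 1
    (both half-away-from-zero); reads to 2 decimals."""
    out = table.copy()
    for (cls, metric) in out.index:
        nd = {"reads": 2, "pct_of_total": 1}.get(metric, 2)
        out.loc[(cls, metric)] = [
            round_half_away(v, nd) for v in out.loc[(cls, metric)]
        ]
    return out


def significance_flag(
    count_a: int, total_a: int, count_b: int, total_b: int, alpha: float = 0.05
) -> tuple[float, bool]:
    """Two-sided two-proportion z-test with continuity correction.

    Operates on raw (un-prorated) counts.  Equivalent to the Yates-corrected
    chi-square test on the 2x2 table.  Returns (p_value, p < alpha).
    """
    for count, total in ((count_a, total_a), (count_b, total_b)):
        if total <= 0:
            raise ValueError("totals must be positive")
        if not 0 <= count <= total:
            raise ValueError(f"count {count} outside [0, total={total}]")
    p1, p2 = count_a / total_a, count_b / total_b
    pooled = (count_a + count_b) / (total_a + total_b)
    se = np.sqrt(pooled * (1 - pooled) * (1 / total_a + 1 / total_b))
    if se == 0:
        return 1.0, False
    cc = 0.5 * (1 / total_a + 1 / total_b)
    z = max(abs(p1 - p2) - cc, 0.0) / se
    p_value = 2.0 * stats.norm.sf(z)
    return float(p_value), bool(p_value < alpha)


@dataclass(frozen=True)
class GeneSet:
    label: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


def _as_rows(table) -> Iterable[tuple]:
    if isinstance(table, pd.DataFrame):
        return list(table.itertuples(index=False, name=None))
    return list(table)


def filter_predictions(
    table, min_score: float = 80.0, label: str = "targets"
) -> GeneSet:
    """Keep predicted target genes with score strictly greater than
    ``min_score`` (scores live on the 50-100 prediction scale); gene symbols
    are upper-cased and de-duplicated."""
    kept: set[str] = set()
    for row_no, row in enumerate(_as_rows(table), 1):
        gene, score = row[0], row[1]
        try:
            score = float(score)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {row_no}: non-numeric score {score!r}") from exc
        if not 50.0 <= score <= 100.0:
            raise ValueError(f"row {row_no}: score {score} outside [50, 100]")
        if score > min_score:
            kept.add(str(gene).upper())
    return GeneSet(label=label, genes=frozenset(kept))


def filter_pathways(table, max_q: float = 0.05, label: str = "pathways") -> GeneSet:
    """Keep pathway terms with adjusted (Benjamini-Hochberg) p strictly less
    than ``max_q``."""
    kept: set[str] = set()
    for row_no, row in enumerate(_as_rows(table), 1):
        term, q = row[0], row[1]
        try:
            q = float(q)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {row_no}: non-numeric q-value {q!r}") from exc
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"row {row_no}: q-value {q} outside [0, 1]")
        if q < max_q:
            kept.add(str(term).upper())
    return GeneSet(label=label, genes=frozenset(kept))


def set_overlap(sets: Sequence[GeneSet]) -> dict:
    """Exclusive Venn partition of 2 or 3 gene sets.

    Returns ``{"labels": [...], "regions": {pattern: count}, "totals":
    {label: size}}`` where ``pattern`` is a membership string over the input
    order ("110" = in the first two sets only).  Region counts over the
    patterns containing a set sum to that set's size.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError(f"set_overlap supports 2 or 3 sets, got {len(sets)}")
    universe = set().union(*(s.genes for s in sets))
    regions: dict[str, int] = {}
    for gene in universe:
        pattern = "".join("1" if gene in s.genes else "0" for s in sets)
        regions[pattern] = regions.get(pattern, 0) + 1
    n = len(sets)
    all_patterns = [
        format(mask, f"0{n}b") for mask in range(1, 2**n)
    ]
    return {
        "labels": [s.label for s in sets],
        "regions": {p: regions.get(p, 0) for p in all_patterns},
        "totals": {s.label: len(s.genes) for s in sets},
    }


def load_example_prorated_counts() -> pd.DataFrame:
    """Worked-example input: prorated fragment read counts (four fragment
    classes x six rat brain samples — frontal cortex, cerebellum and
    hippocampus of males and females, prorated to the male frontal cortex
    library).  Ships with the package so the comparison arithmetic has a
    reproducible demonstration."""
    with resources.files("ncrf.data").joinpath(
        "rat_brain_prorated_counts.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return df


def write_venn_json(partition: dict, path: str | Path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(partition, fh, indent=2)
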