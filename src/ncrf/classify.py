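"""Per-sample classification summaries: class counts and fractions, insert
size distributions, and GC content (one summary per pooled sample).

Conventions pinned here so results are testable:

* fractions are computed over mapped reads only;
* size quartiles use linear interpolation between order statistics, and
  boxplot outliers are values beyond 1.5 IQR outside the quartiles;
* GC content is pooled — total G+C over all insert bases in the class
  divided by the total base count (N bases count in the denominator only) —
  not a mean of per-read fractions.

Insert sequences are taken as the aligned reference slice, which equals the
read insert up to the counted mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import AlignmentHit
from .reference import NcRNACatalog


@dataclass(frozen=True)
class SizeStats:
    n: int
    min: float
    q1: float
    median: float
    q3: float
    max: float
    outliers: tuple[int, ...] = ()

    @property
    def empty(self) -> bool:
        return self.n == 0


_EMPTY_SIZE = SizeStats(n=0, min=float("nan"), q1=float("nan"),
                        median=float("nan"), q3=float("nan"), max=float("nan"))


@dataclass
class SampleSummary:
    sample_id: str
    class_counts: dict[str, int] = field(default_factory=dict)
    class_fractions: dict[str, float] = field(default_factory=dict)
    size_stats: dict[str, SizeStats] = field(default_factory=dict)
    gc_content: dict[str, float] = field(default_factory=dict)
    total_mapped: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in sorted(self.class_counts):
            ss = self.size_stats.get(cls, _EMPTY_SIZE)
            rows.append(
                {
                    "sample_id": self.sample_id,
                    "ncrna_class": cls,
                    "count": self.class_counts[cls],
                    "fraction": round(self.class_fractions.get(cls, float("nan")), 4),
                    "size_min": ss.min,
                    "size_q1": ss.q1,
                    "size_median": ss.median,
                    "size_q3": ss.q3,
                    "size_max": ss.max,
                    "gc_content": self.gc_content.get(cls, float("nan")),
                }
            )
        return pd.DataFrame(rows)


def size_distribution(lengths: list[int]) -> SizeStats:
    """Boxplot-style five-number summary of insert lengths.

    Quartiles by linear interpolation; outliers are observations outside
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR] (the whisker convention).
    """
    if not lengths:
        return _EMPTY_SIZE
    arr = np.asarray(lengths, dtype=float)
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = tuple(int(v) for v in sorted(arr[(arr < lo) | (arr > hi)]))
    return SizeStats(
        n=len(lengths),
        min=float(arr.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(arr.max()),
        outliers=outliers,
    )


def gc_content(hits: list[AlignmentHit], catalog: NcRNACatalog) -> float:
    """Pooled GC fraction over the insert sequences of the given hits."""
    gc = 0
    total = 0
    for hit in hits:
        seq = catalog[hit.ncrna_id].sequence[hit.offset : hit.offset + hit.insert_length]
        gc += seq.count("G") + seq.count("C")
        total += len(seq)
    return gc / total if total else float("nan")


def classify_hits(
    hits: list[AlignmentHit], catalog: NcRNACatalog, sample_id: str
) -> SampleSummary:
    """Summarize one (pooled) sample: each hit contributes to exactly the
    class of its reference record."""
    by_class: dict[str, list[AlignmentHit]] = {}
    for hit in hits:
        if hit.ncrna_id not in catalog:
            raise KeyError(f"hit references unknown ncRNA id {hit.ncrna_id!r}")
        by_class.setdefault(catalog[hit.ncrna_id].ncrna_class, []).append(hit)

    total = len(hits)
    summary = SampleSummary(sample_id=sample_id, total_mapped=total)
    for cls, cls_hits in sorted(by_class.items()):
        summary.class_counts[cls] = len(cls_hits)
        summary.class_fractions[cls] = len(cls_hits) / total if total else float("nan")
        summary.size_stats[cls] = size_distribution(
            [h.insert_length for h in cls_hits]
        )
        summary.gc_content[cls] = gc_content(cls_hits, catalog)
    return summary


def pool_samples(hit_lists: list[list[AlignmentHit]]) -> list[AlignmentHit]:
    """Pool biological replicates into one sample before summarization."""
    pooled: list[AlignmentHit] = []
    for hits in hit_lists:
        pooled.extend(hits)
    return pooled


def write_summary(summary: SampleSummary, path: str | Path) -> None:
    summary.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")
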