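"""End-anchored ncRNA fragment (ncRF) calling and fragment-level tables.

A fragment call is an aligned read that (a) is short enough to be a
processed fragment rather than a near-full-length precursor (insert <= 27
nt; >= 29 nt reads are precursor signal and the 28-nt band is excluded from
both), (b) maps to a fragment-bearing precursor class (tRNA, rRNA, snRNA,
snoRNA, repeat, lincRNA, antisense — mature miRNAs are not processed into
fragments), and (c) sits on a precursor with adequate read support
(>= 5 reads of any length by default).

End typing: a read starting at the reference 5' end (offset <= tolerance)
is a 5' fragment; one ending at the 3' end (offset + length >= reference
length - tolerance) is a 3' fragment; reads touching neither end are kept
as ``internal`` — they still count in positional-bin profiles but are
excluded from 5'/3' ratio tables.  With tolerance 0 a read can only touch
both ends of a reference no longer than itself, which fragment-bearing
references never are; if it happens, 5' wins.

Fragment classes are named after their precursor: tRF, rRF, snRF, snoRF,
repeatRF, otherRF.  tRF families aggregate at two levels — amino acid
("tRF-Gly") and isoacceptor ("tRF-GlyGCC").  tRFs are further subtyped by
length: <= 22 nt reads are tRF-5/tRF-3, 23-27 nt reads are halves
(tRH-5/tRH-3); the cutoff is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import AlignmentHit
from .reference import NcRNACatalog, fragment_bearing_classes

NCRF_CLASS_BY_PRECURSOR = {
    "tRNA": "tRF",
    "rRNA": "rRF",
    "snRNA": "snRF",
    "snoRNA": "snoRF",
    "repeat": "repeatRF",
    "lincRNA": "otherRF",
    "antisense": "otherRF",
}

DEFAULT_MAX_LEN = 27
PRECURSOR_MIN_LEN = 29
DEFAULT_MIN_SUPPORT = 5
TRF_HALF_CUTOFF = 23  # insert >= this is a tRNA half (tRH)


@dataclass(frozen=True)
class FragmentCall:
    read_id: str
    ncrna_id: str
    ncrf_class: str
    end_type: str  # five_prime | three_prime | internal
    insert_length: int
    family_label: str
    family: str = ""
    subtype: str = ""
    offset: int = 0


@dataclass(frozen=True)
class BinDistribution:
    ncrna_class: str
    bin_counts: tuple[int, ...]

    @property
    def total(self) -> int:
        return sum(self.bin_counts)

    @property
    def empty(self) -> bool:
        return self.total == 0

    @property
    def bin_fractions(self) -> tuple[float, ...]:
        t = self.total
        if t == 0:
            return tuple(0.0 for _ in self.bin_counts)
        return tuple(c / t for c in self.bin_counts)


def assign_end_type(
    offset: int, insert_length: int, reference_length: int, tolerance: int = 0
) -> str:
    if offset <= tolerance:
        return "five_prime"
    if offset + insert_length >= reference_length - tolerance:
        return "three_prime"
    return "internal"


def _family_label(
    ncrf_class: str, family: str, subtype: str, end_type: str, ncrna_id: str
) -> str:
    if ncrf_class == "tRF":
        return f"tRF-{family}{subtype}"
    base = family or ncrna_id
    if ncrf_class == "snoRF":
        suffix = {"five_prime": "-5", "three_prime": "-3"}.get(end_type, "")
        return f"snoRF{suffix}:{base}"
    return f"{ncrf_class}:{base}"


def call_fragments(
    hits: list[AlignmentHit],
    catalog: NcRNACatalog,
    min_support: int = DEFAULT_MIN_SUPPORT,
    max_len: int = DEFAULT_MAX_LEN,
    end_tolerance: int = 0,
) -> list[FragmentCall]:
    """Call one fragment per qualifying hit (see module docstring).

    ``min_support`` counts all reads on the precursor, fragments and
    precursor-length reads alike.
    """
    if min_support < 1:
        raise ValueError(f"min_support must be >= 1, got {min_support}")
    support: dict[str, int] = {}
    for hit in hits:
        support[hit.ncrna_id] = support.get(hit.ncrna_id, 0) + 1

    bearing = fragment_bearing_classes()
    calls: list[FragmentCall] = []
    for hit in hits:
        if hit.insert_length > max_len:
            continue
        rec = catalog[hit.ncrna_id]
        if rec.ncrna_class not in bearing:
            continue
        if support[hit.ncrna_id] < min_support:
            continue
        ncrf_class = NCRF_CLASS_BY_PRECURSOR[rec.ncrna_class]
        end_type = assign_end_type(
            hit.offset, hit.insert_length, len(rec), end_tolerance
        )
        calls.append(
            FragmentCall(
                read_id=hit.read_id,
                ncrna_id=hit.ncrna_id,
                ncrf_class=ncrf_class,
                end_type=end_type,
                insert_length=hit.insert_length,
                family_label=_family_label(
                    ncrf_class, rec.family, rec.subtype, end_type, rec.id
                ),
                family=rec.family,
                subtype=rec.subtype,
                offset=hit.offset,
            )
        )
    return calls


def positional_bins(
    hits: list[AlignmentHit],
    catalog: NcRNACatalog,
    ncrna_class: str,
    n_bins: int = 10,
    max_len: int = DEFAULT_MAX_LEN,
) -> BinDistribution:
    """Fragment-read start-position profile over the precursor length.

    Each fragment-length read (insert <= ``max_len``) on a reference of the
    requested class is assigned to exactly one bin by its 5'-most base:
    ``bin = floor(n_bins * offset / reference_length)``; fractions are the
    bin counts over the total, so they always sum to 1 when any read counts.
    """
    counts = [0] * n_bins
    for hit in hits:
        rec = catalog[hit.ncrna_id]
        if rec.ncrna_class != ncrna_class or hit.insert_length > max_len:
            continue
        if len(rec) < n_bins:
            raise ValueError(
                f"reference {rec.id!r} shorter than {n_bins} bins"
            )
        b = min(n_bins * hit.offset // len(rec), n_bins - 1)
        counts[b] += 1
    return BinDistribution(ncrna_class=ncrna_class, bin_counts=tuple(counts))


def family_table(
    calls: list[FragmentCall], level: str = "isoacceptor"
) -> pd.DataFrame:
    """Counts and within-class percentages per fragment family.

    ``level`` affects only tRFs: ``isoacceptor`` keeps anticodon resolution
    ("tRF-GlyGCC"); ``amino_acid`` pools anticodons ("tRF-Gly").
    """
    if level not in {"isoacceptor", "amino_acid"}:
        raise ValueError(f"unknown level {level!r}")
    rows = []
    for call in calls:
        label = call.family_label
        if level == "amino_acid" and call.ncrf_class == "tRF":
            label = f"tRF-{call.family}"
        rows.append((call.ncrf_class, label))
    if not rows:
        return pd.DataFrame(columns=["ncrf_class", "family_label", "count", "percent"])
    df = pd.DataFrame(rows, columns=["ncrf_class", "family_label"])
    table = (
        df.groupby(["ncrf_class", "family_label"]).size().rename("count").reset_index()
    )
    table["percent"] = (
        100.0 * table["count"] / table.groupby("ncrf_class")["count"].transform("sum")
    )
    return table.sort_values(
        ["ncrf_class", "count"], ascending=[True, False]
    ).reset_index(drop=True)


def size_fraction_table(
    calls: list[FragmentCall],
    ncrf_class: str,
    min_len: int = 15,
    max_len: int = DEFAULT_MAX_LEN,
    omit_length: int | None = None,
) -> pd.DataFrame:
    """Read counts per insert length for one fragment class.

    ``omit_length`` drops one length from the table (used to look past a
    dominant modal fraction, e.g. the 18-nt tRF peak).
    """
    lengths = [c.insert_length for c in calls if c.ncrf_class == ncrf_class]
    counter = {length: 0 for length in range(min_len, max_len + 1)}
    for length in lengths:
        if min_len <= length <= max_len:
            counter[length] += 1
    if omit_length is not None:
        counter.pop(omit_length, None)
    return pd.DataFrame(
        {"insert_length": list(counter), "count": list(counter.values())}
    )


def end_ratio(
    calls: list[FragmentCall], ncrf_class: str, orientation: str | None = None
) -> tuple[int, int, float]:
    """(5' count, 3' count, ratio) for one fragment class.

    Orientation defaults to the field convention: 3':5' for snoRF/snRF/rRF
    (3'-dominant classes), 5':3' for tRF.  The ratio is NaN when its
    denominator is zero.  Internal calls are excluded.
    """
    five = sum(
        1 for c in calls if c.ncrf_class == ncrf_class and c.end_type == "five_prime"
    )
    three = sum(
        1 for c in calls if c.ncrf_class == ncrf_class and c.end_type == "three_prime"
    )
    if orientation is None:
        orientation = "five_to_three" if ncrf_class == "tRF" else "three_to_five"
    if orientation == "three_to_five":
        ratio = three / five if five else float("nan")
    elif orientation == "five_to_three":
        ratio = five / three if three else float("nan")
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return five, three, ratio


def trf_subtype(call: FragmentCall, half_cutoff: int = TRF_HALF_CUTOFF) -> str:
    """Length/end nomenclature for tRFs: tRF-5/tRF-3 below the half cutoff,
    tRH-5/tRH-3 at or above it; internal fragments are 'tRF-i'."""
    if call.ncrf_class != "tRF":
        raise ValueError("trf_subtype applies to tRF calls only")
    if call.end_type == "internal":
        return "tRF-i"
    end = "5" if call.end_type == "five_prime" else "3"
    stem = "tRH" if call.insert_length >= half_cutoff else "tRF"
    return f"{stem}-{end}"


def calls_to_frame(calls: list[FragmentCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": c.read_id,
                "ncrna_id": c.ncrna_id,
                "ncrf_class": c.ncrf_class,
                "end_type": c.end_type,
                "insert_length": c.insert_length,
                "family_label": c.family_label,
                "offset": c.offset,
            }
            for c in calls
        ],
        columns=[
            "read_id",
            "ncrna_id",
            "ncrf_class",
            "end_type",
            "insert_length",
            "family_label",
            "offset",
        ],
    )
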