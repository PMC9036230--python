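"""Fragment enrichment relative to precursor abundance.

For each precursor (or family) the enrichment ratio is the number of
fragment-length reads (<= 27 nt, i.e. the fragment calls) divided by the
number of precursor-length reads (>= 29 nt); 28-nt reads count in neither.
A ratio of 1 means one fragment per precursor read.  Family-level ratios
are ratios of summed counts, not means of per-precursor ratios, so
low-count precursors cannot dominate.

Because a raw ratio near 1 is uninformative, status labels apply a
symmetric band: enriched when ratio > 1 + delta, underrepresented when
ratio < 1 - delta (default delta 0.25), balanced in between, undefined
when there are no precursor reads.  Optionally a two-proportion test
(see :mod:`ncrf.compare`) must also reject equality before an
enriched/underrepresented label is assigned.
"""

from __future__ import annotations

import pandas as pd

from .align import AlignmentHit
from .fragments import (
    NCRF_CLASS_BY_PRECURSOR,
    PRECURSOR_MIN_LEN,
    FragmentCall,
    _family_label,
)
from .reference import NcRNACatalog

DEFAULT_DELTA = 0.25


def enrichment_ratio(ncrf_reads: int, precursor_reads: int) -> float:
    """Fragment:precursor read ratio; NaN when there is no precursor signal."""
    if ncrf_reads < 0 or precursor_reads < 0:
        raise ValueError("read counts must be non-negative")
    if precursor_reads == 0:
        return float("nan")
    return ncrf_reads / precursor_reads


def status_of(ratio: float, delta: float = DEFAULT_DELTA) -> str:
    if ratio != ratio:  # NaN
        return "undefined"
    if ratio > 1 + delta:
        return "enriched"
    if ratio < 1 - delta:
        return "underrepresented"
    return "balanced"


def enrichment_profile(
    hits: list[AlignmentHit],
    calls: list[FragmentCall],
    catalog: NcRNACatalog,
    level: str = "family",
    delta: float = DEFAULT_DELTA,
    ncrf_class: str | None = None,
) -> pd.DataFrame:
    """Per-precursor or per-family enrichment table.

    ``hits`` and ``calls`` must come from the same sample; precursor reads
    are re-counted here from the raw hits (insert >= 29 nt), fragments from
    the calls.  ``level`` is ``ncrna`` (one row per precursor id) or
    ``family`` (counts summed over the family label, for tRFs the
    isoacceptor, e.g. "tRF-GlyGCC").  ``ncrf_class`` restricts rows to one
    fragment class.
    """
    if level not in {"ncrna", "family"}:
        raise ValueError(f"unknown level {level!r}")

    def fam_key(rec_id: str) -> str:
        rec = catalog[rec_id]
        cls = NCRF_CLASS_BY_PRECURSOR.get(rec.ncrna_class)
        if cls is None:
            return ""
        # family key ignores the end so 5'/3' fragments pool with their precursor
        return _family_label(cls, rec.family, rec.subtype, "", rec.id)

    frag_counts: dict[str, int] = {}
    cls_of: dict[str, str] = {}
    for call in calls:
        if ncrf_class is not None and call.ncrf_class != ncrf_class:
            continue
        key = call.ncrna_id if level == "ncrna" else fam_key(call.ncrna_id)
        frag_counts[key] = frag_counts.get(key, 0) + 1
        cls_of[key] = call.ncrf_class

    prec_counts: dict[str, int] = {}
    for hit in hits:
        if hit.insert_length < PRECURSOR_MIN_LEN:
            continue
        rec = catalog[hit.ncrna_id]
        cls = NCRF_CLASS_BY_PRECURSOR.get(rec.ncrna_class)
        if cls is None or (ncrf_class is not None and cls != ncrf_class):
            continue
        key = hit.ncrna_id if level == "ncrna" else fam_key(hit.ncrna_id)
        prec_counts[key] = prec_counts.get(key, 0) + 1
        cls_of.setdefault(key, cls)

    rows = []
    for key in sorted(set(frag_counts) | set(prec_counts)):
        nf = frag_counts.get(key, 0)
        np_ = prec_counts.get(key, 0)
        ratio = enrichment_ratio(nf, np_)
        rows.append(
            {
                "label": key,
                "ncrf_class": cls_of.get(key, ""),
                "ncrf_reads": nf,
                "precursor_reads": np_,
                "ratio": ratio,
                "status": status_of(ratio, delta),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["label", "ncrf_class", "ncrf_reads", "precursor_reads",
                 "ratio", "status"],
    )
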