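"""Adapter trimming and ungapped mismatch-bounded mapping to the catalog.

The read layout is a 7-nt adapter, then an insert of 15-29 nt, then
read-through padding that continues the adapter sequence from its first
base.  Trimming removes the leading adapter (tolerating one mismatch) and
the longest trailing run that exactly matches that padding pattern.

Mapping is ungapped and end-to-end with at most ``max_mismatch``
substitutions (default 2), reporting one best-stratum hit per read: among
all placements, the minimum achievable mismatch count wins, and equal-count
ties break deterministically by catalog record order, then smallest offset.
This mirrors a ``bowtie -v 2 --best`` policy except that bowtie's tie-break
among equally good hits is pseudo-random; the deterministic rule here is a
deliberate divergence, which makes catalog ordering significant for
multi-copy sequences.

Every placement of every read is scored (vectorized mismatch counting per
reference), so the reported stratum is exact by construction for any insert
length; reference ``N`` bases never match any read base, and ``N`` in the
read never matches anything.  Only the sense strand is scanned by default
(the catalog holds sense ncRNA sequences; antisense transcripts are their
own reference class); ``both_strands`` adds the reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam
from Bio import SeqIO
from numpy.lib.stride_tricks import sliding_window_view

from .reference import NcRNACatalog

MIN_INSERT = 15
MAX_INSERT = 29


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TrimRejection:
    read_id: str
    reason: str


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    ncrna_id: str
    offset: int  # 0-based start on the reference
    insert_length: int
    mismatches: int
    strand: str = "+"


def _pad_pattern(adapter: str, length: int) -> str:
    reps = (length // len(adapter)) + 1
    return (adapter * reps)[:length]


def trim_adapter(
    read: ReadRecord, adapter: str, min_insert: int = MIN_INSERT
) -> ReadRecord | TrimRejection:
    """Strip the leading adapter and trailing read-through padding.

    The trailing trim takes the smallest insert end position >= ``min_insert``
    whose suffix exactly matches the adapter-continuation pattern (i.e. the
    longest removable pad); an insert that would end up shorter than
    ``min_insert`` rejects the read.
    """
    if len(adapter) != 7:
        raise ValueError("adapter must be 7 nt")
    seq = read.sequence.upper()
    if len(seq) < len(adapter):
        return TrimRejection(read.read_id, "too_short")
    lead_mm = sum(a != b for a, b in zip(seq[: len(adapter)], adapter))
    if lead_mm > 1:
        return TrimRejection(read.read_id, "no_adapter")
    remainder = seq[len(adapter):]
    if len(remainder) < min_insert:
        return TrimRejection(read.read_id, "too_short")
    insert = remainder
    for j in range(min_insert, len(remainder) + 1):
        if remainder[j:] == _pad_pattern(adapter, len(remainder) - j):
            insert = remainder[:j]
            break
    return ReadRecord(read.read_id, insert)


def _encode_read(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    arr[arr == ord("N")] = 255  # read N matches nothing, including reference N
    return arr


class CatalogMapper:
    """Reusable exhaustive mapper over one catalog.

    Precomputes encoded reference arrays; ``map_read`` scans every placement
    of the insert on every reference (optionally both strands) and applies
    the best-stratum, record-order/offset tie-break.  ``map_reads`` adds an
    insert-sequence memo, which collapses the heavy repetition typical of
    small-RNA libraries (many reads share the same insert).
    """

    def __init__(self, catalog: NcRNACatalog, both_strands: bool = False):
        self.catalog = catalog
        self.both_strands = both_strands
        self._refs: list[tuple[str, np.ndarray, str]] = []
        for rec in catalog:
            fwd = np.frombuffer(rec.sequence.encode(), dtype=np.uint8)
            self._refs.append((rec.id, fwd, "+"))
            if both_strands:
                rc = _revcomp(rec.sequence)
                self._refs.append(
                    (rec.id, np.frombuffer(rc.encode(), dtype=np.uint8), "-")
                )

    def map_read(
        self, insert: ReadRecord, max_mismatch: int = 2
    ) -> AlignmentHit | None:
        seq = insert.sequence.upper()
        length = len(seq)
        if not MIN_INSERT <= length <= MAX_INSERT:
            return None
        if seq.count("N") * 2 > length:
            return None  # mostly-N insert is unmappable
        placement = self._best_placement(seq, max_mismatch)
        if placement is None:
            return None
        ncrna_id, offset, mismatches, strand = placement
        return AlignmentHit(
            read_id=insert.read_id,
            ncrna_id=ncrna_id,
            offset=offset,
            insert_length=length,
            mismatches=mismatches,
            strand=strand,
        )

    def _best_placement(
        self, seq: str, max_mismatch: int
    ) -> tuple[str, int, int, str] | None:
        query = _encode_read(seq)
        length = query.size
        best: tuple[str, int, int, str] | None = None
        best_mm = max_mismatch + 1
        for ref_id, ref, strand in self._refs:
            if ref.size < length:
                continue
            windows = sliding_window_view(ref, length)
            mm = (windows != query).sum(axis=1)
            idx = int(np.argmin(mm))
            rec_best = int(mm[idx])
            if rec_best < best_mm:
                strand_offset = idx
                if strand == "-":
                    # report coordinates on the forward reference
                    strand_offset = ref.size - length - idx
                best = (ref_id, strand_offset, rec_best, strand)
                best_mm = rec_best
                if best_mm == 0:
                    break
        return best if best_mm <= max_mismatch else None

    def map_reads(
        self, inserts: list[ReadRecord], max_mismatch: int = 2
    ) -> list[AlignmentHit]:
        """Map a batch with memoization; preserves input order, drops no-hits."""
        memo: dict[str, tuple[str, int, int, str] | None] = {}
        hits: list[AlignmentHit] = []
        for insert in inserts:
            seq = insert.sequence.upper()
            length = len(seq)
            if not MIN_INSERT <= length <= MAX_INSERT:
                continue
            if seq.count("N") * 2 > length:
                continue
            if seq not in memo:
                memo[seq] = self._best_placement(seq, max_mismatch)
            placement = memo[seq]
            if placement is None:
                continue
            ncrna_id, offset, mismatches, strand = placement
            hits.append(
                AlignmentHit(insert.read_id, ncrna_id, offset, length,
                             mismatches, strand)
            )
        return hits


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def map_read(
    insert: ReadRecord,
    catalog: NcRNACatalog,
    max_mismatch: int = 2,
    both_strands: bool = False,
) -> AlignmentHit | None:
    """One-shot convenience wrapper around :class:`CatalogMapper`."""
    return CatalogMapper(catalog, both_strands).map_read(insert, max_mismatch)


def read_fastq(path: str | Path) -> list[ReadRecord]:
    return [
        ReadRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def trim_and_map(
    reads: list[ReadRecord],
    catalog: NcRNACatalog,
    adapter: str,
    max_mismatch: int = 2,
    both_strands: bool = False,
) -> tuple[list[AlignmentHit], dict[str, int]]:
    """Full align stage: trim every read, map the survivors.

    Returns the hits plus a tally of rejected/unmapped reads by reason.
    """
    stats = {"input": len(reads), "too_short": 0, "no_adapter": 0, "unmapped": 0}
    inserts: list[ReadRecord] = []
    for read in reads:
        result = trim_adapter(read, adapter)
        if isinstance(result, TrimRejection):
            stats[result.reason] = stats.get(result.reason, 0) + 1
        else:
            inserts.append(result)
    hits = CatalogMapper(catalog, both_strands).map_reads(inserts, max_mismatch)
    stats["unmapped"] = len(inserts) - len(hits)
    stats["mapped"] = len(hits)
    return hits, stats


def _sam_header(catalog: NcRNACatalog) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": rec.id, "LN": len(rec)} for rec in catalog],
        }
    )


def write_sam(
    hits: list[AlignmentHit],
    catalog: NcRNACatalog,
    sam_path: str | Path,
    sequences: dict[str, str] | None = None,
) -> None:
    """Write hits as a text SAM; the NM tag carries the mismatch count.

    When no read sequence is supplied for a hit, the aligned reference slice
    stands in (exact up to the counted mismatches).
    """
    header = _sam_header(catalog)
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        for hit in hits:
            a = pysam.AlignedSegment(header)
            a.query_name = hit.read_id
            ref = catalog[hit.ncrna_id]
            seq = (sequences or {}).get(
                hit.read_id,
                ref.sequence[hit.offset : hit.offset + hit.insert_length],
            )
            a.query_sequence = seq
            a.flag = 16 if hit.strand == "-" else 0
            a.reference_id = header.get_tid(hit.ncrna_id)
            a.reference_start = hit.offset  # pysam is 0-based; SAM text is 1-based
            a.mapping_quality = 255
            a.cigarstring = f"{hit.insert_length}M"
            a.set_tag("NM", hit.mismatches)
            out.write(a)


def read_sam(sam_path: str | Path, catalog: NcRNACatalog) -> list[AlignmentHit]:
    """Ingest primary mapped SAM records as hits (POS 1-based -> offset
    0-based via pysam); skips unmapped and secondary/supplementary records."""
    hits: list[AlignmentHit] = []
    skipped = {"unmapped": 0, "secondary": 0}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for name in sam.references:
            if name not in catalog:
                raise ValueError(f"SAM reference {name!r} absent from catalog")
        for rec in sam:
            if rec.is_unmapped:
                skipped["unmapped"] += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                skipped["secondary"] += 1
                continue
            length = rec.query_alignment_length or len(rec.query_sequence or "")
            hits.append(
                AlignmentHit(
                    read_id=rec.query_name,
                    ncrna_id=rec.reference_name,
                    offset=rec.reference_start,
                    insert_length=length,
                    mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                    strand="-" if rec.is_reverse else "+",
                )
            )
    if any(skipped.values()):
        import logging

        logging.getLogger(__name__).info(
            "read_sam: skipped %d unmapped, %d secondary/supplementary records",
            skipped["unmapped"],
            skipped["secondary"],
        )
    return hits
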