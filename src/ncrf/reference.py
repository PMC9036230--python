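"""ncRNA reference catalog: records, validation, FASTA I/O.

A catalog is the set of non-coding RNA sequences that small-RNA reads are
mapped against: mature miRNAs, tRNAs, rRNAs, snoRNAs, snRNAs, lincRNAs,
repeat-associated RNAs and so on.  Class and family metadata travel in the
FASTA description line as space-separated ``key=value`` pairs after the id
(e.g. ``trna-Gly-GCC-1 class=tRNA family=Gly subtype=GCC``); a BED/TSV
side-file can override the headers when both are given.

Coordinates everywhere in this package are 0-based half-open; conversion to
1-based happens only at the SAM boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Class vocabulary shared by the whole pipeline (the catalog may carry any
#: of these; unknown labels are routed to "other").
NCRNA_CLASSES = frozenset(
    {
        "miRNA",
        "tRNA",
        "rRNA",
        "snoRNA",
        "snRNA",
        "lincRNA",
        "antisense",
        "miscRNA",
        "piRNA",
        "scaRNA",
        "ribozyme",
        "Mt_tRNA",
        "Mt_rRNA",
        "processed_transcript",
        "repeat",
        "other",
    }
)

_VALID_BASES = frozenset("ACGTN")


class CatalogError(ValueError):
    """Malformed or inconsistent reference catalog."""


@dataclass(frozen=True)
class NcRNARecord:
    """One reference ncRNA with its class/family metadata."""

    id: str
    ncrna_class: str
    family: str
    subtype: str
    sequence: str

    def __post_init__(self) -> None:
        if self.ncrna_class not in NCRNA_CLASSES:
            raise CatalogError(
                f"record {self.id!r}: unknown ncRNA class {self.ncrna_class!r}"
            )
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise CatalogError(
                f"record {self.id!r}: invalid characters {sorted(bad)} in sequence"
            )
        if len(self.sequence) < 15:
            raise CatalogError(
                f"record {self.id!r}: sequence shorter than 15 nt ({len(self.sequence)})"
            )
        if self.ncrna_class == "tRNA":
            if not self.family:
                raise CatalogError(f"tRNA record {self.id!r} lacks a family (amino acid)")
            if len(self.subtype) != 3:
                raise CatalogError(
                    f"tRNA record {self.id!r}: anticodon subtype must be 3 nt, "
                    f"got {self.subtype!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class NcRNACatalog:
    """Ordered collection of reference records.

    Record order is the file order and is significant downstream: the mapper
    breaks equal-mismatch ties by record order, then offset.
    """

    records: list[NcRNARecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dups: list[str] = []
        for rec in self.records:
            if rec.id in seen:
                dups.append(rec.id)
            seen.add(rec.id)
        if dups:
            raise CatalogError(f"duplicate record ids: {sorted(set(dups))}")
        self._by_id = {rec.id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._by_id

    def __getitem__(self, rec_id: str) -> NcRNARecord:
        return self._by_id[rec_id]

    @property
    def class_index(self) -> dict[str, list[str]]:
        """Mapping ncRNA class -> ids, covering exactly the records."""
        idx: dict[str, list[str]] = {}
        for rec in self.records:
            idx.setdefault(rec.ncrna_class, []).append(rec.id)
        return idx

    def classes(self) -> set[str]:
        return {rec.ncrna_class for rec in self.records}


def parse_header(header: str) -> tuple[str, str, str, str]:
    """Parse one FASTA description line into (id, class, family, subtype).

    Permissive: missing ``key=value`` pairs yield empty family/subtype and
    class ``other`` (with a warning); never raises.
    """
    parts = header.strip().split()
    if not parts:
        return "", "other", "", ""
    rec_id = parts[0]
    kv = {}
    for token in parts[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            kv[key] = value
    ncrna_class = kv.get("class", "")
    if ncrna_class not in NCRNA_CLASSES:
        if ncrna_class:
            logger.warning(
                "record %s: unknown class %r routed to 'other'", rec_id, ncrna_class
            )
        ncrna_class = "other"
    return rec_id, ncrna_class, kv.get("family", ""), kv.get("subtype", "")


def _read_annotation(path: Path) -> dict[str, tuple[str, str, str]]:
    """Side-file: TSV columns (id, class, family, subtype) or BED6 with the
    name field carrying ``id|class|family|subtype``."""
    ann: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 6 and fields[1].isdigit() and fields[2].isdigit():
                # BED6: chrom start end name score strand
                name = fields[3]
                sub = name.split("|")
                rec_id = sub[0]
                cls = sub[1] if len(sub) > 1 else "other"
                fam = sub[2] if len(sub) > 2 else ""
                subtype = sub[3] if len(sub) > 3 else ""
            elif len(fields) >= 2:
                rec_id = fields[0]
                cls = fields[1]
                fam = fields[2] if len(fields) > 2 else ""
                subtype = fields[3] if len(fields) > 3 else ""
            else:
                raise CatalogError(f"{path}:{line_no}: unparseable annotation line")
            if cls not in NCRNA_CLASSES:
                raise CatalogError(
                    f"{path}:{line_no}: unknown class {cls!r} for id {rec_id!r}"
                )
            ann[rec_id] = (cls, fam, subtype)
    return ann


def read_catalog(
    fasta_path: str | Path, annotation_path: str | Path | None = None
) -> NcRNACatalog:
    """Load a validated catalog from FASTA (+ optional annotation side-file).

    Records keep file order.  Raises :class:`CatalogError` on duplicate ids,
    invalid sequences, or annotation referencing unknown classes.
    """
    fasta_path = Path(fasta_path)
    annotation = _read_annotation(Path(annotation_path)) if annotation_path else {}
    records: list[NcRNARecord] = []
    for seqrec in SeqIO.parse(str(fasta_path), "fasta"):
        rec_id, cls, fam, subtype = parse_header(seqrec.description)
        if rec_id in annotation:
            cls, fam, subtype = annotation[rec_id]
        records.append(
            NcRNARecord(
                id=rec_id,
                ncrna_class=cls,
                family=fam,
                subtype=subtype,
                sequence=str(seqrec.seq).upper(),
            )
        )
    if not records:
        logger.warning("catalog %s is empty", fasta_path)
    return NcRNACatalog(records=records)


def write_catalog(catalog: NcRNACatalog, fasta_path: str | Path) -> None:
    """Write the catalog back to FASTA with key=value metadata headers."""
    with open(fasta_path, "w") as fh:
        for rec in catalog:
            parts = [rec.id, f"class={rec.ncrna_class}"]
            if rec.family:
                parts.append(f"family={rec.family}")
            if rec.subtype:
                parts.append(f"subtype={rec.subtype}")
            fh.write(">" + " ".join(parts) + "\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


def fragment_bearing_classes() -> frozenset[str]:
    """Classes whose reads are eligible to be called as end-anchored
    fragments.  Mature miRNAs are excluded: they are not processed into
    fragments the way tRNA/rRNA/snRNA/snoRNA precursors are."""
    return frozenset(
        {"tRNA", "rRNA", "snRNA", "snoRNA", "repeat", "lincRNA", "antisense"}
    )
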