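"""Synthetic small-RNA datasets with planted, recoverable structure.

The generator emulates a brain small-RNA sequencing library as this pipeline
expects it: 36-nt single-end reads, each a 7-nt adapter followed by an insert
of at most 29 nt, with read-through padding when the insert is shorter.  The
planted structure mirrors what such libraries look like in practice:

* a miRNA-dominated class mixture (miRNA ~0.77 of mapped reads, repeats the
  second-largest class, tRNA/rRNA/snoRNA/snRNA each a few percent);
* tRNA-fragment inserts with the characteristic 18-nt major and 26-nt minor
  length modes;
* a 5' origin bias for tRNA and repeat fragments, a 3' bias for snRNA,
  snoRNA and rRNA fragments (snoRNA default 1:7 five:three);
* a glycine-dominated tRF family mixture (Gly-GCC ~88% of tRF reads, Glu and
  Lys next, Val-CAC a minor family);
* per-family fragment:precursor ratios so that enrichment analysis has a
  planted direction (Gly-GCC over-processed ~3:1, Val-CAC under-processed
  ~1:5).

Every read is recorded in a truth manifest (source record, class, insert
length, end of origin, fragment flag) so the pipeline's recovery of each
planted parameter can be tested exactly.

Insert length 28 is never planted by default: fragments are <=27 nt and
precursor-length reads are 29 nt, and the band between is deliberately left
empty so the caller's exclusion of 28-nt reads is observable.  Set
``emit_ambiguous`` to plant 28-mers on purpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import NcRNACatalog, NcRNARecord, write_catalog

DEFAULT_ADAPTER = "TGGAATT"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


def _default_class_mixture() -> dict[str, float]:
    return {
        "miRNA": 0.77,
        "repeat": 0.12,
        "tRNA": 0.025,
        "rRNA": 0.015,
        "snoRNA": 0.02,
        "snRNA": 0.015,
        "lincRNA": 0.02,
        "antisense": 0.015,
    }


def _default_fragment_prob() -> dict[str, float]:
    return {
        "miRNA": 1.0,
        "repeat": 0.6,
        "tRNA": 0.5,
        "rRNA": 0.6,
        "snoRNA": 0.6,
        "snRNA": 0.6,
        "lincRNA": 0.5,
        "antisense": 0.5,
    }


def _default_end_bias() -> dict[str, float]:
    # probability that a fragment originates at the 5' end
    return {
        "miRNA": 0.5,
        "repeat": 0.8,
        "tRNA": 0.9,
        "rRNA": 0.2,
        "snoRNA": 0.125,  # 1:7 five:three
        "snRNA": 0.2,
        "lincRNA": 0.5,
        "antisense": 0.5,
    }


def _default_length_modes() -> dict[str, list[tuple[int, float]]]:
    return {
        "miRNA": [(21, 0.2), (22, 0.6), (23, 0.2)],
        "tRNA": [(18, 0.65), (26, 0.25), (20, 0.05), (22, 0.05)],
        "rRNA": [(17, 0.5), (25, 0.5)],
        "snoRNA": [(15, 0.2), (16, 0.2), (25, 0.3), (26, 0.3)],
        "snRNA": [(17, 0.3), (18, 0.4), (19, 0.3)],
        "repeat": [(20, 0.5), (24, 0.5)],
        "lincRNA": [(20, 0.6), (26, 0.4)],
        "antisense": [(18, 0.5), (19, 0.5)],
    }


def _default_trna_family_weights() -> dict[tuple[str, str], float]:
    # Read-level weights; combined with the per-family fragment odds below
    # they plant a ~90% glycine share among tRF calls (Glu and Lys next,
    # Val-CAC a minor, under-processed family).
    return {
        ("Gly", "GCC"): 0.84,
        ("Glu", "CTC"): 0.07,
        ("Lys", "CTT"): 0.055,
        ("Val", "CAC"): 0.035,
    }


def _default_trna_family_fragment_prob() -> dict[tuple[str, str], float]:
    # fragment:precursor odds -> planted enrichment ratio p/(1-p)
    return {
        ("Gly", "GCC"): 0.75,  # ratio 3: over-processed
        ("Val", "CAC"): 1.0 / 6.0,  # ratio 0.2: under-processed
    }


@dataclass
class SimConfig:
    seed: int = 0
    n_reads: int = 10_000
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 36
    class_mixture: dict[str, float] = field(default_factory=_default_class_mixture)
    fragment_prob: dict[str, float] = field(default_factory=_default_fragment_prob)
    end_bias: dict[str, float] = field(default_factory=_default_end_bias)
    length_modes: dict[str, list[tuple[int, float]]] = field(
        default_factory=_default_length_modes
    )
    trna_family_weights: dict[tuple[str, str], float] = field(
        default_factory=_default_trna_family_weights
    )
    trna_family_fragment_prob: dict[tuple[str, str], float] = field(
        default_factory=_default_trna_family_fragment_prob
    )
    mismatch_rate: float = 0.0
    records_per_class: int = 3
    emit_ambiguous: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_reads <= 0:
            raise SimConfigError(f"n_reads must be positive, got {self.n_reads}")
        if len(self.adapter) != 7:
            raise SimConfigError("adapter must be 7 nt")
        max_insert = self.read_length - len(self.adapter)
        if max_insert != 29:
            raise SimConfigError(
                f"read_length must be adapter length + 29 (got {self.read_length})"
            )
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise SimConfigError(f"class_mixture sums to {total}, expected 1")
        if any(v < 0 for v in self.class_mixture.values()):
            raise SimConfigError("class_mixture fractions must be non-negative")
        if not 0 <= self.mismatch_rate <= 0.05:
            raise SimConfigError("mismatch_rate must be in [0, 0.05]")
        for cls, modes in self.length_modes.items():
            for length, weight in modes:
                if not 15 <= length <= 29:
                    raise SimConfigError(
                        f"length mode {length} for {cls} outside [15, 29]"
                    )
                if length == 28 and not self.emit_ambiguous:
                    raise SimConfigError(
                        "insert length 28 is the ambiguous band; set emit_ambiguous "
                        "to plant it deliberately"
                    )
                if weight < 0:
                    raise SimConfigError("length-mode weights must be non-negative")
        for prob_map in (self.fragment_prob, self.end_bias):
            for cls, p in prob_map.items():
                if not 0 <= p <= 1:
                    raise SimConfigError(f"probability {p} for {cls} outside [0, 1]")
        if any(w < 0 for w in self.trna_family_weights.values()):
            raise SimConfigError("tRNA family weights must be non-negative")

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with fields replaced (re-validated)."""
        return replace(self, **kwargs)


def _adapter_contaminated(seq: str, adapter: str) -> bool:
    """Adapter-contamination screen for surrogate references.

    Rejects sequences containing the adapter, and sequences whose 29-nt
    prefix ends in a proper prefix of the adapter pattern: a precursor-length
    (29-nt, pad-free) read from such a reference would be indistinguishable
    from a shorter insert plus read-through pad, so trimming could not be
    exactly invertible.  Shorter (padded) inserts are unambiguous for a
    non-periodic adapter once the adapter itself is absent.
    """
    if adapter in seq:
        return True
    if len(seq) >= 29:
        prefix29 = seq[:29]
        for k in range(1, 15):  # trimmed insert must stay >= 15 nt
            if prefix29[29 - k :] == (adapter * 3)[:k]:
                return True
    return False


def _random_sequence(rng: np.random.Generator, length: int, adapter: str) -> str:
    """Uniform ACGT sequence passing the adapter-contamination screen."""
    while True:
        seq = bytes(rng.choice(_BASES, size=length)).decode()
        if not _adapter_contaminated(seq, adapter):
            return seq


_SEQ_LENGTH_RANGES = {
    "tRNA": (70, 90),
    "snoRNA": (60, 250),
    "snRNA": (100, 200),
    "rRNA": (120, 160),
}

_FAMILY_CYCLES = {
    "rRNA": ["5_8S_rRNA", "5S_rRNA", "Rn5-8s"],
    "snoRNA": ["snoRD116", "snoRA54", "snoRA-3"],
    "snRNA": ["U1", "U5", "U2"],
}


def generate_catalog(config: SimConfig) -> NcRNACatalog:
    """Deterministic surrogate reference catalog for the configured mixture.

    tRNA gets one record per (amino acid, anticodon) in the family weights;
    every other class with nonzero mixture gets ``records_per_class`` records
    with surrogate family labels.
    """
    rng = np.random.default_rng([config.seed, 0])
    records: list[NcRNARecord] = []
    for cls, frac in config.class_mixture.items():
        if frac <= 0:
            continue
        if cls == "tRNA":
            if not config.trna_family_weights:
                raise SimConfigError("tRNA in mixture but no tRNA family weights")
            for i, (aa, anticodon) in enumerate(config.trna_family_weights, 1):
                lo, hi = _SEQ_LENGTH_RANGES["tRNA"]
                length = int(rng.integers(lo, hi + 1))
                records.append(
                    NcRNARecord(
                        id=f"trna-{aa}-{anticodon}-{i}",
                        ncrna_class="tRNA",
                        family=aa,
                        subtype=anticodon,
                        sequence=_random_sequence(rng, length, config.adapter),
                    )
                )
        else:
            lo, hi = _SEQ_LENGTH_RANGES.get(cls, (60, 300))
            families = _FAMILY_CYCLES.get(cls, [""])
            for i in range(config.records_per_class):
                length = int(rng.integers(lo, hi + 1))
                records.append(
                    NcRNARecord(
                        id=f"{cls.lower()}-{i + 1}",
                        ncrna_class=cls,
                        family=families[i % len(families)],
                        subtype="",
                        sequence=_random_sequence(rng, length, config.adapter),
                    )
                )
    return NcRNACatalog(records=records)


def _pad_pattern(adapter: str, length: int) -> str:
    """Read-through padding: the adapter repeated from its first base."""
    reps = (length // len(adapter)) + 1
    return (adapter * reps)[:length]


def _inject_mismatches(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    for i in np.flatnonzero(hit):
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def generate_reads(
    catalog: NcRNACatalog,
    config: SimConfig,
    fastq_path: str | Path | None = None,
    manifest_path: str | Path | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Emit reads and the truth manifest; optionally write FASTQ/TSV.

    Returns ``(reads, manifest)`` where reads are ``(read_id, sequence)``
    pairs and the manifest has one row per read with columns ``read_id,
    ncrna_id, ncrna_class, insert_length, end_type, is_fragment``.
    """
    rng = np.random.default_rng([config.seed, 1])
    classes = [c for c, f in config.class_mixture.items() if f > 0]
    probs = np.array([config.class_mixture[c] for c in classes])
    probs = probs / probs.sum()

    by_class: dict[str, list[NcRNARecord]] = {}
    for rec in catalog:
        by_class.setdefault(rec.ncrna_class, []).append(rec)
    for cls in classes:
        if cls not in by_class:
            raise SimConfigError(f"mixture class {cls!r} has no catalog records")

    trna_fams = list(config.trna_family_weights)
    if trna_fams:
        fam_w = np.array([config.trna_family_weights[f] for f in trna_fams], float)
        fam_w = fam_w / fam_w.sum()
    trna_by_family: dict[tuple[str, str], list[NcRNARecord]] = {}
    for rec in by_class.get("tRNA", []):
        trna_by_family.setdefault((rec.family, rec.subtype), []).append(rec)

    class_draws = rng.choice(len(classes), size=config.n_reads, p=probs)

    reads: list[tuple[str, str]] = []
    rows: list[tuple] = []
    for i in range(config.n_reads):
        cls = classes[class_draws[i]]
        if cls == "tRNA":
            fam = trna_fams[rng.choice(len(trna_fams), p=fam_w)]
            pool = trna_by_family[fam]
            frag_p = config.trna_family_fragment_prob.get(
                fam, config.fragment_prob.get(cls, 0.5)
            )
        else:
            pool = by_class[cls]
            frag_p = config.fragment_prob.get(cls, 0.5)
        rec = pool[rng.integers(len(pool))]

        is_fragment = bool(rng.random() < frag_p) or len(rec.sequence) < 29
        if is_fragment:
            modes = config.length_modes.get(cls, [(18, 1.0)])
            lengths = [m[0] for m in modes]
            weights = np.array([m[1] for m in modes], float)
            weights = weights / weights.sum()
            insert_len = lengths[rng.choice(len(lengths), p=weights)]
            insert_len = min(insert_len, len(rec.sequence))
            five = bool(rng.random() < config.end_bias.get(cls, 0.5))
            if five:
                insert = rec.sequence[:insert_len]
                end_type = "five_prime"
            else:
                insert = rec.sequence[-insert_len:]
                end_type = "three_prime"
        else:
            insert_len = 29
            insert = rec.sequence[:29]
            end_type = "five_prime"

        insert = _inject_mismatches(rng, insert, config.mismatch_rate)
        pad_len = config.read_length - len(config.adapter) - len(insert)
        read_seq = config.adapter + insert + _pad_pattern(config.adapter, pad_len)
        read_id = f"read_{i:07d}"
        reads.append((read_id, read_seq))
        rows.append((read_id, rec.id, cls, insert_len, end_type, is_fragment))

    manifest = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "ncrna_id",
            "ncrna_class",
            "insert_length",
            "end_type",
            "is_fragment",
        ],
    )
    if fastq_path is not None:
        write_fastq(reads, fastq_path)
    if manifest_path is not None:
        manifest.to_csv(manifest_path, sep="\t", index=False)
    return reads, manifest


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    """Plain FASTQ with constant 'I' qualities (qualities are never used)."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def generate_dataset(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write catalog FASTA, reads FASTQ, truth manifest TSV and a config echo
    into ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = generate_catalog(config)
    paths = {
        "catalog": out / "catalog.fasta",
        "reads": out / "reads.fastq",
        "manifest": out / "truth_manifest.tsv",
        "config": out / "sim_config.txt",
    }
    write_catalog(catalog, paths["catalog"])
    generate_reads(catalog, config, fastq_path=paths["reads"],
                   manifest_path=paths["manifest"])
    with open(paths["config"], "w") as fh:
        for key, value in vars(config).items():
            fh.write(f"{key}\t{value!r}\n")
    return paths
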