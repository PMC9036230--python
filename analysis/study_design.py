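"""Shared design for the analysis scripts: a six-sample brain small-RNA
study (frontal cortex, cerebellum, hippocampus x male/female) simulated at
desk scale.

Per-sample tweaks mirror the qualitative contrasts the pipeline is meant to
expose: the hippocampus has the smallest miRNA share and the cerebellum the
largest; male samples run at somewhat higher depth so proration has work to
do.  Each sample gets its own seed; the catalog is shared (seeded from the
study seed) so all samples map to the same references.
"""

from __future__ import annotations

from pathlib import Path

from ncrf.simulate import SimConfig

STUDY_SEED = 2026
N_READS = 30_000

_ROOT = Path(__file__).resolve().parent.parent
RESULTS = _ROOT / "results"
# bulky per-sample intermediates (FASTQ, SAM, per-read tables) are kept out
# of results/ — they are regenerated by 01_simulate.py on demand
SCRATCH = _ROOT / "scratch"

# miRNA share per region (hippocampus lowest, cerebellum highest); the
# repeat class absorbs the difference so mixtures stay normalized.
MIRNA_SHARE = {"FC": 0.77, "HIP": 0.70, "CER": 0.83}
DEPTH_FACTOR = {"M": 1.0, "F": 0.8}

SAMPLES = ["FC_M", "CER_M", "HIP_M", "FC_F", "CER_F", "HIP_F"]


def sample_config(sample: str) -> SimConfig:
    region, sex = sample.split("_")
    base = SimConfig(seed=STUDY_SEED)
    mixture = dict(base.class_mixture)
    delta = MIRNA_SHARE[region] - mixture["miRNA"]
    mixture["miRNA"] += delta
    mixture["repeat"] -= delta
    return SimConfig(
        seed=STUDY_SEED + 10 * SAMPLES.index(sample) + 1,
        n_reads=int(N_READS * DEPTH_FACTOR[sex]),
        class_mixture=mixture,
    )


def sim_dir() -> Path:
    d = SCRATCH / "sim"
    d.mkdir(parents=True, exist_ok=True)
    return d


def sample_dir(sample: str) -> Path:
    d = sim_dir() / sample
    d.mkdir(parents=True, exist_ok=True)
    return d
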