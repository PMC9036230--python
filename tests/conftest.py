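from __future__ import annotations

from types import SimpleNamespace

import pytest

from ncrf.align import ReadRecord, trim_and_map
from ncrf.fragments import call_fragments
from ncrf.reference import NcRNACatalog, NcRNARecord
from ncrf.simulate import SimConfig, generate_catalog, generate_reads


@pytest.fixture(scope="session")
def clean_config() -> SimConfig:
    """The default study conditions, error-free reads, desk-scale depth."""
    return SimConfig(seed=11, n_reads=50_000, mismatch_rate=0.0)


@pytest.fixture(scope="session")
def clean_run(clean_config):
    """Full pipeline on one clean simulated sample, shared across tests."""
    catalog = generate_catalog(clean_config)
    reads, manifest = generate_reads(catalog, clean_config)
    hits, stats = trim_and_map(
        [ReadRecord(rid, seq) for rid, seq in reads], catalog, clean_config.adapter
    )
    calls = call_fragments(hits, catalog)
    return SimpleNamespace(
        config=clean_config,
        catalog=catalog,
        reads=reads,
        manifest=manifest,
        hits=hits,
        stats=stats,
        calls=calls,
    )


@pytest.fixture()
def tiny_catalog() -> NcRNACatalog:
    """Hand-built three-record catalog with known sequences."""
    return NcRNACatalog(
        records=[
            NcRNARecord(
                id="trna-Gly-GCC-1",
                ncrna_class="tRNA",
                family="Gly",
                subtype="GCC",
                sequence="GCATTGGTGGTTCAGTGGTAGAATTCTCGCCTGCCACGCGGGAGGCCCGGGTTCGATTCCCGG",
            ),
            NcRNARecord(
                id="snord116-1",
                ncrna_class="snoRNA",
                family="snoRD116",
                subtype="",
                sequence="TGGATCGATGATGAGTCCCCCAATACTGACGGATAACTGAGCAAATGCTGA"
                "CTGAACCCATTCTGAGTGA",
            ),
            NcRNARecord(
                id="u1-1",
                ncrna_class="snRNA",
                family="U1",
                subtype="",
                sequence="ATACTTACCTGGCAGGGGAGATACCATGATCACGAAGGTGGTTTTCCCAGG"
                "GCGAGGCTTATCCATTGCACTCCGGATGTGCTGACCCCTGCGATTTCCCCA",
            ),
        ]
    )
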