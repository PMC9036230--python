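import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncrf.align import AlignmentHit
from ncrf.fragments import (
    assign_end_type,
    call_fragments,
    end_ratio,
    family_table,
    positional_bins,
    size_fraction_table,
    trf_subtype,
    FragmentCall,
)
from ncrf.reference import NcRNACatalog, NcRNARecord


@pytest.fixture()
def trna_catalog():
    return NcRNACatalog(
        records=[
            NcRNARecord("trna-Gly-GCC-1", "tRNA", "Gly", "GCC", "A" * 30 + "C" * 30),
            NcRNARecord("trna-Glu-CTC-1", "tRNA", "Glu", "CTC", "G" * 30 + "T" * 30),
            NcRNARecord("mir-1", "miRNA", "", "", "ACGT" * 6),
        ]
    )


def _hits(rec_id, n, offset=0, length=18, start=0):
    return [
        AlignmentHit(f"{rec_id}_{start + i}", rec_id, offset, length, 0)
        for i in range(n)
    ]


class TestCallFragments:
    def test_supported_end_anchored_reads_become_calls(self, trna_catalog):
        hits = _hits("trna-Gly-GCC-1", 6)
        calls = call_fragments(hits, trna_catalog)
        assert len(calls) == 6
        assert {c.end_type for c in calls} == {"five_prime"}
        assert {c.ncrf_class for c in calls} == {"tRF"}
        assert {c.family_label for c in calls} == {"tRF-GlyGCC"}

    def test_below_min_support_yields_no_calls(self, trna_catalog):
        calls = call_fragments(_hits("trna-Gly-GCC-1", 4), trna_catalog)
        assert calls == []

    def test_support_counts_precursor_reads_too(self, trna_catalog):
        """Two fragments plus three precursor-length reads clear the
        five-read support bar; only the fragments become calls."""
        hits = _hits("trna-Gly-GCC-1", 2) + _hits(
            "trna-Gly-GCC-1", 3, length=29, start=10
        )
        calls = call_fragments(hits, trna_catalog)
        assert len(calls) == 2

    def test_length_band_excludes_28_and_above(self, trna_catalog):
        hits = (
            _hits("trna-Gly-GCC-1", 3, length=27)
            + _hits("trna-Gly-GCC-1", 3, length=28, start=10)
            + _hits("trna-Gly-GCC-1", 3, length=29, start=20)
        )
        calls = call_fragments(hits, trna_catalog)
        assert len(calls) == 3
        assert all(c.insert_length == 27 for c in calls)

    def test_mirna_never_called(self, trna_catalog):
        calls = call_fragments(_hits("mir-1", 10), trna_catalog)
        assert calls == []

    def test_min_support_must_be_positive(self, trna_catalog):
        with pytest.raises(ValueError, match="min_support"):
            call_fragments([], trna_catalog, min_support=0)

    def test_end_tolerance_relaxes_anchoring(self, trna_catalog):
        hits = _hits("trna-Gly-GCC-1", 5, offset=1)
        strict = call_fragments(hits, trna_catalog, end_tolerance=0)
        relaxed = call_fragments(hits, trna_catalog, end_tolerance=1)
        assert {c.end_type for c in strict} == {"internal"}
        assert {c.end_type for c in relaxed} == {"five_prime"}


@pytest.mark.parametrize(
    "offset, length, ref_len, expected",
    [
        (0, 18, 60, "five_prime"),
        (42, 18, 60, "three_prime"),
        (10, 18, 60, "internal"),
    ],
)
def test_assign_end_type(offset, length, ref_len, expected):
    assert assign_end_type(offset, length, ref_len) == expected


class TestPositionalBins:
    def test_single_read_at_start_fills_first_bin(self):
        catalog = NcRNACatalog(
            records=[NcRNARecord("x", "tRNA", "Gly", "GCC", "A" * 100)]
        )
        dist = positional_bins([AlignmentHit("r", "x", 0, 18, 0)], catalog, "tRNA")
        assert dist.bin_fractions[0] == 1.0
        assert sum(dist.bin_fractions) == 1.0

    def test_uniform_offsets_give_near_uniform_bins(self):
        """Reads at every admissible offset: compare to direct enumeration
        of floor(10*offset/len) over those offsets."""
        ref_len, length = 95, 15
        catalog = NcRNACatalog(
            records=[NcRNARecord("x", "tRNA", "Gly", "GCC", "A" * ref_len)]
        )
        hits = [
            AlignmentHit(f"r{o}", "x", o, length, 0)
            for o in range(ref_len - length + 1)
        ]
        expected = [0] * 10
        for o in range(ref_len - length + 1):
            expected[10 * o // ref_len] += 1
        dist = positional_bins(hits, catalog, "tRNA")
        assert list(dist.bin_counts) == expected

    def test_planted_five_prime_bias_peaks_in_first_bin(self, clean_run):
        dist = positional_bins(clean_run.hits, clean_run.catalog, "tRNA")
        assert dist.bin_fractions.index(max(dist.bin_fractions)) == 0

    def test_planted_three_prime_bias_loads_late_bins(self, clean_run):
        """3'-anchored fragments start at reference_length - insert_length,
        so their start bins concentrate in the last few bins (which bin
        exactly depends on reference and insert lengths)."""
        dist = positional_bins(clean_run.hits, clean_run.catalog, "snoRNA")
        fractions = dist.bin_fractions
        assert fractions.index(max(fractions)) >= 7
        assert sum(fractions[5:]) > sum(fractions[:5])

    def test_empty_class_flagged(self):
        catalog = NcRNACatalog(
            records=[NcRNARecord("x", "tRNA", "Gly", "GCC", "A" * 100)]
        )
        dist = positional_bins([], catalog, "tRNA")
        assert dist.empty
        assert len(dist.bin_counts) == 10

    @given(offsets=st.lists(st.integers(0, 80), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_fractions_always_normalize(self, offsets):
        catalog = NcRNACatalog(
            records=[NcRNARecord("x", "snoRNA", "snoRD116", "", "A" * 100)]
        )
        hits = [AlignmentHit(f"r{i}", "x", o, 15, 0) for i, o in enumerate(offsets)]
        dist = positional_bins(hits, catalog, "snoRNA")
        assert len(dist.bin_counts) == 10
        assert math.isclose(sum(dist.bin_fractions), 1.0, abs_tol=1e-9)


def _call(family, subtype, n, ncrf_class="tRF", end="five_prime", length=18):
    label = f"tRF-{family}{subtype}" if ncrf_class == "tRF" else f"{ncrf_class}:x"
    return [
        FragmentCall(f"{family}{i}", "ref", ncrf_class, end, length, label,
                     family, subtype)
        for i in range(n)
    ]


class TestFamilyTable:
    def test_dominant_family_share(self):
        calls = _call("Gly", "GCC", 9) + _call("Glu", "CTC", 1)
        table = family_table(calls, level="amino_acid")
        gly = table[table.family_label == "tRF-Gly"].iloc[0]
        assert gly["percent"] == 90.0

    def test_isoacceptor_level_keeps_anticodon(self):
        table = family_table(_call("Gly", "GCC", 3))
        assert list(table.family_label) == ["tRF-GlyGCC"]

    def test_empty_input_empty_table(self):
        assert family_table([]).empty

    def test_percentages_sum_to_100_within_class(self, clean_run):
        table = family_table(clean_run.calls)
        sums = table.groupby("ncrf_class")["percent"].sum()
        assert (sums - 100.0).abs().max() < 0.01


class TestSizeFractionTable:
    def test_counts_per_length(self):
        calls = _call("Gly", "GCC", 5, length=18) + _call("Glu", "CTC", 3, length=26)
        table = size_fraction_table(calls, "tRF").set_index("insert_length")
        assert table.loc[18, "count"] == 5
        assert table.loc[26, "count"] == 3
        assert table["count"].sum() == 8

    def test_empty_input_all_zero(self):
        table = size_fraction_table([], "tRF")
        assert (table["count"] == 0).all()

    def test_omit_modal_length(self):
        calls = _call("Gly", "GCC", 5, length=18)
        table = size_fraction_table(calls, "tRF", omit_length=18)
        assert 18 not in set(table.insert_length)


class TestEndRatio:
    def test_seven_to_one(self):
        calls = _call("", "", 7, ncrf_class="snoRF", end="three_prime") + _call(
            "", "", 1, ncrf_class="snoRF", end="five_prime"
        )
        five, three, ratio = end_ratio(calls, "snoRF")
        assert (five, three, ratio) == (1, 7, 7.0)

    def test_zero_denominator_flagged(self):
        calls = _call("", "", 3, ncrf_class="snoRF", end="three_prime")
        five, three, ratio = end_ratio(calls, "snoRF")
        assert five == 0 and three == 3
        assert math.isnan(ratio)

    def test_trf_convention_is_five_to_three(self):
        calls = _call("Gly", "GCC", 9, end="five_prime") + _call(
            "Gly", "GCC", 3, end="three_prime"
        )
        assert end_ratio(calls, "tRF")[2] == 3.0


def test_trf_subtype_nomenclature():
    short5 = _call("Gly", "GCC", 1, length=18)[0]
    half3 = _call("Gly", "GCC", 1, end="three_prime", length=26)[0]
    assert trf_subtype(short5) == "tRF-5"
    assert trf_subtype(half3) == "tRH-3"


def test_partition_every_qualifying_hit_called_once(clean_run):
    """Every <=27-nt hit on a supported fragment-bearing precursor yields
    exactly one call; nothing of length >= 28 is ever called."""
    from ncrf.reference import fragment_bearing_classes

    support = {}
    for h in clean_run.hits:
        support[h.ncrna_id] = support.get(h.ncrna_id, 0) + 1
    bearing = fragment_bearing_classes()
    expected = [
        h
        for h in clean_run.hits
        if h.insert_length <= 27
        and clean_run.catalog[h.ncrna_id].ncrna_class in bearing
        and support[h.ncrna_id] >= 5
    ]
    assert len(clean_run.calls) == len(expected)
    assert {c.read_id for c in clean_run.calls} == {h.read_id for h in expected}
    assert all(c.insert_length <= 27 for c in clean_run.calls)
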