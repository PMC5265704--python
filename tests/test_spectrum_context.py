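"""Substitution classes, spectra, enrichment, zygosity, and sequence context."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oxisoma.io_formats import ReferenceSequence, complement
from oxisoma.spectrum_context import (
    SUBSTITUTION_CLASSES,
    ccg_motif_fraction,
    collapse_class,
    enrichment,
    spectrum,
    three_prime_context,
    zygosity_by_tissue,
)

from helpers import call_shim

_PAIRS = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]


class TestCollapseClass:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [("G", "T", "G:C>T:A"), ("C", "A", "G:C>T:A"), ("A", "G", "A:T>G:C"),
         ("T", "C", "A:T>G:C"), ("G", "A", "G:C>A:T"), ("A", "T", "A:T>T:A"),
         ("T", "G", "A:T>C:G"), ("C", "G", "G:C>C:G")],
    )
    def test_mapping(self, ref, alt, expected):
        assert collapse_class(ref, alt) == expected

    @given(st.sampled_from(_PAIRS))
    def test_invariant_under_complementation(self, pair):
        ref, alt = pair
        assert collapse_class(ref, alt) == collapse_class(complement(ref), complement(alt))

    def test_identity_rejected(self):
        with pytest.raises(ValueError):
            collapse_class("G", "G")


def _calls_for_counts(counts: dict[str, int]):
    example_change = {
        "A:T>G:C": ("A", "G"), "G:C>A:T": ("G", "A"), "G:C>T:A": ("G", "T"),
        "A:T>T:A": ("A", "T"), "A:T>C:G": ("A", "C"), "G:C>C:G": ("G", "C"),
    }
    calls = []
    for cls, n in counts.items():
        ref, alt = example_change[cls]
        calls.extend(call_shim(ref, alt) for _ in range(n))
    return calls


class TestSpectrum:
    def test_dominant_transversion_proportion(self):
        calls = _calls_for_counts({"G:C>T:A": 87, "G:C>A:T": 7, "A:T>G:C": 6})
        table = spectrum(calls, "somatic")
        assert table.total == 100
        assert table.proportions["G:C>T:A"] == pytest.approx(0.87)

    def test_single_call(self):
        table = spectrum([call_shim("A", "G")], "somatic")
        assert table.proportions == {c: (1.0 if c == "A:T>G:C" else 0.0) for c in SUBSTITUTION_CLASSES}

    def test_uniform_mix(self):
        table = spectrum(_calls_for_counts({c: 10 for c in SUBSTITUTION_CLASSES}), "germline")
        assert all(p == pytest.approx(1 / 6) for p in table.proportions.values())

    def test_empty_subset_flagged(self):
        table = spectrum([], "somatic")
        assert table.total == 0 and table.proportions is None

    @given(st.lists(st.sampled_from(_PAIRS), min_size=1, max_size=60))
    def test_proportions_sum_to_one(self, pairs):
        table = spectrum([call_shim(r, a) for r, a in pairs], "x")
        assert sum(table.proportions.values()) == pytest.approx(1.0, abs=1e-12)


class TestEnrichment:
    def test_constructed_difference(self):
        som = spectrum(_calls_for_counts({"G:C>T:A": 87, "G:C>A:T": 13}), "somatic")
        germ = spectrum(_calls_for_counts({"G:C>T:A": 7, "G:C>A:T": 50, "A:T>G:C": 43}), "germline")
        result = enrichment(som, germ)
        assert result.differences["G:C>T:A"] == pytest.approx(0.80)

    def test_identical_tables_give_zero(self):
        tab = spectrum(_calls_for_counts({"G:C>T:A": 5, "A:T>G:C": 5}), "x")
        assert all(d == 0 for d in enrichment(tab, tab).differences.values())

    @given(
        st.lists(st.sampled_from(_PAIRS), min_size=1, max_size=40),
        st.lists(st.sampled_from(_PAIRS), min_size=1, max_size=40),
    )
    def test_differences_sum_to_zero(self, som_pairs, germ_pairs):
        som = spectrum([call_shim(r, a) for r, a in som_pairs], "somatic")
        germ = spectrum([call_shim(r, a) for r, a in germ_pairs], "germline")
        assert abs(sum(enrichment(som, germ).differences.values())) < 1e-12

    def test_empty_table_rejected(self):
        tab = spectrum(_calls_for_counts({"G:C>T:A": 5}), "x")
        with pytest.raises(ValueError):
            enrichment(tab, spectrum([], "y"))


class TestZygosity:
    def test_threshold_rule(self):
        calls = [
            call_shim("G", "T", vaf1=0.40, vaf2=0.02),  # het in t1
            call_shim("C", "A", vaf1=0.01, vaf2=0.30),  # het in t2
            call_shim("G", "T", vaf1=0.07, vaf2=0.01),  # 5-10% gap: indeterminate
            call_shim("G", "T", vaf1=0.40, vaf2=0.08),  # partner not hom-ref: indeterminate
            call_shim("A", "G", vaf1=0.40, vaf2=0.02),  # other class: ignored
        ]
        table = zygosity_by_tissue(calls, "G:C>T:A")
        assert (table.het_tissue1, table.het_tissue2, table.indeterminate) == (1, 1, 2)

    def test_fraction_over_determinate_sites(self):
        calls = [call_shim("G", "T", vaf1=0.4, vaf2=0.0) for _ in range(7)]
        calls += [call_shim("G", "T", vaf1=0.0, vaf2=0.4) for _ in range(3)]
        table = zygosity_by_tissue(calls, "G:C>T:A")
        assert table.fraction_het_tissue1 == pytest.approx(0.70)

    def test_empty_class_has_no_fraction(self):
        assert zygosity_by_tissue([], "G:C>T:A").fraction_het_tissue1 is None


class TestThreePrimeContext:
    def test_g_strand_direct_readoff(self):
        ref = ReferenceSequence("r", "TTGATT")
        tally = three_prime_context([call_shim("G", "T", pos=3)], ref)
        assert tally.counts["A"] == 1 and tally.total == 1

    def test_c_event_reoriented_to_g_strand(self):
        # 5' T of the mutated C complements to A 3' of the G on the other strand
        ref = ReferenceSequence("r", "ATCGT")
        tally = three_prime_context([call_shim("C", "A", pos=3)], ref)
        assert tally.counts["A"] == 1

    def test_edge_sites_excluded_with_warning(self):
        ref = ReferenceSequence("r", "ACGTG")
        with pytest.warns(UserWarning):
            tally = three_prime_context([call_shim("G", "T", pos=5)], ref)
        assert tally.n_excluded == 1 and tally.total == 0

    def test_null_distribution_roughly_uniform(self):
        rng = np.random.default_rng(21)
        bases = "".join("ACGT"[i] for i in rng.integers(0, 4, 4000))
        ref = ReferenceSequence("r", bases)
        calls = [
            call_shim("G" if bases[p - 1] == "G" else "C", "T" if bases[p - 1] == "G" else "A", pos=p)
            for p in range(2, 4000)
            if bases[p - 1] in "GC"
        ]
        tally = three_prime_context(calls, ref)
        for b in "ACGT":
            assert abs(tally.counts[b] / tally.total - 0.25) < 0.05


class TestCcgMotif:
    def test_c_strand_motif(self):
        ref = ReferenceSequence("r", "ACCGT")
        res = ccg_motif_fraction([call_shim("C", "A", pos=3)], ref)  # context CCG
        assert res.n_motif == 1 and res.fraction == 1.0

    def test_non_motif_context(self):
        ref = ReferenceSequence("r", "AACGT")
        res = ccg_motif_fraction([call_shim("C", "A", pos=3)], ref)  # context ACG
        assert res.n_motif == 0 and res.fraction == 0.0

    def test_g_event_via_reverse_complement(self):
        # genomic CGG centred on the mutated G reads CCG on the C strand
        ref = ReferenceSequence("r", "ACGGT")
        res = ccg_motif_fraction([call_shim("G", "T", pos=3)], ref)
        assert res.n_motif == 1

    def test_edge_excluded(self):
        ref = ReferenceSequence("r", "CGGTA")
        res = ccg_motif_fraction([call_shim("C", "A", pos=1)], ref)
        assert res.n_excluded == 1 and res.fraction is None
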