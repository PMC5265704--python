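"""Codon-effect annotation and hypergeometric enrichment statistics."""

from math import comb

import numpy as np
import pytest

from oxisoma.annotation_enrichment import (
    annotate_effect,
    long_gene_test,
    overrepresentation,
    syn_nonsyn_summary,
)
from oxisoma.io_formats import GeneModel, ReferenceSequence

from oracles import bh_oracle, ora_tail_oracle as hypergeom_tail_oracle, transcript_oracle


class TestAnnotateEffect:
    def _plus_gene(self):
        ref = ReferenceSequence("r", "AAATGGCTGAGTAGAAA")
        # CDS at 3..14: ATG GCT GAG TAG
        gene = GeneModel("g+", "r", "+", 2, 16, [(3, 14)])
        return ref, gene

    def test_synonymous_third_position(self):
        ref, gene = self._plus_gene()
        # GCT -> GCC, codon 2 third position (genomic pos 8)
        eff = annotate_effect(("r", 8, "T", "C"), [gene], ref)
        assert eff.effect == "synonymous"
        assert eff.ref_aa == eff.alt_aa == "A"
        assert eff.codon_position == 3

    def test_stopgain(self):
        ref, gene = self._plus_gene()
        # GAG -> TAG at codon 3 first position (genomic pos 9)
        eff = annotate_effect(("r", 9, "G", "T"), [gene], ref)
        assert eff.effect == "stopgain"
        assert (eff.ref_aa, eff.alt_aa) == ("E", "*")

    def test_utr_and_noncoding(self):
        ref, gene = self._plus_gene()
        assert annotate_effect(("r", 2, "A", "G"), [gene], ref).effect == "UTR"
        assert annotate_effect(("r", 16, "G", "C"), [gene], ref).effect == "UTR"
        assert annotate_effect(("r", 1, "A", "G"), [gene], ref).effect == "noncoding"

    def test_minus_strand_matches_transcript_oracle(self):
        rng = np.random.default_rng(9)
        bases = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        ref = ReferenceSequence("r", bases)
        gene = GeneModel("g-", "r", "-", 5, 55, [(40, 51), (10, 30)])  # 12 + 21 = 33 bp
        for pos in range(5, 56):
            ref_base = ref.base(pos)
            for alt in "ACGT":
                if alt == ref_base:
                    continue
                eff = annotate_effect(("r", pos, ref_base, alt), [gene], ref)
                assert eff.effect == transcript_oracle(pos, ref_base, alt, gene, ref)

    def test_random_variants_both_strands_match_oracle(self, toy_simref):
        rng = np.random.default_rng(31)
        ref = toy_simref.reference
        genes = toy_simref.genes
        for _ in range(300):
            pos = int(rng.integers(1, len(ref) + 1))
            ref_base = ref.base(pos)
            alt = "ACGT"[("ACGT".index(ref_base) + int(rng.integers(1, 4))) % 4]
            eff = annotate_effect((ref.name, pos, ref_base, alt), genes, ref)
            oracle = sorted(
                (transcript_oracle(pos, ref_base, alt, g, ref) for g in genes.values()
                 if g.contains(pos)),
                key=["stopgain", "nonsynonymous", "synonymous", "UTR", "noncoding"].index,
            )
            expected = oracle[0] if oracle else "noncoding"
            assert eff.effect == expected, f"pos {pos} {ref_base}>{alt}"

    def test_most_severe_effect_wins_for_overlapping_genes(self):
        ref = ReferenceSequence("r", "AAATGGCTGAGTAGAAA")
        coding = GeneModel("g1", "r", "+", 2, 16, [(3, 14)])
        span_only = GeneModel("g2", "r", "+", 1, 17, [])
        eff = annotate_effect(("r", 9, "G", "T"), [span_only, coding], ref)
        assert eff.effect == "stopgain" and eff.gene_id == "g1"

    def test_missing_alt_rejected(self):
        ref, gene = self._plus_gene()
        with pytest.raises(ValueError):
            annotate_effect(("r", 8, "T", None), [gene], ref)


class TestSynNonsyn:
    def test_fractions(self):
        from oxisoma.annotation_enrichment import CodingEffect

        effects = [CodingEffect("g", "nonsynonymous")] * 60 + [CodingEffect("g", "stopgain")] * 4
        effects += [CodingEffect("g", "synonymous")] * 36 + [CodingEffect(None, "noncoding")] * 10
        summary = syn_nonsyn_summary(effects)
        assert summary.n_coding == 100
        assert summary.fraction_nonsynonymous == pytest.approx(0.64)

    def test_empty_coding_set_flagged(self):
        assert syn_nonsyn_summary([]).fraction_nonsynonymous is None


def _genes_with_lengths(lengths, prefix="g"):
    return [
        GeneModel(f"{prefix}{i}", "chr1", "+", 1, int(length), [])
        for i, length in enumerate(lengths)
    ]


class TestLongGeneTest:
    def test_matches_enumeration_oracle(self):
        bg = _genes_with_lengths([200_000] * 18 + [50_000] * 82)
        fg = bg[:5] + bg[50:55]  # 5 long of 10
        res = long_gene_test(fg, bg, length_threshold=100_000)
        assert (res.k, res.n, res.K, res.N) == (5, 10, 18, 100)
        assert res.p_value == pytest.approx(hypergeom_tail_oracle(5, 100, 18, 10), rel=1e-9)

    def test_no_excess_when_foreground_is_background(self):
        bg = _genes_with_lengths([200_000] * 18 + [50_000] * 82)
        res = long_gene_test(bg, bg, length_threshold=100_000)
        assert res.p_value == pytest.approx(1.0)

    def test_maximal_enrichment(self):
        bg = _genes_with_lengths([200_000] * 5 + [50_000] * 95)
        res = long_gene_test(bg[:5], bg, length_threshold=100_000)
        assert res.p_value == pytest.approx(hypergeom_tail_oracle(5, 100, 5, 5), rel=1e-9)
        assert res.p_value == pytest.approx(1 / comb(100, 5), rel=1e-9)


class TestOverrepresentation:
    def test_fully_contained_set(self):
        universe = [f"u{i}" for i in range(1000)]
        fg = universe[:5]
        res = overrepresentation(fg, {"S": set(fg)}, universe)[0]
        assert res.p_value == pytest.approx(1 / comb(1000, 5), rel=1e-9)

    def test_disjoint_set_has_p_one(self):
        universe = [f"u{i}" for i in range(50)]
        res = overrepresentation(universe[:5], {"S": universe[40:45]}, universe)[0]
        assert res.p_value == pytest.approx(1.0)

    def test_matches_enumeration_on_small_universe(self):
        rng = np.random.default_rng(17)
        universe = [f"u{i}" for i in range(120)]
        fg = list(rng.choice(universe, size=15, replace=False))
        sets = {
            f"S{j}": set(rng.choice(universe, size=int(rng.integers(5, 40)), replace=False))
            for j in range(6)
        }
        for res in overrepresentation(fg, sets, universe):
            want = hypergeom_tail_oracle(res.k, res.N, res.K, res.n)
            assert res.p_value == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_bh_adjustment_matches_definition(self):
        rng = np.random.default_rng(23)
        universe = [f"u{i}" for i in range(150)]
        fg = list(rng.choice(universe, size=20, replace=False))
        sets = {
            f"S{j}": set(rng.choice(universe, size=25, replace=False)) for j in range(8)
        }
        results = overrepresentation(fg, sets, universe)
        expected = bh_oracle([r.p_value for r in results])
        for r, want in zip(results, expected):
            assert r.adj_p == pytest.approx(want, rel=1e-9)
        # monotone non-decreasing in rank, capped at 1
        adj = [r.adj_p for r in results]
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))
        assert all(0 <= a <= 1 for a in adj)

    def test_bh_of_ties_to_maximum(self):
        # (0.01, 0.02, 0.03) over 3 sets adjusts to (0.03, 0.03, 0.03)
        assert bh_oracle([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        from statsmodels.stats.multitest import multipletests

        assert multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1] == pytest.approx([0.03] * 3)

    def test_foreground_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation(["x"], {"S": {"a"}}, ["a", "b"])
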