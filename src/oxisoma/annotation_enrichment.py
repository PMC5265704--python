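"""Minimal coding-effect annotation and gene-level enrichment statistics.

The annotator rebuilds the affected codon in transcription order (reverse
complemented on the minus strand) and translates it with the standard
genetic code, labelling each variant synonymous / nonsynonymous /
stopgain / UTR / noncoding. Gene-level statistics are one-sided
hypergeometric tests: an excess of long genes (genomic span above a
threshold, default 100 kb) in a foreground list, and per-gene-set
over-representation with Benjamini-Hochberg adjustment across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneModel, ReferenceSequence, complement

EFFECT_SEVERITY = ("stopgain", "nonsynonymous", "synonymous", "UTR", "noncoding")


@dataclass(frozen=True)
class CodingEffect:
    gene_id: str | None
    effect: str
    ref_aa: str | None = None
    alt_aa: str | None = None
    codon_position: int | None = None


def _effect_for_gene(
    pos: int, ref: str, alt: str, gene: GeneModel, reference: ReferenceSequence
) -> CodingEffect:
    offset = gene.cds_offset(pos)
    if offset is None:
        return CodingEffect(gene.gene_id, "UTR")
    cds_seq = gene.cds_sequence(reference)
    codon_index, within = divmod(offset, 3)
    codon = cds_seq[codon_index * 3: codon_index * 3 + 3]
    alt_cds = alt if gene.strand == "+" else complement(alt)
    alt_codon = codon[:within] + alt_cds + codon[within + 1:]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "stopgain"
    else:
        effect = "nonsynonymous"
    return CodingEffect(gene.gene_id, effect, ref_aa, alt_aa, within + 1)


def annotate_effect(
    variant,
    gene_models: Mapping[str, GeneModel] | Iterable[GeneModel],
    reference: ReferenceSequence,
) -> CodingEffect:
    """Coding effect of one SNV against the supplied gene models.

    ``variant`` is anything with chrom/pos/ref_base/alt_base attributes (a
    paired call) or a (chrom, pos, ref, alt) tuple. When several genes
    overlap the site the most severe effect is reported
    (stopgain > nonsynonymous > synonymous > UTR).
    """
    if hasattr(variant, "chrom"):
        chrom, pos, ref, alt = variant.chrom, variant.pos, variant.ref_base, variant.alt_base
    else:
        chrom, pos, ref, alt = variant
    if alt is None:
        raise ValueError("variant has no alternate allele")
    genes = gene_models.values() if isinstance(gene_models, Mapping) else gene_models
    hits = [
        _effect_for_gene(pos, ref, alt, g, reference)
        for g in genes
        if g.chrom == chrom and g.contains(pos)
    ]
    if not hits:
        return CodingEffect(None, "noncoding")
    return min(hits, key=lambda e: EFFECT_SEVERITY.index(e.effect))


@dataclass
class SynNonsynSummary:
    n_coding: int
    n_synonymous: int
    n_nonsynonymous: int  # includes stopgain

    @property
    def fraction_nonsynonymous(self) -> float | None:
        """Nonsynonymous (incl. stopgain) fraction of coding sites; None if no coding sites."""
        return self.n_nonsynonymous / self.n_coding if self.n_coding else None


def syn_nonsyn_summary(effects: Iterable[CodingEffect]) -> SynNonsynSummary:
    n_syn = n_non = 0
    for e in effects:
        if e.effect == "synonymous":
            n_syn += 1
        elif e.effect in ("nonsynonymous", "stopgain"):
            n_non += 1
    return SynNonsynSummary(n_coding=n_syn + n_non, n_synonymous=n_syn, n_nonsynonymous=n_non)


@dataclass
class EnrichmentTest:
    """A hypergeometric over-representation result.

    k of n foreground genes hit, against K of N in the background/universe;
    ``p_value`` is the one-sided upper tail P(X >= k).
    """

    name: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    adj_p: float | None = None


def _hypergeom_upper(k: int, N: int, K: int, n: int) -> float:
    return float(min(hypergeom.sf(k - 1, N, K, n), 1.0))


def long_gene_test(
    fg_genes: Sequence[GeneModel],
    bg_genes: Sequence[GeneModel],
    length_threshold: int = 100_000,
) -> EnrichmentTest:
    """One-sided test for an excess of long genes in the foreground.

    Gene length is genomic span (gene_end - gene_start + 1), not summed
    CDS. The background is the universe the foreground was drawn from.
    """
    k = sum(g.length > length_threshold for g in fg_genes)
    K = sum(g.length > length_threshold for g in bg_genes)
    n, N = len(fg_genes), len(bg_genes)
    if n == 0 or N == 0:
        raise ValueError("empty gene list")
    return EnrichmentTest("long_genes", k, n, K, N, _hypergeom_upper(k, N, K, n))


def overrepresentation(
    fg_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentTest]:
    """Per-set hypergeometric ORA with BH adjustment, sorted by p-value.

    The foreground must be a subset of the universe; each set is
    intersected with the universe before testing.
    """
    fg = set(fg_genes)
    uni = set(universe)
    if not fg <= uni:
        raise ValueError(f"foreground genes outside universe: {sorted(fg - uni)[:5]}")
    results = []
    for name, members in gene_sets.items():
        mem = set(members) & uni
        k = len(fg & mem)
        results.append(EnrichmentTest(name, k, len(fg), len(mem), len(uni),
                                      _hypergeom_upper(k, len(uni), len(mem), len(fg))))
    if results:
        adj = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, a in zip(results, adj):
            r.adj_p = float(a)
    results.sort(key=lambda r: (r.p_value, r.name))
    return results
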