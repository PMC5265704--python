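"""Paired-tissue genotype calling and somatic classification.

At each site both tissues are genotyped from variant allele frequency (VAF)
thresholds, and the pair is classified Somatic / Germline / Reference /
Undetermined. A site is somatic when the two tissues carry different
genotypes and a one-sided Fisher's exact test on the 2x2 ref/variant
read-count table (the "somatic p-value") rejects at the configured level.

Default thresholds: minimum coverage 8 reads, heterozygote VAF >= 0.10,
homozygote VAF >= 0.90, base quality >= 20, mapping quality >= 40, strand
bias <= 90%, somatic p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from math import comb
from pathlib import Path

from scipy.stats import binom

from .io_formats import BASES, SiteCounts


class Genotype(Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    NO_CALL = "no_call"


class CallStatus(Enum):
    REFERENCE = "Reference"
    GERMLINE = "Germline"
    SOMATIC = "Somatic"
    UNDETERMINED = "Undetermined"


@dataclass
class CallingParams:
    """Thresholds governing genotype calling and somatic classification.

    ``hom_ref_error_rate`` parameterizes the error model used by the
    germline confidence test (see :func:`_variant_confident`); it is not a
    calling threshold. ``min_var_reads`` is an optional descriptive gate on
    somatic variant-read support (default 0 = off).
    """

    min_coverage: int = 8
    min_var_freq_het: float = 0.10
    min_hom_freq: float = 0.90
    max_strand_bias: float = 0.90
    min_base_quality: float = 20.0
    min_mapping_quality: float = 40.0
    somatic_p_threshold: float = 0.05
    hom_ref_error_rate: float = 0.01
    min_var_reads: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_var_freq_het < self.min_hom_freq <= 1:
            raise ValueError("require 0 < min_var_freq_het < min_hom_freq <= 1")
        for name in ("min_coverage", "min_base_quality", "min_mapping_quality",
                     "somatic_p_threshold", "max_strand_bias", "min_var_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CallingParams":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


@dataclass
class SiteGenotype:
    genotype: Genotype
    alt_base: str | None
    vaf: float
    depth: int


@dataclass
class PairedCall:
    """Joint call for one site across the tissue pair."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str | None
    site1: SiteCounts
    site2: SiteCounts
    gt1: SiteGenotype
    gt2: SiteGenotype
    status: CallStatus
    somatic_p: float
    filter_flags: set[str] = field(default_factory=set)

    @property
    def key(self) -> tuple[str, int, str | None]:
        return (self.chrom, self.pos, self.alt_base)

    @property
    def kept(self) -> bool:
        return not self.filter_flags


def _best_alt(counts: dict[str, int], ref_base: str) -> tuple[str | None, str | None]:
    """Best- and second-best-supported non-reference alleles (count, then base order)."""
    alts = sorted(
        (b for b in BASES if b != ref_base),
        key=lambda b: (-counts[b], b),
    )
    best = alts[0] if counts[alts[0]] > 0 else None
    second = alts[1] if counts[alts[1]] > 0 else None
    return best, second


def call_genotype(site: SiteCounts, params: CallingParams, alt_base: str | None = None) -> SiteGenotype:
    """Genotype one tissue at one site from VAF thresholds.

    When ``alt_base`` is not given, the non-reference base with the highest
    read count is used. Sites failing the coverage or quality gates yield
    ``no_call``.
    """
    depth = site.depth
    if depth < params.min_coverage or depth == 0:
        return SiteGenotype(Genotype.NO_CALL, None, 0.0, depth)
    if site.mean_mq < params.min_mapping_quality:
        return SiteGenotype(Genotype.NO_CALL, None, 0.0, depth)
    if alt_base is None:
        alt_base, _ = _best_alt({b: site.allele_depth(b) for b in BASES}, site.ref_base)
    var = site.allele_depth(alt_base) if alt_base else 0
    if var > 0 and site.mean_bq[alt_base] < params.min_base_quality:
        return SiteGenotype(Genotype.NO_CALL, None, 0.0, depth)
    vaf = var / depth
    if vaf >= params.min_hom_freq:
        gt = Genotype.HOM_ALT
    elif vaf >= params.min_var_freq_het:
        gt = Genotype.HET
    else:
        gt = Genotype.HOM_REF
    return SiteGenotype(gt, alt_base if var > 0 else None, vaf, depth)


def fisher_somatic_p(counts1: tuple[int, int], counts2: tuple[int, int]) -> float:
    """One-sided Fisher's exact p-value for the 2x2 ref/variant table.

    The tail is taken in the direction of the *second* tissue carrying more
    variant reads: the hypergeometric probability, with margins fixed, of
    tissue 2 holding at least as many variant reads as observed. Computed
    exactly in integer arithmetic.
    """
    r1, v1 = counts1
    r2, v2 = counts2
    if min(r1, v1, r2, v2) < 0:
        raise ValueError("read counts must be non-negative")
    n1, n2 = r1 + v1, r2 + v2
    if n1 + n2 == 0:
        raise ValueError("both tissues have zero depth")
    total = n1 + n2
    var_total = v1 + v2
    denom = comb(total, n2)
    num = sum(
        comb(var_total, k) * comb(total - var_total, n2 - k)
        for k in range(v2, min(var_total, n2) + 1)
    )
    return min(num / denom, 1.0)


def _variant_confident(ref_reads: int, var_reads: int, error_rate: float, alpha: float = 0.05) -> bool:
    """One-sided binomial test of variant support against a hom-ref error model.

    Implements the "confidently called as same genotype (p<0.05)" criterion
    for germline sites: variant presence is confident when the observed
    variant-read count is improbable (p < alpha) under sequencing error
    alone. Kept in one place so the interpretation can be swapped out.
    """
    depth = ref_reads + var_reads
    if depth == 0:
        return False
    p = binom.sf(var_reads - 1, depth, error_rate)
    return bool(p < alpha)


def classify_pair(site1: SiteCounts, site2: SiteCounts, params: CallingParams) -> PairedCall:
    """Classify one site of the tissue pair as Somatic/Germline/Reference/Undetermined.

    The single best-supported alternate allele over the combined pair is
    considered; sites with a second alternate allele above the heterozygote
    VAF threshold (tri-allelic) are Undetermined. The Fisher test is
    oriented one-sided toward the tissue with the higher VAF.
    """
    if (site1.chrom, site1.pos, site1.ref_base) != (site2.chrom, site2.pos, site2.ref_base):
        raise ValueError(
            f"mismatched site pair: {site1.chrom}:{site1.pos}:{site1.ref_base} vs "
            f"{site2.chrom}:{site2.pos}:{site2.ref_base}"
        )
    combined = {b: site1.allele_depth(b) + site2.allele_depth(b) for b in BASES}
    alt, second = _best_alt(combined, site1.ref_base)
    total_depth = site1.depth + site2.depth
    triallelic = (
        second is not None
        and total_depth > 0
        and combined[second] / total_depth >= params.min_var_freq_het
    )

    gt1 = call_genotype(site1, params, alt_base=alt)
    gt2 = call_genotype(site2, params, alt_base=alt)

    if alt is None:
        somatic_p = 1.0
    else:
        c1 = (site1.allele_depth(site1.ref_base), site1.allele_depth(alt))
        c2 = (site2.allele_depth(site2.ref_base), site2.allele_depth(alt))
        # orient so the higher-VAF tissue sits in the tail direction
        somatic_p = fisher_somatic_p(c1, c2) if gt2.vaf >= gt1.vaf else fisher_somatic_p(c2, c1)

    no_call = Genotype.NO_CALL in (gt1.genotype, gt2.genotype)
    if no_call or triallelic:
        status = CallStatus.UNDETERMINED
    elif gt1.genotype != gt2.genotype and somatic_p < params.somatic_p_threshold:
        status = CallStatus.SOMATIC
        if params.min_var_reads > 0:
            var_tissue = site1 if gt1.vaf >= gt2.vaf else site2
            if alt is None or var_tissue.allele_depth(alt) < params.min_var_reads:
                status = CallStatus.UNDETERMINED
    elif gt1.genotype == gt2.genotype == Genotype.HOM_REF:
        status = CallStatus.REFERENCE
    elif gt1.genotype == gt2.genotype:
        confident = alt is not None and all(
            _variant_confident(s.allele_depth(s.ref_base), s.allele_depth(alt), params.hom_ref_error_rate)
            for s in (site1, site2)
        )
        status = CallStatus.GERMLINE if confident else CallStatus.UNDETERMINED
    else:
        status = CallStatus.UNDETERMINED

    return PairedCall(
        chrom=site1.chrom,
        pos=site1.pos,
        ref_base=site1.ref_base,
        alt_base=alt,
        site1=site1,
        site2=site2,
        gt1=gt1,
        gt2=gt2,
        status=status,
        somatic_p=somatic_p,
    )


def somatic_percentage(n_somatic: int, n_total_variant_sites: int) -> float:
    """Somatic variants as a percentage of all sites varying from the reference."""
    if n_total_variant_sites == 0:
        raise ValueError("no variant sites: somatic percentage undefined")
    if not 0 <= n_somatic <= n_total_variant_sites:
        raise ValueError("require 0 <= n_somatic <= n_total_variant_sites")
    return 100.0 * n_somatic / n_total_variant_sites


@dataclass
class ConcordanceSummary:
    n_a: int
    n_b: int
    n_intersection: int
    n_a_only: int
    n_b_only: int
    fraction_a_in_b: float


def compare_callsets(calls_a, calls_b) -> ConcordanceSummary:
    """Caller-agnostic overlap of two call sets keyed by (chrom, pos, alt).

    ``fraction_a_in_b`` is |A n B| / |A| (NaN for an empty A).
    """
    a, b = set(calls_a), set(calls_b)
    inter = a & b
    frac = len(inter) / len(a) if a else float("nan")
    return ConcordanceSummary(
        n_a=len(a),
        n_b=len(b),
        n_intersection=len(inter),
        n_a_only=len(a - b),
        n_b_only=len(b - a),
        fraction_a_in_b=frac,
    )
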