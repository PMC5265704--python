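"""Substitution spectra, somatic-vs-germline enrichment, zygosity and context.

SNVs collapse into six strand-symmetric substitution classes (e.g. G>T and
C>A both belong to G:C>T:A). Spectra are per-pair count/proportion tables
for a somatic or germline call subset; enrichment is the per-class
difference of proportions (positive = somatic-enriched). Zygosity tables
resolve, for one class, which tissue carries the heterozygous variant
allele, using the reporting thresholds (het VAF > 10%, hom-ref VAF < 5%)
that are distinct from the calling thresholds. Sequence-context analyses
cover the base 3' of the mutated G (oxidative-repair bias) and the
mid-CCG motif (shearing-artifact signature).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import ReferenceSequence, complement
from .somatic_calling import PairedCall

SUBSTITUTION_CLASSES = (
    "A:T>G:C",
    "G:C>A:T",
    "G:C>T:A",
    "A:T>T:A",
    "A:T>C:G",
    "G:C>C:G",
)

_CLASS_BY_CHANGE = {
    ("A", "G"): "A:T>G:C", ("T", "C"): "A:T>G:C",
    ("G", "A"): "G:C>A:T", ("C", "T"): "G:C>A:T",
    ("G", "T"): "G:C>T:A", ("C", "A"): "G:C>T:A",
    ("A", "T"): "A:T>T:A", ("T", "A"): "A:T>T:A",
    ("A", "C"): "A:T>C:G", ("T", "G"): "A:T>C:G",
    ("G", "C"): "G:C>C:G", ("C", "G"): "G:C>C:G",
}


def collapse_class(ref_base: str, alt_base: str) -> str:
    """Map an SNV to its strand-symmetric substitution class."""
    if ref_base == alt_base:
        raise ValueError("ref and alt must differ")
    try:
        return _CLASS_BY_CHANGE[(ref_base, alt_base)]
    except KeyError:
        raise ValueError(f"not a DNA substitution: {ref_base}>{alt_base}") from None


@dataclass
class SpectrumTable:
    """Six-class substitution counts/proportions for one call subset."""

    label: str
    pair_id: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        self.counts = {c: int(self.counts.get(c, 0)) for c in SUBSTITUTION_CLASSES}
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative class count")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict[str, float] | None:
        """Per-class proportions, or None (undefined) for an empty subset."""
        t = self.total
        if t == 0:
            return None
        return {c: n / t for c, n in self.counts.items()}


def spectrum(calls: Iterable[PairedCall], label: str, pair_id: str = "pair") -> SpectrumTable:
    """Tally substitution classes over a somatic or germline call subset.

    Calls without an alternate allele are skipped (they carry no
    substitution).
    """
    counts: Counter[str] = Counter()
    for call in calls:
        if call.alt_base is None:
            continue
        counts[collapse_class(call.ref_base, call.alt_base)] += 1
    return SpectrumTable(label=label, pair_id=pair_id, counts=dict(counts))


@dataclass
class EnrichmentResult:
    """Per-class difference somatic proportion - germline proportion.

    Values lie in [-1, 1] and sum to zero across the six classes.
    """

    pair_id: str
    differences: dict[str, float]


def enrichment(somatic: SpectrumTable, germline: SpectrumTable) -> EnrichmentResult:
    ps, pg = somatic.proportions, germline.proportions
    if ps is None or pg is None:
        raise ValueError("enrichment requires non-empty somatic and germline spectra")
    return EnrichmentResult(
        pair_id=somatic.pair_id,
        differences={c: ps[c] - pg[c] for c in SUBSTITUTION_CLASSES},
    )


@dataclass
class ZygosityTable:
    """Which tissue carries the heterozygous variant allele, for one class."""

    sub_class: str
    het_tissue1: int = 0
    het_tissue2: int = 0
    indeterminate: int = 0

    @property
    def determinate(self) -> int:
        return self.het_tissue1 + self.het_tissue2

    @property
    def fraction_het_tissue1(self) -> float | None:
        d = self.determinate
        return self.het_tissue1 / d if d else None


def zygosity_by_tissue(
    calls: Sequence[PairedCall],
    sub_class: str,
    het_threshold: float = 0.10,
    hom_threshold: float = 0.05,
) -> ZygosityTable:
    """Resolve the variant-carrying tissue per site under the reporting rule.

    A tissue is heterozygous when its VAF exceeds ``het_threshold`` and
    homozygous-reference below ``hom_threshold``; VAFs in between are
    indeterminate, as are sites where both or neither tissue reads het.
    Only calls of ``sub_class`` are considered.
    """
    table = ZygosityTable(sub_class=sub_class)
    for call in calls:
        if call.alt_base is None or collapse_class(call.ref_base, call.alt_base) != sub_class:
            continue
        v1, v2 = call.gt1.vaf, call.gt2.vaf
        het1 = v1 > het_threshold
        het2 = v2 > het_threshold
        hom1 = v1 < hom_threshold
        hom2 = v2 < hom_threshold
        if het1 and hom2:
            table.het_tissue1 += 1
        elif het2 and hom1:
            table.het_tissue2 += 1
        else:
            table.indeterminate += 1
    return table


@dataclass
class ContextTally:
    counts: dict[str, int] = field(default_factory=lambda: {b: 0 for b in "ACGT"})
    n_excluded: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def three_prime_context(calls: Iterable[PairedCall], reference: ReferenceSequence) -> ContextTally:
    """Distribution of the base 3' of the mutated G for G:C>T:A events.

    Each event is re-oriented to the strand carrying the mutated G: for a
    genomic G>T the 3' neighbour is read directly; for a C>A the G sits on
    the reverse strand, so the 3' neighbour is the complement of the base
    5' of the C. Sites at the reference edge are excluded with a warning.
    """
    tally = ContextTally()
    for call in calls:
        if call.alt_base is None:
            continue
        if collapse_class(call.ref_base, call.alt_base) != "G:C>T:A":
            continue
        if call.ref_base == "G":
            neighbour_pos = call.pos + 1
            flip = False
        else:  # ref C: mutated G on the reverse strand
            neighbour_pos = call.pos - 1
            flip = True
        if not 1 <= neighbour_pos <= len(reference):
            warnings.warn(f"site {call.chrom}:{call.pos} at reference edge; excluded from 3' context")
            tally.n_excluded += 1
            continue
        base = reference.base(neighbour_pos)
        if flip:
            base = complement(base)
        if base in tally.counts:
            tally.counts[base] += 1
        else:  # N in the reference
            tally.n_excluded += 1
    return tally


@dataclass
class MotifResult:
    n_motif: int
    n_evaluable: int
    n_excluded: int

    @property
    def fraction(self) -> float | None:
        return self.n_motif / self.n_evaluable if self.n_evaluable else None


def ccg_motif_fraction(calls: Iterable[PairedCall], reference: ReferenceSequence) -> MotifResult:
    """Fraction of G:C>T:A events whose mutated C is the middle of a CCG.

    Events are oriented to the pyrimidine (C) strand: a genomic C>A is in
    the motif when its trinucleotide context is C[C]G; a genomic G>T when
    the reverse complement of its context is C[C]G (i.e. genomic C[G]G).
    Edge sites are excluded.
    """
    n_motif = n_eval = n_excl = 0
    for call in calls:
        if call.alt_base is None:
            continue
        if collapse_class(call.ref_base, call.alt_base) != "G:C>T:A":
            continue
        if call.pos <= 1 or call.pos >= len(reference):
            n_excl += 1
            continue
        left = reference.base(call.pos - 1)
        right = reference.base(call.pos + 1)
        n_eval += 1
        if call.ref_base == "C":
            in_motif = left == "C" and right == "G"
        else:  # ref G: C strand is the reverse strand
            c_left = complement(right)
            c_right = complement(left)
            in_motif = c_left == "C" and c_right == "G"
        if in_motif:
            n_motif += 1
    return MotifResult(n_motif=n_motif, n_evaluable=n_eval, n_excluded=n_excl)
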