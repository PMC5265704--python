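# Methods

This note documents the statistical model, the defaults and why they were
chosen, the synthetic-data generator's assumptions, and the numerical and
design choices made where the design was genuinely open.

## Somatic classification model

Each site carries, per tissue, read counts for all four bases split by
strand and read-pair orientation (F1R2/F2R1), plus per-allele mean base
quality and a site mean mapping quality. Genotypes are threshold calls on
the variant allele frequency (VAF) of the single best-supported alternate
allele:

| parameter | default | meaning |
|---|---|---|
| `min_coverage` | 8 reads | below this (or any quality gate) the tissue is `no_call` |
| `min_var_freq_het` | 0.10 | VAF at or above this calls a heterozygote |
| `min_hom_freq` | 0.90 | VAF at or above this calls a homozygote |
| `min_base_quality` | 20 | minimum mean base quality of the variant allele |
| `min_mapping_quality` | 40 | minimum mean mapping quality at the site |
| `somatic_p_threshold` | 0.05 | significance level for the somatic call |
| `max_strand_bias` | 0.90 | maximum fraction of variant reads on one strand |

Threshold edges are closed at the lower bound (VAF exactly 0.10 → het,
exactly 0.90 → hom-alt); the thresholds themselves do not dictate
open/closed edges, so the choice is fixed here and tested.

The somatic p-value is the one-sided Fisher's exact (hypergeometric tail)
probability of the observed 2×2 ref/variant read-count table, taken in the
direction of the tissue with the higher VAF. It is computed exactly in
integer arithmetic (`math.comb`), which keeps the unit tests free to use
`scipy.stats` as an independent cross-check rather than as the
implementation. A pair is:

* **Somatic** — genotypes differ and p < 0.05;
* **Reference** — both hom-ref;
* **Germline** — genotypes equal and non-reference, and variant presence is
  *confident* in both tissues;
* **Undetermined** — anything else, including any `no_call` and tri-allelic
  sites (a second alternate allele at or above the het threshold).

"Confident" germline support is an open design point: it is implemented as
a one-sided exact binomial test of each tissue's variant reads against a
hom-ref sequencing-error model (`hom_ref_error_rate`, default 0.01),
rejecting at 0.05 in both tissues. The interpretation is isolated in one
function (`somatic_calling._variant_confident`) so it can be swapped
without touching classification logic. The error rate is deliberately an
order of magnitude above the simulator's per-read error (10⁻³) so the test
is conservative at 100× depth.

`min_var_reads` (default 0) optionally requires a minimum variant-read
count in the variant-carrying tissue before accepting a somatic call; it is
descriptive in the source analysis and therefore off by default.

## Artifact filters

Three independent, order-independent filters flag rather than delete:

* **strand_bias** — fails when more than `max_strand_bias` of the
  *variant-supporting* reads (not total depth) sit on one strand. Computing
  the fraction on variant reads is a choice: the filter targets
  variant-call artifacts, and total-depth strand balance is uninformative
  for that.
* **orientation_bias** — fails when every variant-supporting read is F1R2,
  or every one is F2R1. This all-or-nothing rule is the oxidative
  (8-oxo-dG) shearing-stress signature; one opposite-orientation read
  rescues the site.
* **identity_region** — fails when the site lies in a masked region
  (regions ≥ 87% identical to another genomic region). Masks are normally
  supplied as BED; `build_identity_mask` constructs one for small
  references by enumerating *every* ungapped offset between non-overlapping
  windows (windowed match sums per shift). That construction is exact and
  deterministic but O(L²), so the pipeline uses the simulator-emitted decoy
  BED instead of rebuilding masks for large genomes.

Read-bias filters are evaluated on the variant-carrying tissue (the one
with the higher VAF), since artifact support lives where the variant reads
are; the choice is configurable by calling the filter primitives directly.

## Spectrum, zygosity and context

SNVs collapse into six strand-symmetric classes (A:T>G:C, G:C>A:T,
G:C>T:A, A:T>T:A, A:T>C:G, G:C>C:G). Spectra are count/proportion tables
per call subset; enrichment is the per-class difference somatic −
germline proportion, which sums to zero by construction (asserted at
1e-12).

Zygosity reporting deliberately uses different thresholds from calling:
het above 10% VAF, hom-ref below 5%, with the [5%, 10%] gap (and sites
where both or neither tissue reads het) counted as indeterminate and
excluded from the reported fraction. The source analysis separates these
reporting thresholds from the calling thresholds; the gap's treatment is
not specified anywhere, so indeterminate-and-excluded is this package's
documented choice.

Context operations orient each G:C>T:A event to a fixed strand: the purine
(G) strand for the 3′-neighbour tally (the base 3′ of the oxidized G
modulates repair efficiency, with 3′-A enhancing G>T), and the pyrimidine
(C) strand for the mid-CCG motif (a shearing-artifact signature). C-strand
events are reverse-complemented accordingly, and both orientations are
pinned by reverse-complement tests. Sites at the reference edge are
excluded (with a warning for the 3′ tally).

## Annotation and enrichment

The codon annotator rebuilds the affected codon in transcription order
(reverse-complemented on minus-strand genes) and translates with the
standard genetic code; stop-loss is reported as nonsynonymous. Variants in
several overlapping genes get the most severe effect
(stopgain > nonsynonymous > synonymous > UTR > noncoding). Correctness is
established against an independent oracle that re-translates the whole
mutated transcript.

Gene-level statistics are one-sided hypergeometric upper tails
(`scipy.stats.hypergeom`), with Benjamini–Hochberg adjustment across gene
sets (`statsmodels`). Gene length is genomic span, not summed CDS, because
the long-gene observation in the neuronal double-strand-break literature
refers to genomic extent; the threshold defaults to 100 kb. Ranked,
permutation-based gene-set enrichment is intentionally replaced by
over-representation analysis: the foreground is an unranked gene list, for
which ORA is the standard equivalent. The background universe is a
required explicit input, since the right universe (all genes vs captured
genes) depends on the experiment.

## Validation rule

"Two-fold difference" is interpreted as the ratio of the larger to the
smaller VAF on the validation platform; a zero VAF in one tissue passes
the fold criterion when the other is positive, and two zeros fail (the
zero case is undefined in the source rule). The ≥ 100-read support is
required in the variant-carrying tissue only (`reads_in_both=True` applies
it to both). Direction consistency — the same tissue carrying the higher
VAF on both platforms — is an explicit conjunct, since accordance between
platforms is defined by that trend. The rule is monotone in read support
and fold difference, and invariant under a consistent tissue swap; both
properties are tested.

## Synthetic-data generator

The simulator works at the pileup level: per-site, per-tissue depth is
Poisson(`mean_depth`, default 100× — the exome depth the analysis
assumes), variant reads are Binomial(depth, VAF), and each remaining read
errs with probability 10⁻³ uniformly to another base. Strand and
orientation are Binomial(0.5) per read — except artifact sites, whose
variant reads carry a single configured orientation. Sequencing errors are
not allowed to mimic the artifact allele at artifact sites, so injected
artifacts are pure single-orientation by construction (that purity is the
definition of the injected artifact class, and the filter's false-negative
behaviour on mixed support is exercised separately by unit fixtures).

Default study conditions:

* germline: `n_germline` sites, class mix 36% A:T>G:C and 38% G:C>A:T
  (remaining classes equal shares), one third homozygous (VAF 0.99),
  heterozygotes at Beta-distributed VAF centred on 0.5 (concentration 40);
  the 2:1 het:hom split is the usual human exome ratio.
* somatic: class mix 87% G:C>T:A; heterozygous in tissue 1 with
  probability 0.85 (the observed range is 70–100%), VAF Beta with mean
  0.35 (concentration 60), reflecting subclonal mosaicism with sub-0.5
  VAFs; the other tissue carries no variant reads beyond sequencing error.
* artifacts: C>A on the C strand, single orientation (F1R2 by default),
  VAF mean 0.30 — high enough that an unfiltered pipeline would call them
  somatic; optionally placed mid-CCG (`artifact_ccg_fraction`).
* a duplicated decoy segment (500 bp at identity 1.0 by default), masked
  in the emitted BED; variants are never injected inside it.
* toy gene models (1–3 CDS exons, both strands, lengths 0.6–3.8 kb) tile
  the genome outside the decoy, and one "guidance-like" gene set is drawn
  from the longest third of genes so length-biased enrichment has signal.

What the simulator does *not* emulate: read-level errors correlated along
reads, alignment and mapping-quality pathology, exome-capture bias, GC
bias, or realistic quality-score distributions (qualities are emitted as
constants above the thresholds; threshold behaviour is tested with
hand-built sites). Passing recovery tests therefore demonstrates the
statistics and filters are implemented correctly under the stated
generative model — not that the pipeline is robust to all real-data
failure modes.

All randomness flows through `numpy.random.default_rng` seeded from the
config; a fixed config yields byte-identical outputs, which the pipeline
manifest (per-stage output checksums and site counts) makes checkable.

## Problem sizes and numerical choices

The test suite and acceptance script run desk-scale versions of the study:
60 kb genomes with 5,000 germline, 200 somatic (VAF 0.4) and 100 artifact
sites for recovery; 10,000 sites for null calibration; margins ≤ 30 for
exhaustive Fisher verification (≈ 2.5 × 10⁵ tables, absolute agreement
better than 1e-9); 1,000 random variants for annotation verification.
Spectrum recovery is judged against binomial 95% confidence intervals at
the injected proportions. The synthetic pipeline config lowers the
long-gene threshold to 2 kb because toy genomes are 10–60 kb; the library
default remains 100 kb.

Known limitations: single alternate allele per site (tri-allelic sites are
set aside as Undetermined); no indels; no joint multi-sample calling; the
identity-mask builder is quadratic and meant for small references; VCF
output is uncompressed and unindexed.
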