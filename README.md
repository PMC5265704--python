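# oxisoma

Paired-tissue somatic single-nucleotide-variant calling and
mutational-spectrum analysis on pileup-level data.

## The problem

Two tissues of the same individual — e.g. a neuron-rich frontal cortex and a
neuron-poor corpus callosum — share a germline genome but can diverge by
*somatic* variants present in only a subset of cells. Detecting those
variants from ~100× exome pileups is dominated by two failure modes: read
evidence that differs between tissues by chance, and sequencing artifacts
that mimic real variants. The hallmark artifact here is oxidative damage to
guanine (8-oxo-dG), which mispairs with adenine and produces G:C>T:A
transversions whose variant reads come from a single read-pair orientation
(F1R2 *or* F2R1).

`oxisoma` implements the complete analysis as a reusable library:

* **Genotyping & somatic classification** — at each site both tissues are
  genotyped from variant allele frequency (VAF = variant reads / depth):
  hom-ref below 0.10, het in [0.10, 0.90), hom-alt at ≥ 0.90, with minimum
  coverage 8, base quality 20 and mapping quality 40. A site is **Somatic**
  when the genotypes differ and the one-sided Fisher's exact *somatic
  p-value* on the 2×2 ref/variant read-count table

  $p = \sum_{k \ge v_2} \frac{\binom{v_1+v_2}{k}\binom{r_1+r_2}{n_2-k}}{\binom{n_1+n_2}{n_2}}$

  (oriented toward the tissue with higher VAF) is below 0.05; **Germline**
  when both tissues confidently share a non-reference genotype.
* **Artifact filters** — strand bias (> 90% of variant reads on one
  strand), orientation bias (all variant reads F1R2, or all F2R1), and an
  identity-region mask (sites in regions ≥ 87% identical to another
  genomic region; BED input or built for small references by exhaustive
  ungapped self-comparison).
* **Spectrum & context** — six strand-symmetric substitution classes,
  somatic-vs-germline enrichment (difference of class proportions),
  tissue-resolved zygosity (reporting rule: het above 10% VAF, hom-ref
  below 5%), the base 3′ of the mutated G, and the mid-CCG artifact motif.
* **Annotation & enrichment** — minimal codon-effect annotation
  (synonymous / nonsynonymous / stopgain) against GFF-lite gene models,
  a long-gene (> 100 kb) excess test, and hypergeometric gene-set
  over-representation with Benjamini–Hochberg adjustment.
* **Amplicon validation rule** — a discovered site is validated when the
  variant allele has ≥ 100 supporting reads, the two tissues' VAFs differ
  ≥ two-fold on the validation platform, and the same tissue carries the
  higher VAF on both platforms.
* **Synthetic data** — a pileup-level simulator with known ground truth
  (germline/somatic/artifact sites, duplicated decoy regions, toy gene
  models) so every stage is testable offline.

## Worked example

Run the whole pipeline on a simulated pair (10 kb genome, 150 germline,
30 somatic and 10 artifact sites at 100× depth):

```sh
cat > example.yaml <<'YAML'
simulate:
  genome_length: 10000
  n_germline: 150
  n_somatic: 30
  n_artifact: 10
  n_genes: 8
YAML
oxisoma run --config example.yaml --seed 1 --out demo/
```

prints

```
stage simulate: ok {'genome_length': 10000, 'n_injected': 190}
stage call: ok {'reference': 9810, 'germline': 150, 'somatic': 40, 'undetermined': 0, 'sites': 10000}
stage filter: ok {'somatic_in': 40, 'somatic_kept': 30, 'somatic_filtered': 10, 'germline_in': 150, 'germline_kept': 150, 'germline_filtered': 0}
stage spectrum: ok {'ccg_motif': 0, 'ccg_evaluable': 28, 'three_prime_A_fraction': 0.39285714285714285, 'somatic_percentage': 16.666666666666668, 'zygosity_fraction_het_tissue1': 0.7142857142857143}
stage annotate: ok {'coding': 4, 'nonsynonymous': 4, 'fraction_nonsynonymous': 1.0, 'long_gene_p': 1.0}
stage validate: skipped {}
```

Reading the counts: 40 raw somatic calls contain the 30 injected somatic
sites plus the 10 injected single-orientation artifacts, and the filter
stage removes exactly the 10 artifacts. The spectrum table
(`demo/spectrum_somatic.tsv`) shows the G:C>T:A-dominated somatic spectrum:

```
sub_class	count	proportion
A:T>G:C	0	0
G:C>A:T	2	0.0666667
G:C>T:A	28	0.933333
...
```

and `demo/zygosity.tsv` resolves which tissue carries the G:C>T:A
heterozygotes (20 of 28 in tissue 1 here, fraction 0.714). Every stage's
outputs and checksums land in `demo/manifest.json`; re-running with the
same config and seed reproduces byte-identical files.

The same stages are available individually (`oxisoma simulate / call /
filter / spectrum / annotate / validate`) over the documented file formats
below.

## File formats

* **Pileup TSV** (columns `chrom pos ref A C G T bq_A bq_C bq_G bq_T mq`):
  one row per site per tissue; each base column holds the comma-joined
  quadruple `fwdF1R2,fwdF2R1,revF1R2,revF2R1`. This dialect exists because
  classic mpileup text cannot represent read-pair orientation.
* **VCF 4.2** output with INFO keys `SOMATIC_P`, `STATUS`, `VAF_T1`,
  `VAF_T2`; filter names appear verbatim in FILTER.
* **BED** for identity masks (0-based half-open); **GFF-lite**
  (`gene_id chrom strand feature start end`, features `gene`/`CDS`,
  1-based inclusive) for gene models; **GMT** for gene sets; a 7-column
  TSV for amplicon validation tables.

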