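# triobench

Simulation and benchmarking toolkit for *de novo* mutation (DNM) calling
from whole-genome-sequenced family trios.

A DNM is a variant present in an offspring but absent from both parents'
germlines. Trio sequencing detects them by comparing the three members'
genotypes, but because sequencing error rates dwarf the germline mutation
rate (~1–1.8 × 10⁻⁸ per base per generation, i.e. tens of true DNMs against
billions of sequenced bases), DNM callers are dominated by false positives
and disagree strongly with one another. Evaluating a caller therefore needs
a trio dataset with a known truth set. `triobench` provides exactly that,
fully synthetic and desk-scale:

- **Trio simulator** — parental genotypes drawn per site under
  Hardy–Weinberg proportions from a population allele-frequency table
  (a bundled U-shaped Beta(0.2, 0.2) spectrum stands in for a real panel);
  offspring genotypes by Mendelian transmission (one allele sampled
  uniformly from each parent); a configurable spike of heterozygous DNMs
  (default 100: 92 SNVs + 8 indels) with the trio pattern
  (father 0/0, mother 0/0, offspring 0/1); truth VCF, PED and a truth
  manifest TSV; a Mendelian-consistency scan that recovers exactly the
  spiked sites.
- **Read simulator** — Illumina-like paired-end reads at configured
  coverage (default 30×, 150 bp) with i.i.d. uniform base errors, emitted
  *pre-aligned at truth coordinates* as sorted, indexed BAMs (CIGARs derived
  from each haplotype's variant set; no aligner runs), plus optional FASTQ.
- **Reference Bayesian trio caller** — per-site genotype likelihoods from
  ref/alt/other pileup counts under a base-error model; a prior over all 27
  trio genotype configurations combining Hardy–Weinberg parental priors
  with Mendelian transmission carrying a per-allele mutation probability μ
  (default 1.2 × 10⁻⁸); the posterior mass on non-Mendelian configurations
  is the DNM score.
- **Evaluation layer** — caller-output adapters (normalized TSV, VCF with
  a score INFO key, prediction CSV), the (0/0, 0/0, 0/1) genotype-pattern
  filter, confusion matrices with F1 = 2·TP/(2·TP + FP + FN), a
  *benchmarking-set maximal-F1 threshold* sweep over each caller's observed
  score range, multi-caller concordance (exact partition of the call union
  into 2ᵏ−1 membership classes), VAF/depth profiles from allelic counts,
  and min–max score normalization for plotting.

## Worked example

One command simulates a 1 Mb trio at 30× with 100 spiked DNMs, calls DNMs
with the built-in Bayesian caller, and evaluates against the truth
manifest:

```bash
triobench demo --seed 7 --outdir demo_run
# truth DNMs: 100  calls: 92  F1@0.5: 0.95288  best F1: 0.95833
```

The caller emitted 92 candidate calls; 91 spiked DNMs score posterior ≥ 0.5
(the 8 spiked indels are outside the SNV scan, so recall tops out at
92/100), with zero false positives. `demo_run/report/report.md` summarizes
performance and the trio VAF profile of the true positives:

| group | n  | offspring VAF mean (sd) | father VAF | mother VAF | offspring depth |
|-------|----|-------------------------|------------|------------|-----------------|
| TP    | 92 | 0.499 (0.098)           | 0.0000     | 0.0004     | 29.7            |

which is the expected signature of a true heterozygous DNM: offspring VAF
centered at 0.5, parental VAFs at or near zero.

The same stages are available separately (`triobench simulate / call /
evaluate / concordance`) and as library functions; external callers'
outputs are evaluated through `load_call_table` adapters.

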