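# Methods

## Germline trio model

Each polymorphic site is bi-allelic with population alternate-allele
frequency *p*. Parental genotypes are drawn independently per site and per
parent under Hardy–Weinberg proportions — 0/0 with (1−p)², 0/1 with
2p(1−p), 1/1 with p² — with no linkage between sites. The offspring
receives one allele drawn uniformly from each parent, independently.
De novo mutations are then spiked into the offspring as heterozygous
variants at positions free of existing variation, so every spiked site has
the trio genotype pattern (father 0/0, mother 0/0, offspring 0/1). A site
is a Mendelian violation iff the offspring genotype cannot be assembled
from one allele of each parent; on truth data the violations are exactly
the spiked sites, which the test suite asserts.

Only autosomes are modelled (ploidy 2 everywhere); multi-allelic sites are
neither generated nor accepted on input; genotypes are unphased throughout.
Missing genotypes ("./.") are representable on input because evaluation
needs them, but truth data never contains them.

### Stand-ins for external resources

The package ships no real genome, population panel or mutation catalogue.

- *Reference*: a uniformly random sequence at 41% GC (human-like),
  default 1 Mb on one synthetic autosome (`chr1`).
- *Allele-frequency spectrum*: Beta(0.2, 0.2) truncated to (0.01, 0.99),
  giving the U shape of a real site-frequency spectrum restricted to
  common polymorphisms. A user TSV (chrom, pos, ref, alt, af) overrides it.
- *DNM catalogue*: spikes are placed uniformly on the reference with a 2:1
  transition:transversion ratio for SNVs and indel lengths uniform on
  1–10 bp (insertions and deletions equally likely), left-anchored in VCF
  style. A user-supplied template list overrides the sampler.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_dnsnv` / `n_dnindel` | 92 / 8 | spiked de novo SNVs / indels (the benchmark's 100-DNM composition) |
| `coverage` | 30× | mean haploid-genome read depth; a 60–66× regime can be configured for platinum-pedigree-like data |
| `read_length` | 150 bp | per-mate read length |
| `fragment_mean` / `fragment_sd` | 350 / 30 bp | Normal fragment-length model, truncated below at `read_length` (typical Illumina PE library) |
| `base_error_rate` | 1e-3 | i.i.d. per-base substitution probability (flat Q30) |
| `reference_length` | 1 Mb | synthetic chromosome size |
| `n_inherited_sites` | 3000 | polymorphic sites drawn from the frequency spectrum; 3 per kb approximates common-SNP density (~1 per 300 bp) |
| `dnm_prior` (μ) | 1.2e-8 | per-allele, per-generation mutation probability in the trio prior; within the accepted human germline range of ~1–1.8e-8 |
| `af_prior_default` | 1e-3 | Hardy–Weinberg prior frequency for sites absent from the frequency table |
| `emission_floor` | 0.01 | minimum posterior for a call to be emitted |
| `min_alt_reads` | 3 | offspring alt-read support required to become a scan candidate |

One master seed drives everything; each stage (parental sampling per
parent, transmission, spiking, reads per member) derives its own labelled
stream, so truth outputs are bit-reproducible and adding a stage never
perturbs another.

## Read simulation

Pair count is round(coverage × genome_length / (2 × read_length)); fragment
starts are uniform on each haplotype and the haplotype of origin is uniform,
so per-site alt-read counts at a heterozygous site are Binomial(depth, ½).
Heterozygous variants are carried on haplotype 1, homozygous-alt variants
on both. Reads are written directly at their truth coordinates with CIGARs
computed from the haplotype-to-reference alignment map (insertions at read
edges become soft clips; deletions at edges are dropped). The error model
is deliberately minimal — uniform substitutions, flat quality, no indel
errors, no quality decay, no GC bias, no duplicates, MAPQ fixed at 60 —
which is sufficient to exercise genotype-likelihood callers but does not
reproduce machine-specific artifact structure: passing tests show the
statistical machinery is correct, not that any caller is robust to real
Illumina noise, mapping ambiguity or somatic/mosaic signal.

Allelic counting classifies reads overlapping a site as ref-supporting,
alt-supporting or other; VAF = alt/(ref+alt+other), defined as 0 at depth 0.
SNVs are counted by base; indel support requires the exact I/D CIGAR event
at the anchored position, and ref support requires spanning the event
footprint plus one base — reads that overlap but do not span are "other".
Other bases count toward depth, never toward alt.

## Bayesian trio caller

Genotype likelihoods use read counts: under a homozygote each read shows
the carried allele with probability 1−ε and any specific other base with
ε/3; a heterozygote is an even per-read mixture of the two homozygote
emissions. All-zero counts yield flat likelihoods flagged no-data. ε
defaults to the simulator's base error rate (floored at 1e-4 so the
error-free configuration stays proper); base-quality-aware likelihoods are
a possible extension, not the default.

The trio prior is Hardy–Weinberg for each parent at the site's population
frequency and Mendelian transmission for the offspring in which each
transmitted allele flips to the other allele with probability μ. The
posterior over the 27 ordered configurations is the normalized product of
prior and the three likelihoods; the DNM score is the posterior mass on
configurations where the offspring carries an allele absent from both
parents (all non-Mendelian configurations — an analogue of the posterior
probability of a de novo configuration reported by likelihood-based trio
callers, not a replica of any one tool's aggregation). With μ = 0 these
configurations have zero prior, so the score is exactly 0; the score is
non-decreasing in offspring alt count, and the implementation matches an
independent enumeration oracle to 1e-9 in the tests.

Whole-region scan mode finds SNV candidates from offspring base counts
(most frequent non-reference base, support ≥ `min_alt_reads`); indels are
evaluated only at user-supplied candidate sites, since indel discovery
from pileups is a different problem from the scoring this caller is meant
to exercise. Indel likelihoods at candidate sites reuse the count model on
alt-supporting vs non-supporting read classes. There is no multi-site
haplotype or phasing logic; comparisons are unphased.

## Evaluation

Calls and truth match on exact (chrom, pos, ref, alt); indel keys are
compared after left-alignment normalization (trimming shared trailing,
then leading, bases). One truth entry yields at most one TP; surplus
passing calls are FPs; precision, recall and F1 use the conventions
P = TP/(TP+FP), R = TP/(TP+FN) (0 when undefined), F1 = 2TP/(2TP+FP+FN).
Thresholding is inclusive (score ≥ τ for higher-is-better scores, ≤ τ for
lower-is-better ones) so the best observed score is always attainable. The
maximal-F1 sweep evaluates every distinct observed score as a threshold
and breaks F1 ties toward the most stringent threshold, minimizing false
positives. The genotype-pattern filter retains exactly
(0/0, 0/0, 0/1) records; any missing genotype removes the record, because
a call whose parents could not be genotyped cannot be verified as de novo.
Concordance partitions the union of keys into all 2ᵏ−1 caller subsets and
reports percentages of the union to 1 decimal place. Score normalization
is min–max to [0, 1] with lower-is-better scales flipped; a degenerate
single-score table maps to 1.0 with a warning.

## Problem sizes and numerical choices

The default configuration — 1 Mb reference, 3000 inherited sites, 100
spiked DNMs, 30× — runs the full simulate-call-evaluate loop in well under
a minute and is the regime the test suite and acceptance script use;
coverage calibration is checked on 100 kb. Posterior arithmetic is done in
log space with a log-sum-exp normalization; spike placement retries
uniformly and aborts with a count of placed variants if the reference is
too crowded; VCF round trips use pysam and BAM emission writes SAM text
sorted and indexed by samtools. The sensitivity of the built-in caller at
30×/ε = 1e-3 for heterozygous dnSNVs exceeds 95% at posterior ≥ 0.5; its
practical limit is parental depth — a parent pileup far below ~17 reads
no longer outweighs the ~2μ de novo prior against an inherited-het
explanation, which is the expected behaviour of this model class, not a
defect.

## Known limitations

No real-data artifacts (mapping error, systematic error motifs, somatic
or mosaic VAF shifts), no sex chromosomes, no structural variants, no LD
between sites, no phasing or parent-of-origin inference, and the built-in
caller is a reference implementation for harness validation rather than a
competitor to production DNM callers.
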