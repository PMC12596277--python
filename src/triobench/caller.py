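"""A built-in Bayesian trio de novo mutation caller.

Per site, bi-allelic genotype likelihoods are computed from ref/alt/other
read counts under a per-base error model; a trio prior combines
Hardy-Weinberg parental priors at the population allele frequency with
Mendelian transmission carrying a small per-allele mutation probability mu
(default 1.2e-8, within the human germline point-mutation-rate range of
roughly 1-1.8e-8 per base per generation). The posterior over all 27
ordered trio genotype configurations yields a de novo probability: the
total mass on configurations in which the offspring carries an allele it
could not have inherited from either parent.

This is a generic trio-posterior model — an analogue of the posterior
probability of a de novo configuration reported by likelihood-based trio
callers, not a clone of any particular tool.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .readsim import base_counts, collect_allelic_counts
from .types import (
    GENOTYPES,
    AllelicCounts,
    DnmCall,
    SimulationConfig,
    canonical_gt,
)

__all__ = [
    "GenotypeLikelihoods",
    "TrioPosterior",
    "genotype_likelihood",
    "trio_posterior",
    "call_dnms",
    "write_calls_vcf",
    "write_call_table",
    "CALLER_NAME",
]

CALLER_NAME = "triobench-bayes"

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

# genotypes indexed 0,1,2 = 0/0, 0/1, 1/1; alt-allele dosage equals the index
_GT_DOSE = np.array([0.0, 1.0, 2.0])


@dataclass(frozen=True)
class GenotypeLikelihoods:
    """Log-likelihoods of the read counts under each bi-allelic genotype."""

    log_likelihoods: tuple[float, float, float]  # order 0/0, 0/1, 1/1
    ml_genotype: str
    no_data: bool = False

    def as_array(self) -> np.ndarray:
        return np.asarray(self.log_likelihoods)


@dataclass(frozen=True)
class TrioPosterior:
    """Posterior over the 27 ordered trio genotype configurations."""

    probabilities: np.ndarray  # shape (3, 3, 3), axes father, mother, offspring
    dnm_probability: float

    @property
    def map_configuration(self) -> tuple[str, str, str]:
        f, m, o = np.unravel_index(int(self.probabilities.argmax()), (3, 3, 3))
        return (GENOTYPES[f], GENOTYPES[m], GENOTYPES[o])


def genotype_likelihood(
    ref_count: int, alt_count: int, other_count: int = 0, epsilon: float = 0.001
) -> GenotypeLikelihoods:
    """Count-based log-likelihoods for genotypes 0/0, 0/1, 1/1.

    Each read independently shows a specific base: under a homozygote the
    carried allele appears with probability 1-eps and any specific other
    base with eps/3; under a heterozygote each read is an even mixture of
    the two homozygote emissions. All-zero counts give flat likelihoods
    flagged as no-data.
    """
    if min(ref_count, alt_count, other_count) < 0:
        raise ValueError("read counts must be non-negative")
    if not (0.0 < epsilon < 0.5):
        raise ValueError(f"epsilon must be in (0, 0.5), got {epsilon}")
    depth = ref_count + alt_count + other_count
    if depth == 0:
        return GenotypeLikelihoods((0.0, 0.0, 0.0), GENOTYPES[0], no_data=True)
    log_hit = np.log1p(-epsilon)  # emitted base == carried allele
    log_miss = np.log(epsilon / 3.0)  # any one specific non-carried base
    log_half = np.log(0.5 * np.exp(log_hit) + 0.5 * np.exp(log_miss))
    ll = (
        ref_count * log_hit + alt_count * log_miss + other_count * log_miss,
        ref_count * log_half + alt_count * log_half + other_count * log_miss,
        ref_count * log_miss + alt_count * log_hit + other_count * log_miss,
    )
    ml = GENOTYPES[int(np.argmax(ll))]
    return GenotypeLikelihoods(tuple(float(x) for x in ll), ml)


def _transmission_matrix(mu: float) -> np.ndarray:
    """t[g, a]: probability a parent with genotype g transmits allele a.

    The drawn allele mutates to the other allele with probability mu
    (bi-allelic model), so t[g, 1] = dose/2 * (1-mu) + (1 - dose/2) * mu.
    """
    base = _GT_DOSE / 2.0
    t_alt = base * (1.0 - mu) + (1.0 - base) * mu
    return np.column_stack([1.0 - t_alt, t_alt])


def _offspring_given_parents(mu: float) -> np.ndarray:
    """P[gf, gm, gc]: offspring genotype given parental genotypes."""
    t = _transmission_matrix(mu)
    out = np.zeros((3, 3, 3))
    for gf in range(3):
        for gm in range(3):
            for a in (0, 1):
                for b in (0, 1):
                    out[gf, gm, a + b] += t[gf, a] * t[gm, b]
    return out


# Mendelian-violation mask over ordered (father, mother, offspring) configs:
# the offspring carries an allele absent from both parents.
def _violation_mask() -> np.ndarray:
    mask = np.zeros((3, 3, 3), dtype=bool)
    alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    for gf in range(3):
        for gm in range(3):
            for gc in range(3):
                target = tuple(sorted(alleles[gc]))
                ok = any(
                    tuple(sorted((a, b))) == target
                    for a in alleles[gf]
                    for b in alleles[gm]
                )
                mask[gf, gm, gc] = not ok
    return mask


_VIOLATION = _violation_mask()


def trio_posterior(
    gl_father: GenotypeLikelihoods,
    gl_mother: GenotypeLikelihoods,
    gl_offspring: GenotypeLikelihoods,
    af_prior: float,
    mu: float,
) -> TrioPosterior:
    """Posterior over the 27 trio genotype configurations.

    Prior: Hardy-Weinberg for each parent at population frequency af_prior;
    offspring conditional on parents via Mendelian transmission with
    per-allele mutation probability mu. Posterior is proportional to prior
    times the product of the three members' likelihoods. dnm_probability is
    the mass on configurations where the offspring genotype cannot be
    formed from one allele of each parent (with mu = 0 these configurations
    have zero prior, so the probability is exactly 0).
    """
    if not (0.0 <= mu < 1.0):
        raise ValueError(f"mu must be in [0, 1), got {mu}")
    if not (0.0 <= af_prior <= 1.0):
        raise ValueError(f"af_prior must be in [0, 1], got {af_prior}")
    for gl in (gl_father, gl_mother, gl_offspring):
        if not np.all(np.isfinite(gl.as_array())):
            raise ValueError("non-finite genotype likelihood")
    p = af_prior
    hw = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    prior = hw[:, None, None] * hw[None, :, None] * _offspring_given_parents(mu)
    with np.errstate(divide="ignore"):
        log_joint = (
            np.log(prior)
            + gl_father.as_array()[:, None, None]
            + gl_mother.as_array()[None, :, None]
            + gl_offspring.as_array()[None, None, :]
        )
    log_norm = logsumexp(log_joint)
    post = np.exp(log_joint - log_norm)
    dnm_p = float(post[_VIOLATION].sum())
    return TrioPosterior(post, min(max(dnm_p, 0.0), 1.0))


def _scan_candidates(
    bam_path: str | os.PathLike,
    reference: dict[str, str],
    min_alt_reads: int,
) -> list[tuple[str, int, str, str]]:
    """SNV candidate sites: offspring positions with alt-base support.

    The most frequent non-reference base is taken as the alternate allele.
    (Indels are only evaluated at user-supplied candidate sites.)
    """
    candidates: list[tuple[str, int, str, str]] = []
    for chrom in sorted(reference):
        seq = reference[chrom]
        cov = base_counts(bam_path, chrom, 0, len(seq))  # 4 x L
        ref_idx = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        lut = np.full(256, -1, dtype=np.int8)
        for b, i in _BASE_INDEX.items():
            lut[ord(b)] = i
        ref_rows = lut[ref_idx]
        cov_masked = cov.copy()
        valid = ref_rows >= 0
        cols = np.arange(cov.shape[1])
        cov_masked[ref_rows[valid], cols[valid]] = 0
        alt_best = cov_masked.argmax(axis=0)
        alt_count = cov_masked.max(axis=0)
        hits = np.nonzero((alt_count >= min_alt_reads) & valid)[0]
        bases = "ACGT"
        for j in hits.tolist():
            candidates.append((chrom, j + 1, seq[j], bases[int(alt_best[j])]))
    return candidates


def call_dnms(
    bam_father: str | os.PathLike,
    bam_mother: str | os.PathLike,
    bam_offspring: str | os.PathLike,
    reference: dict[str, str],
    config: SimulationConfig | None = None,
    candidate_sites: list[tuple[str, int, str, str]] | None = None,
    af_table: dict[tuple[str, int, str, str], float] | None = None,
) -> list[DnmCall]:
    """Call de novo mutations from three indexed BAMs.

    Without candidate sites the offspring BAM is scanned for SNV candidates;
    each candidate's trio pileup is turned into genotype likelihoods and a
    trio posterior, and a DnmCall is emitted for every site whose de novo
    probability exceeds the emission floor. Scores are posterior
    probabilities (higher is better). A population frequency table supplies
    the Hardy-Weinberg prior at known sites; unknown sites use the default.
    """
    config = config or SimulationConfig()
    config.validate()
    if candidate_sites is None:
        candidate_sites = _scan_candidates(bam_offspring, reference, config.min_alt_reads)
    eps = max(config.base_error_rate, 1e-4)  # likelihoods need eps > 0
    calls: list[DnmCall] = []
    counts_f = collect_allelic_counts(bam_father, candidate_sites)
    counts_m = collect_allelic_counts(bam_mother, candidate_sites)
    counts_o = collect_allelic_counts(bam_offspring, candidate_sites)
    for site, cf, cm, co in zip(candidate_sites, counts_f, counts_m, counts_o):
        chrom, pos, ref, alt = site
        gl_f = genotype_likelihood(cf.ref_count, cf.alt_count, cf.other_count, eps)
        gl_m = genotype_likelihood(cm.ref_count, cm.alt_count, cm.other_count, eps)
        gl_o = genotype_likelihood(co.ref_count, co.alt_count, co.other_count, eps)
        af = config.af_prior_default
        if af_table is not None:
            af = af_table.get(site, config.af_prior_default)
        post = trio_posterior(gl_f, gl_m, gl_o, af, config.dnm_prior)
        if post.dnm_probability >= config.emission_floor:
            calls.append(
                DnmCall(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gt_father=gl_f.ml_genotype,
                    gt_mother=gl_m.ml_genotype,
                    gt_offspring=gl_o.ml_genotype,
                    score=post.dnm_probability,
                    score_orientation="higher_is_better",
                    caller_name=CALLER_NAME,
                )
            )
    calls.sort(key=lambda c: (c.chrom, c.pos))
    return calls


def write_calls_vcf(
    calls: list[DnmCall], contigs: dict[str, int], path: str | os.PathLike
) -> None:
    """Write calls as VCF 4.2 with the posterior in INFO/DNMP."""
    import pysam

    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("DNMP", 1, "Float", "Posterior probability of a de novo mutation")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in ("FATHER", "MOTHER", "OFFSPRING"):
        header.add_sample(s)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as vcf:
        for c in calls:
            rec = vcf.new_record(
                contig=c.chrom,
                start=c.pos - 1,
                stop=c.pos - 1 + len(c.ref),
                alleles=(c.ref, c.alt),
            )
            rec.info["DNMP"] = float(c.score)
            for sample, gt in zip(
                ("FATHER", "MOTHER", "OFFSPRING"), (c.gt_father, c.gt_mother, c.gt_offspring)
            ):
                a, b = gt.split("/")
                rec.samples[sample]["GT"] = (
                    (None, None) if a == "." else (int(a), int(b))
                )
            vcf.write(rec)


def write_call_table(calls: list[DnmCall], path: str | os.PathLike) -> None:
    """Normalized call-table TSV, the evaluation layer's interchange format."""
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "caller": c.caller_name,
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "gt_father": c.gt_father,
                "gt_mother": c.gt_mother,
                "gt_offspring": c.gt_offspring,
                "score": c.score,
                "orientation": c.score_orientation,
            }
            for c in calls
        ],
        columns=[
            "caller", "chrom", "pos", "ref", "alt",
            "gt_father", "gt_mother", "gt_offspring", "score", "orientation",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
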