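"""Germline genotype simulation for a mother-father-offspring trio.

Parental genotypes are drawn per site under Hardy-Weinberg proportions from
a population allele-frequency table; the offspring inherits one allele from
each parent (Mendelian transmission); de novo mutations are then spiked
into the offspring as heterozygous variants absent from both parents, and
recorded in a truth manifest. A Mendelian-consistency scan recovers exactly
the spiked sites on truth data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeding import stage_rng
from .types import (
    GENOTYPES,
    HET,
    HOM_REF,
    AlleleFrequencyEntry,
    SimulationConfig,
    TrioSite,
    TruthVariant,
    canonical_gt,
    gt_alleles,
)
from .frequencies import validate_frequency_table

__all__ = [
    "sample_parental_genotypes",
    "merge_parental_sites",
    "transmit_offspring_genotype",
    "transmit_all",
    "spike_dnms",
    "check_mendelian_consistency",
    "is_mendelian_consistent",
    "simulate_trio_sites",
]

_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}  # transition partners


def _hw_probs(p: float) -> tuple[float, float, float]:
    q = 1.0 - p
    return (q * q, 2.0 * p * q, p * p)


def sample_parental_genotypes(
    afs: list[AlleleFrequencyEntry], seed: int
) -> tuple[list[tuple[AlleleFrequencyEntry, str]], list[tuple[AlleleFrequencyEntry, str]]]:
    """Draw each parent's genotype at every site under Hardy-Weinberg.

    At population frequency p the genotype is 0/0 with (1-p)^2, 0/1 with
    2p(1-p) and 1/1 with p^2, independently per parent and per site.
    Returns complete per-site lists (including 0/0 draws) for father and
    mother, deterministic for a given seed.
    """
    validate_frequency_table(afs)
    out: list[list[tuple[AlleleFrequencyEntry, str]]] = []
    for member in ("father", "mother"):
        rng = stage_rng(seed, f"parental-genotypes:{member}")
        p = np.array([e.af for e in afs])
        probs = np.column_stack([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        u = rng.random(len(afs))
        idx = (u[:, None] >= probs.cumsum(axis=1)).sum(axis=1)
        out.append([(e, GENOTYPES[i]) for e, i in zip(afs, idx.tolist())])
    return out[0], out[1]


def merge_parental_sites(
    father_sites: list[tuple[AlleleFrequencyEntry, str]],
    mother_sites: list[tuple[AlleleFrequencyEntry, str]],
) -> list[TrioSite]:
    """Union both parents' sites into one sorted list of TrioSite.

    A parent absent at a site is homozygous reference there. Conflicting
    ref alleles at one position are an error; two different alt alleles at
    one position would make the site multi-allelic and are rejected.
    """
    merged: dict[tuple[str, int], TrioSite] = {}
    for sites, attr in ((father_sites, "gt_father"), (mother_sites, "gt_mother")):
        for entry, gt in sites:
            k = (entry.chrom, entry.pos)
            site = merged.get(k)
            if site is None:
                site = TrioSite(entry.chrom, entry.pos, entry.ref, entry.alt)
                merged[k] = site
            else:
                if site.ref != entry.ref:
                    raise ValueError(
                        f"conflicting ref alleles at {entry.chrom}:{entry.pos}: "
                        f"{site.ref!r} vs {entry.ref!r}"
                    )
                if site.alt != entry.alt:
                    raise ValueError(
                        f"multi-allelic merge at {entry.chrom}:{entry.pos}: "
                        f"{site.alt!r} vs {entry.alt!r}"
                    )
            setattr(site, attr, gt)
    return sorted(merged.values(), key=lambda s: (s.chrom, s.pos))


def transmit_offspring_genotype(
    gt_father: str, gt_mother: str, rng: np.random.Generator
) -> str:
    """Draw the offspring genotype: one allele uniformly from each parent."""
    fa = gt_alleles(gt_father)
    ma = gt_alleles(gt_mother)
    if fa is None or ma is None:
        raise ValueError("cannot transmit from a missing parental genotype")
    a = fa[int(rng.integers(2))]
    b = ma[int(rng.integers(2))]
    return canonical_gt(a, b)


def transmit_all(sites: list[TrioSite], seed: int) -> list[TrioSite]:
    """Fill gt_offspring at every site by Mendelian transmission (in place)."""
    rng = stage_rng(seed, "transmission")
    for site in sites:
        site.gt_offspring = transmit_offspring_genotype(site.gt_father, site.gt_mother, rng)
    return sites


@dataclass
class _SpikePlacer:
    """Collision-free position bookkeeping for spiked variants."""

    occupied: set[tuple[str, int]]

    def free(self, chrom: str, start: int, end: int) -> bool:
        return all((chrom, p) not in self.occupied for p in range(start, end + 1))

    def take(self, chrom: str, start: int, end: int) -> None:
        for p in range(start, end + 1):
            self.occupied.add((chrom, p))


def spike_dnms(
    offspring_sites: list[TrioSite],
    reference: dict[str, str],
    config: SimulationConfig,
    dnm_catalog: list[TruthVariant] | None = None,
    max_indel_length: int = 10,
    ts_tv_ratio: float = 2.0,
) -> tuple[list[TrioSite], list[TruthVariant]]:
    """Add de novo mutations to the offspring and return the truth manifest.

    Every spiked record is heterozygous in the offspring with both parents
    homozygous reference. Without a catalog, positions are uniform on the
    reference, SNVs follow a 2:1 transition:transversion ratio and indel
    lengths are uniform on 1..max_indel_length (insertions and deletions
    equally likely), all left-anchored in VCF style. Spikes never collide
    with existing polymorphic sites or with each other.
    """
    config.validate()
    rng = stage_rng(config.seed, "spike-dnms")
    n_total = config.n_dnsnv + config.n_dnindel
    if n_total == 0:
        return list(offspring_sites), []

    placer = _SpikePlacer({(s.chrom, p) for s in offspring_sites
                           for p in range(s.pos, s.pos + len(s.ref))})
    manifest: list[TruthVariant] = []

    if dnm_catalog is not None:
        chosen = list(dnm_catalog)
        if len(chosen) < n_total:
            raise ValueError(
                f"catalog holds {len(chosen)} templates, {n_total} spikes requested"
            )
        idx = rng.choice(len(chosen), size=n_total, replace=False)
        for i in idx.tolist():
            t = chosen[i]
            end = t.pos + len(t.ref) - 1
            if not placer.free(t.chrom, t.pos, end):
                raise ValueError(f"catalog variant collides at {t.chrom}:{t.pos}")
            placer.take(t.chrom, t.pos, end)
            manifest.append(
                TruthVariant(t.chrom, t.pos, t.ref, t.alt, t.vtype, "de_novo",
                             HOM_REF, HOM_REF, HET)
            )
    else:
        chroms = sorted(reference)
        lengths = np.array([len(reference[c]) for c in chroms], dtype=float)
        todo = ["SNV"] * config.n_dnsnv + ["INDEL"] * config.n_dnindel
        p_ts = ts_tv_ratio / (ts_tv_ratio + 1.0)
        max_attempts = 50 * n_total + 1000
        attempts = 0
        for vtype in todo:
            placed = False
            while not placed:
                attempts += 1
                if attempts > max_attempts:
                    raise ValueError(
                        f"could not place all spikes without collision: "
                        f"{len(manifest)} of {n_total} placed"
                    )
                ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
                chrom, seq = chroms[ci], reference[chroms[ci]]
                if vtype == "SNV":
                    pos = int(rng.integers(1, len(seq) + 1))
                    if not placer.free(chrom, pos, pos):
                        continue
                    ref = seq[pos - 1]
                    if rng.random() < p_ts:
                        alt = _TS_PARTNER[ref]
                    else:
                        tv = [b for b in "ACGT" if b != ref and b != _TS_PARTNER[ref]]
                        alt = tv[int(rng.integers(2))]
                    var = TruthVariant(chrom, pos, ref, alt, "SNV", "de_novo",
                                       HOM_REF, HOM_REF, HET)
                    span_end = pos
                else:
                    ln = int(rng.integers(1, max_indel_length + 1))
                    is_ins = bool(rng.integers(2))
                    # anchor needs pos >= 2 and, for deletions, span inside reference
                    hi = len(seq) - (0 if is_ins else ln)
                    if hi < 2:
                        continue
                    pos = int(rng.integers(2, hi + 1))
                    anchor = seq[pos - 1]
                    if is_ins:
                        ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=ln))
                        ref, alt = anchor, anchor + ins
                        span_end = pos
                        vt = "INS"
                    else:
                        ref, alt = seq[pos - 1 : pos + ln], anchor
                        span_end = pos + ln
                        vt = "DEL"
                    if not placer.free(chrom, pos, span_end):
                        continue
                    var = TruthVariant(chrom, pos, ref, alt, vt, "de_novo",
                                       HOM_REF, HOM_REF, HET)
                placer.take(chrom, var.pos, span_end)
                manifest.append(var)
                placed = True

    spiked = list(offspring_sites) + [
        TrioSite(v.chrom, v.pos, v.ref, v.alt, HOM_REF, HOM_REF, HET) for v in manifest
    ]
    spiked.sort(key=lambda s: (s.chrom, s.pos))
    manifest.sort(key=lambda v: (v.chrom, v.pos))
    return spiked, manifest


def is_mendelian_consistent(gt_father: str, gt_mother: str, gt_offspring: str) -> bool:
    """True iff the offspring genotype can take one allele from each parent."""
    fa, ma, oa = gt_alleles(gt_father), gt_alleles(gt_mother), gt_alleles(gt_offspring)
    if fa is None or ma is None or oa is None:
        raise ValueError("missing genotype: consistency undefined")
    target = tuple(sorted(oa))
    return any(tuple(sorted((a, b))) == target for a in fa for b in ma)


def check_mendelian_consistency(trio_sites: list[TrioSite]) -> list[TrioSite]:
    """Return the sites whose trio genotypes violate Mendelian transmission."""
    return [
        s
        for s in trio_sites
        if not is_mendelian_consistent(s.gt_father, s.gt_mother, s.gt_offspring)
    ]


def simulate_trio_sites(
    afs: list[AlleleFrequencyEntry],
    reference: dict[str, str],
    config: SimulationConfig,
    dnm_catalog: list[TruthVariant] | None = None,
) -> tuple[list[TrioSite], list[TruthVariant]]:
    """Full germline stage: parents -> merge -> transmission -> spike."""
    father, mother = sample_parental_genotypes(afs, config.seed)
    merged = merge_parental_sites(
        [(e, g) for e, g in father if g != HOM_REF],
        [(e, g) for e, g in mother if g != HOM_REF],
    )
    transmit_all(merged, config.seed)
    return spike_dnms(merged, reference, config, dnm_catalog)
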