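"""Shared domain types for the trio simulator, caller and evaluation layers.

Genotypes are kept as canonical unphased strings ("0/0", "0/1", "1/1",
missing "./.") throughout: they round-trip VCF unchanged and the whole
benchmark is bi-allelic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "MISSING",
    "GENOTYPES",
    "gt_alleles",
    "canonical_gt",
    "AlleleFrequencyEntry",
    "TruthVariant",
    "TrioSite",
    "AllelicCounts",
    "DnmCall",
    "SimulationConfig",
]

HOM_REF = "0/0"
HET = "0/1"
HOM_ALT = "1/1"
MISSING = "./."
GENOTYPES = (HOM_REF, HET, HOM_ALT)

_ALLELES = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1)}


def gt_alleles(gt: str) -> Optional[tuple[int, int]]:
    """Allele pair of a canonical genotype string; None for missing."""
    if gt == MISSING:
        return None
    try:
        return _ALLELES[gt]
    except KeyError:
        raise ValueError(f"not a canonical bi-allelic genotype: {gt!r}") from None


def canonical_gt(allele_a: int, allele_b: int) -> str:
    """Unphased canonical string with the smaller allele first."""
    a, b = sorted((allele_a, allele_b))
    if not (0 <= a <= 1 and 0 <= b <= 1):
        raise ValueError(f"alleles must be 0 or 1, got ({allele_a}, {allele_b})")
    return f"{a}/{b}"


@dataclass(frozen=True)
class AlleleFrequencyEntry:
    """One bi-allelic site with its population alternate-allele frequency p."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    af: float

    def validate(self) -> None:
        if not (0.0 <= self.af <= 1.0):
            raise ValueError(f"af outside [0,1] at {self.chrom}:{self.pos}: {self.af}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or set(allele) - set("ACGT"):
                raise ValueError(
                    f"allele not an uppercase ACGT string at {self.chrom}:{self.pos}: {allele!r}"
                )


@dataclass(frozen=True)
class TruthVariant:
    """A simulated variant with known trio genotypes.

    De novo entries always carry the (father 0/0, mother 0/0, offspring 0/1)
    pattern: spiked mutations are heterozygous in the offspring and absent
    from both parental germlines.
    """

    chrom: str
    pos: int  # 1-based; indels carry a shared left anchor base
    ref: str
    alt: str
    vtype: str  # SNV | INS | DEL
    origin: str  # inherited | de_novo
    gt_father: str
    gt_mother: str
    gt_offspring: str

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def validate(self) -> None:
        if self.vtype not in ("SNV", "INS", "DEL"):
            raise ValueError(f"bad vtype {self.vtype!r}")
        if self.origin not in ("inherited", "de_novo"):
            raise ValueError(f"bad origin {self.origin!r}")
        if self.vtype == "SNV" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError(f"SNV with non-1bp alleles at {self.chrom}:{self.pos}")
        if self.origin == "de_novo" and (
            self.gt_father != HOM_REF or self.gt_mother != HOM_REF or self.gt_offspring != HET
        ):
            raise ValueError(
                f"de novo variant at {self.chrom}:{self.pos} must be (0/0, 0/0, 0/1), got "
                f"({self.gt_father}, {self.gt_mother}, {self.gt_offspring})"
            )


@dataclass
class TrioSite:
    """One genomic site with the three members' genotypes."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gt_father: str = HOM_REF
    gt_mother: str = HOM_REF
    gt_offspring: str = MISSING

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def with_gt(self, **kwargs) -> "TrioSite":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class AllelicCounts:
    """Read support at one site, split into ref / alt / other classes."""

    chrom: str
    pos: int  # 1-based
    ref_count: int
    alt_count: int
    other_count: int

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count + self.other_count

    @property
    def vaf(self) -> float:
        """Variant allele fraction alt/depth; 0 by convention at depth 0."""
        return self.alt_count / self.depth if self.depth else 0.0


@dataclass(frozen=True)
class DnmCall:
    """One putative de novo mutation as reported by some caller."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gt_father: str
    gt_mother: str
    gt_offspring: str
    score: float
    score_orientation: str = "higher_is_better"
    caller_name: str = "unknown"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SimulationConfig:
    """All generator knobs for one simulated trio.

    Defaults reproduce the benchmark regime: a 100-DNM spike split 92 SNVs /
    8 indels, 30x paired-end coverage, 150 bp reads, flat Q30 base errors
    (rate 1e-3), on a 1 Mb synthetic autosome.
    """

    seed: int = 1
    n_dnsnv: int = 92
    n_dnindel: int = 8
    coverage: float = 30.0
    read_length: int = 150
    fragment_mean: float = 350.0
    fragment_sd: float = 30.0
    base_error_rate: float = 0.001
    reference_length: int = 1_000_000
    n_inherited_sites: int = 3000
    chrom: str = "chr1"
    # caller knobs
    dnm_prior: float = 1.2e-8  # per-allele per-generation mutation prior mu
    af_prior_default: float = 0.001  # HW prior at sites absent from the frequency table
    emission_floor: float = 0.01  # minimum posterior for a call to be emitted
    min_alt_reads: int = 3  # scan-mode candidate floor (offspring alt support)

    def validate(self) -> None:
        if self.n_dnsnv < 0 or self.n_dnindel < 0 or self.n_inherited_sites < 0:
            raise ValueError("counts must be non-negative")
        if not (0.0 <= self.base_error_rate < 0.5):
            raise ValueError(f"base_error_rate must be in [0, 0.5), got {self.base_error_rate}")
        if self.coverage < 0:
            raise ValueError("coverage must be non-negative")
        if self.read_length <= 0 or self.reference_length <= 0:
            raise ValueError("read_length and reference_length must be positive")
        if not (0.0 <= self.dnm_prior < 1.0):
            raise ValueError("dnm_prior must be in [0, 1)")
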