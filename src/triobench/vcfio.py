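"""VCF / PED / truth-manifest input and output.

Trio VCFs are VCF 4.2 with a GT field per sample in fixed column order
father, mother, offspring; reading and writing round-trip genotypes
exactly. The truth manifest is a headered TSV.
"""

from __future__ import annotations

import os

import pandas as pd
import pysam

from .types import MISSING, TrioSite, TruthVariant, canonical_gt

__all__ = [
    "TRIO_SAMPLES",
    "write_trio_vcf",
    "read_trio_vcf",
    "write_ped",
    "write_truth_manifest",
    "read_truth_manifest",
]

TRIO_SAMPLES = ("FATHER", "MOTHER", "OFFSPRING")

_MANIFEST_COLUMNS = [
    "chrom", "pos", "ref", "alt", "vtype", "origin",
    "gt_father", "gt_mother", "gt_offspring",
]


def _gt_tuple(gt: str) -> tuple:
    if gt == MISSING:
        return (None, None)
    a, b = gt.split("/")
    return (int(a), int(b))


def _gt_string(gt_tuple) -> str:
    if gt_tuple is None or any(a is None for a in gt_tuple):
        return MISSING
    return canonical_gt(*gt_tuple)


def write_trio_vcf(
    sites: list[TrioSite],
    contigs: dict[str, int],
    path: str | os.PathLike,
    samples: tuple[str, str, str] = TRIO_SAMPLES,
) -> None:
    """Write sorted sites as a three-sample VCF 4.2 (father, mother, offspring)."""
    keys = [(s.chrom, s.pos) for s in sites]
    if keys != sorted(keys):
        raise ValueError("sites must be sorted by (chrom, pos) before writing")
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as vcf:
        for site in sites:
            rec = vcf.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos - 1 + len(site.ref),
                alleles=(site.ref, site.alt),
            )
            for sample, gt in zip(
                samples, (site.gt_father, site.gt_mother, site.gt_offspring)
            ):
                rec.samples[sample]["GT"] = _gt_tuple(gt)
                rec.samples[sample].phased = False
            vcf.write(rec)


def read_trio_vcf(
    path: str | os.PathLike, samples: tuple[str, str, str] | None = None
) -> list[TrioSite]:
    """Read a three-sample VCF back into TrioSite records (bi-allelic only)."""
    sites: list[TrioSite] = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        names = samples or tuple(vcf.header.samples)
        if len(names) != 3:
            raise ValueError(f"expected a trio VCF with 3 samples, found {len(names)}")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"multi-allelic or ALT-less record at {rec.chrom}:{rec.pos} not supported"
                )
            gts = [_gt_string(rec.samples[n].get("GT")) for n in names]
            sites.append(
                TrioSite(rec.chrom, rec.pos, rec.ref, rec.alts[0], gts[0], gts[1], gts[2])
            )
    return sites


def write_ped(
    path: str | os.PathLike,
    family_id: str = "FAM1",
    samples: tuple[str, str, str] = TRIO_SAMPLES,
    offspring_sex: int = 2,
) -> None:
    """Six-column PED for one trio; offspring sex configurable (1 male, 2 female)."""
    father, mother, offspring = samples
    rows = [
        (family_id, father, "0", "0", 1, 1),
        (family_id, mother, "0", "0", 2, 1),
        (family_id, offspring, father, mother, offspring_sex, 2),
    ]
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_truth_manifest(manifest: list[TruthVariant], path: str | os.PathLike) -> None:
    df = pd.DataFrame([vars(v) for v in manifest], columns=_MANIFEST_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_truth_manifest(path: str | os.PathLike) -> list[TruthVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"truth manifest missing columns: {sorted(missing)}")
    out = [
        TruthVariant(
            str(r.chrom), int(r.pos), str(r.ref), str(r.alt), str(r.vtype),
            str(r.origin), str(r.gt_father), str(r.gt_mother), str(r.gt_offspring),
        )
        for r in df.itertuples()
    ]
    for v in out:
        v.validate()
    return out
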