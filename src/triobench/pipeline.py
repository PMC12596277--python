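"""End-to-end orchestration: simulate a trio, call DNMs, evaluate.

Every stage derives its random stream from the one master seed in the
configuration, so a re-run with the same config reproduces byte-identical
truth outputs. A RunManifest records the config snapshot, per-stage output
paths and checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time

from . import __version__
from .caller import CALLER_NAME, call_dnms, write_call_table, write_calls_vcf
from .evaluate import (
    CallTable,
    concordance_percentages,
    genotype_pattern_filter,
    load_call_table,
    maximal_f1_sweep,
    score_calls,
    vaf_depth_profile,
    write_report,
)
from .frequencies import read_frequency_table, sample_frequency_table, write_frequency_table
from .readsim import build_diploid_genome, collect_allelic_counts, emit_bam, simulate_reads
from .reference import read_fasta, synthesize_reference, write_fasta
from .trio import check_mendelian_consistency, simulate_trio_sites
from .types import SimulationConfig
from .vcfio import (
    TRIO_SAMPLES,
    write_ped,
    write_trio_vcf,
    write_truth_manifest,
)

__all__ = ["RunManifest", "simulate_trio", "run_end_to_end"]

logger = logging.getLogger(__name__)

MEMBERS = ("father", "mother", "offspring")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record for one end-to-end run."""

    config: dict
    master_seed: int
    version: str
    outputs: dict[str, str] = dataclasses.field(default_factory=dict)
    checksums: dict[str, str] = dataclasses.field(default_factory=dict)
    stage_seconds: dict[str, float] = dataclasses.field(default_factory=dict)
    metrics: dict = dataclasses.field(default_factory=dict)

    def register(self, name: str, path: str, checksum: bool = True) -> None:
        self.outputs[name] = path
        if checksum:
            self.checksums[name] = _sha256(path)

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def simulate_trio(
    config: SimulationConfig,
    outdir: str | os.PathLike,
    af_table_path: str | os.PathLike | None = None,
    with_reads: bool = True,
) -> RunManifest:
    """Simulate truth genotypes (and optionally reads) for one trio.

    Writes: reference FASTA, allele-frequency TSV, truth trio VCF, PED,
    truth manifest TSV and, with reads, one sorted+indexed BAM per member.
    """
    config.validate()
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    manifest = RunManifest(
        config=dataclasses.asdict(config), master_seed=config.seed, version=__version__
    )

    t0 = time.time()
    reference = synthesize_reference(config.reference_length, config.seed, config.chrom)
    ref_path = os.path.join(outdir, "reference.fa")
    write_fasta(reference, ref_path)
    manifest.register("reference", ref_path)
    manifest.stage_seconds["reference"] = time.time() - t0

    t0 = time.time()
    if af_table_path is not None:
        afs = read_frequency_table(af_table_path)
    else:
        afs = sample_frequency_table(reference, config.n_inherited_sites, config.seed)
    af_path = os.path.join(outdir, "allele_frequencies.tsv")
    write_frequency_table(afs, af_path)
    manifest.register("allele_frequencies", af_path)
    manifest.stage_seconds["frequencies"] = time.time() - t0

    t0 = time.time()
    sites, truth = simulate_trio_sites(afs, reference, config)
    contigs = {c: len(s) for c, s in reference.items()}
    vcf_path = os.path.join(outdir, "truth_trio.vcf")
    write_trio_vcf(sites, contigs, vcf_path)
    manifest.register("truth_vcf", vcf_path)
    ped_path = os.path.join(outdir, "trio.ped")
    write_ped(ped_path)
    manifest.register("ped", ped_path)
    truth_path = os.path.join(outdir, "truth_manifest.tsv")
    write_truth_manifest(truth, truth_path)
    manifest.register("truth_manifest", truth_path)
    violations = check_mendelian_consistency(sites)
    manifest.metrics["n_sites"] = len(sites)
    manifest.metrics["n_truth_dnms"] = len(truth)
    manifest.metrics["n_mendelian_violations"] = len(violations)
    manifest.stage_seconds["genotypes"] = time.time() - t0
    logger.info(
        "genotypes: %d sites, %d spiked DNMs, %d Mendelian violations",
        len(sites), len(truth), len(violations),
    )

    if with_reads:
        for member in MEMBERS:
            t0 = time.time()
            haps = build_diploid_genome(
                reference[config.chrom], sites, member, config.chrom
            )
            pairs = simulate_reads(haps, config, config.seed, stage=f"reads:{member}")
            bam_path = os.path.join(outdir, f"{member}.bam")
            emit_bam(pairs, contigs, bam_path, sample=member, read_prefix=f"{member[0]}")
            manifest.register(f"bam_{member}", bam_path, checksum=False)
            manifest.metrics[f"n_pairs_{member}"] = len(pairs)
            manifest.stage_seconds[f"reads:{member}"] = time.time() - t0
            logger.info("reads: %s %d pairs", member, len(pairs))
    return manifest


def run_end_to_end(
    config: SimulationConfig,
    outdir: str | os.PathLike,
    plots: bool = False,
) -> RunManifest:
    """Simulate, call with the built-in Bayesian caller, and evaluate.

    Produces the trio BAMs, truth VCF/PED/manifest, the caller's VCF and
    normalized call table, an evaluation report, and a run-manifest JSON.
    Raises with the failing stage named if any stage errors.
    """
    outdir = os.fspath(outdir)
    stage = "simulate"
    try:
        manifest = simulate_trio(config, outdir, with_reads=True)
        reference = read_fasta(manifest.outputs["reference"])
        contigs = {c: len(s) for c, s in reference.items()}

        stage = "call"
        t0 = time.time()
        afs = read_frequency_table(manifest.outputs["allele_frequencies"])
        af_lookup = {(e.chrom, e.pos, e.ref, e.alt): e.af for e in afs}
        calls = call_dnms(
            manifest.outputs["bam_father"],
            manifest.outputs["bam_mother"],
            manifest.outputs["bam_offspring"],
            reference,
            config=config,
            af_table=af_lookup,
        )
        calls_vcf = os.path.join(outdir, "calls.vcf")
        write_calls_vcf(calls, contigs, calls_vcf)
        manifest.register("calls_vcf", calls_vcf)
        table_path = os.path.join(outdir, "calls.tsv")
        write_call_table(calls, table_path)
        manifest.register("call_table", table_path)
        manifest.metrics["n_calls"] = len(calls)
        manifest.stage_seconds["call"] = time.time() - t0
        logger.info("caller emitted %d candidate DNM calls", len(calls))

        stage = "evaluate"
        t0 = time.time()
        from .vcfio import read_truth_manifest

        truth = read_truth_manifest(manifest.outputs["truth_manifest"])
        if not truth:
            raise ValueError("truth manifest is empty: evaluation is undefined")
        table = load_call_table(table_path, "generic_tsv")
        filtered = genotype_pattern_filter(table)
        default_summary = score_calls(filtered, truth, threshold=0.5)
        sweep = maximal_f1_sweep(filtered, truth)
        call_sites = [(r.chrom, r.pos, r.ref, r.alt) for r in filtered.records]
        profiles = [
            collect_allelic_counts(manifest.outputs[f"bam_{m}"], call_sites)
            for m in MEMBERS
        ]
        profile = vaf_depth_profile(filtered, truth, *profiles)
        report_path = write_report(
            os.path.join(outdir, "report"),
            {CALLER_NAME: {
                "default_summary": default_summary,
                "sweep": sweep,
                "profile": profile,
            }},
            plots=plots,
        )
        manifest.register("report", report_path)
        manifest.metrics["default_f1"] = default_summary.f1
        manifest.metrics["default_tp"] = default_summary.tp
        manifest.metrics["default_fp"] = default_summary.fp
        manifest.metrics["default_fn"] = default_summary.fn
        manifest.metrics["best_f1"] = sweep.best_f1
        manifest.metrics["best_threshold"] = sweep.best_threshold
        manifest.stage_seconds["evaluate"] = time.time() - t0

        manifest_path = os.path.join(outdir, "run_manifest.json")
        manifest.write(manifest_path)
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
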