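"""Benchmarking layer: caller-output normalization, genotype-pattern
filtering, confusion/F1 scoring, the benchmarking-set maximal-F1 threshold
sweep, multi-caller concordance, VAF/depth profiling and report writing.

Calls are keyed by (chrom, pos, ref, alt). A truth variant matched by at
least one passing call is one TP; passing calls with no truth match are
FPs; unmatched truth entries are FNs. F1 = 2TP / (2TP + FP + FN).
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import HET, HOM_REF, MISSING, AllelicCounts, DnmCall, TruthVariant

__all__ = [
    "CallTable",
    "ConfusionSummary",
    "ThresholdSweepResult",
    "load_call_table",
    "genotype_pattern_filter",
    "score_calls",
    "maximal_f1_sweep",
    "concordance",
    "vaf_depth_profile",
    "normalize_scores",
    "normalize_variant",
    "write_report",
]

logger = logging.getLogger(__name__)

Key = tuple[str, int, str, str]


@dataclass
class CallTable:
    """One caller's putative DNMs with a declared score orientation."""

    caller_name: str
    score_orientation: str  # higher_is_better | lower_is_better
    records: list[DnmCall] = field(default_factory=list)
    n_malformed: int = 0

    def __post_init__(self):
        if self.score_orientation not in ("higher_is_better", "lower_is_better"):
            raise ValueError(f"unknown orientation {self.score_orientation!r}")
        seen: set[Key] = set()
        for r in self.records:
            if r.key in seen:
                raise ValueError(f"duplicate variant key {r.key} in table {self.caller_name}")
            seen.add(r.key)
            if not math.isfinite(r.score):
                raise ValueError(f"non-finite score at {r.key}")

    @property
    def keys(self) -> set[Key]:
        return {r.key for r in self.records}

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ConfusionSummary:
    """TP/FN/FP counts and the derived precision, recall and F1."""

    tp: int
    fn: int
    fp: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0


@dataclass(frozen=True)
class ThresholdSweepResult:
    caller_name: str
    sweep: list[tuple[float, ConfusionSummary]]
    best_threshold: float
    best_f1: float


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> Key:
    """Left-align an indel key by trimming shared trailing then leading bases.

    SNV keys pass through unchanged; this makes differently right-padded
    representations of the same indel compare equal.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (chrom, pos, ref, alt)


def _norm_key(key: Key) -> Key:
    return normalize_variant(*key)


# ---------------------------------------------------------------- adapters

def _adapter_generic_tsv(path: str, **kwargs) -> tuple[str, str, list[DnmCall], int]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"caller", "chrom", "pos", "ref", "alt", "score", "orientation"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"call table missing columns: {sorted(missing)}")
    bad = 0
    records = []
    caller = str(df["caller"].iloc[0]) if len(df) else kwargs.get("caller_name", "unknown")
    orientation = (
        str(df["orientation"].iloc[0]) if len(df) else kwargs.get("orientation", "higher_is_better")
    )
    for r in df.itertuples():
        try:
            records.append(
                DnmCall(
                    str(r.chrom), int(r.pos), str(r.ref), str(r.alt),
                    str(getattr(r, "gt_father", MISSING)),
                    str(getattr(r, "gt_mother", MISSING)),
                    str(getattr(r, "gt_offspring", MISSING)),
                    float(r.score), orientation, caller,
                )
            )
        except (TypeError, ValueError):
            bad += 1
    return caller, orientation, records, bad


def _adapter_vcf_info_score(
    path: str,
    score_key: str = "DNMP",
    orientation: str = "higher_is_better",
    caller_name: str | None = None,
    sample_order: tuple[str, str, str] | None = None,
    **kwargs,
) -> tuple[str, str, list[DnmCall], int]:
    import pysam

    caller = caller_name or os.path.basename(os.fspath(path))
    records = []
    bad = 0
    with pysam.VariantFile(os.fspath(path)) as vcf:
        samples = sample_order or tuple(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1 or score_key not in rec.info:
                bad += 1
                continue
            gts = []
            for s in samples[:3]:
                gt = rec.samples[s].get("GT") if s in rec.samples else None
                if gt is None or any(a is None for a in gt):
                    gts.append(MISSING)
                else:
                    a, b = sorted(gt)
                    gts.append(f"{a}/{b}")
            while len(gts) < 3:
                gts.append(MISSING)
            score = rec.info[score_key]
            if isinstance(score, tuple):
                score = score[0]
            records.append(
                DnmCall(rec.chrom, rec.pos, rec.ref, rec.alts[0],
                        gts[0], gts[1], gts[2], float(score), orientation, caller)
            )
    return caller, orientation, records, bad


def _adapter_prediction_csv(
    path: str,
    probability_column: str = "probability",
    caller_name: str = "cnn",
    **kwargs,
) -> tuple[str, str, list[DnmCall], int]:
    """CSV with one probability-scored row per variant (CNN-style output)."""
    df = pd.read_csv(path, dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", probability_column}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"prediction csv missing columns: {sorted(missing)}")
    records = []
    bad = 0
    for r in df.itertuples():
        try:
            records.append(
                DnmCall(
                    str(r.chrom), int(r.pos), str(r.ref), str(r.alt),
                    str(getattr(r, "gt_father", MISSING)),
                    str(getattr(r, "gt_mother", MISSING)),
                    str(getattr(r, "gt_offspring", MISSING)),
                    float(getattr(r, probability_column)),
                    "higher_is_better", caller_name,
                )
            )
        except (TypeError, ValueError):
            bad += 1
    return caller_name, "higher_is_better", records, bad


_ADAPTERS = {
    "generic_tsv": _adapter_generic_tsv,
    "vcf_info_score": _adapter_vcf_info_score,
    "prediction_csv": _adapter_prediction_csv,
}


def load_call_table(path: str | os.PathLike, format_adapter: str = "generic_tsv", **kwargs) -> CallTable:
    """Read a caller's output into the normalized CallTable form.

    Malformed rows are counted and logged, never silently dropped.
    """
    if format_adapter not in _ADAPTERS:
        raise ValueError(
            f"unknown adapter {format_adapter!r}; expected one of {sorted(_ADAPTERS)}"
        )
    caller, orientation, records, bad = _ADAPTERS[format_adapter](os.fspath(path), **kwargs)
    if bad:
        logger.warning("%s: %d malformed records skipped while loading %s", caller, bad, path)
    if not records:
        raise ValueError(f"no parseable records in {path}")
    return CallTable(caller, orientation, records, n_malformed=bad)


# ----------------------------------------------------------------- scoring

def genotype_pattern_filter(table: CallTable) -> CallTable:
    """Keep only calls with the de novo trio pattern (0/0, 0/0, 0/1).

    Records with a missing genotype for any member are removed: calls whose
    parents could not be genotyped are unverifiable as de novo.
    """
    kept = [
        r
        for r in table.records
        if r.gt_father == HOM_REF and r.gt_mother == HOM_REF and r.gt_offspring == HET
    ]
    return CallTable(table.caller_name, table.score_orientation, kept, table.n_malformed)


def _passing(
    records: list[DnmCall], orientation: str, threshold: float | None
) -> list[DnmCall]:
    if threshold is None:
        return list(records)
    if orientation == "higher_is_better":
        return [r for r in records if r.score >= threshold]
    return [r for r in records if r.score <= threshold]


def score_calls(
    table: CallTable,
    truth: list[TruthVariant] | set[Key],
    threshold: float | None = None,
) -> ConfusionSummary:
    """Confusion counts of the table against a truth set at one threshold.

    Thresholding is inclusive (>= for higher_is_better, <= for
    lower_is_better). One truth entry is at most one TP; surplus passing
    calls count as FPs. Indel keys are compared after left-alignment
    normalization.
    """
    if isinstance(truth, set):
        truth_keys = {_norm_key(k) for k in truth}
    else:
        truth_keys = {_norm_key(v.key) for v in truth}
    if not truth_keys:
        raise ValueError("empty truth set: recall is undefined")
    passing = _passing(table.records, table.score_orientation, threshold)
    matched: set[Key] = set()
    fp = 0
    for r in passing:
        k = _norm_key(r.key)
        if k in truth_keys and k not in matched:
            matched.add(k)
        else:
            fp += 1
    tp = len(matched)
    return ConfusionSummary(tp=tp, fn=len(truth_keys) - tp, fp=fp)


def maximal_f1_sweep(
    table: CallTable, truth: list[TruthVariant] | set[Key]
) -> ThresholdSweepResult:
    """F1 across every distinct observed score; report the maximum.

    Ties in F1 break toward the most stringent threshold — the one
    retaining fewest calls — minimizing false positives.
    """
    if not table.records:
        raise ValueError("cannot sweep an empty call table")
    thresholds = sorted({r.score for r in table.records})
    stringent_last = thresholds if table.score_orientation == "higher_is_better" else thresholds[::-1]
    sweep = [(t, score_calls(table, truth, t)) for t in stringent_last]
    best_threshold, best_summary = sweep[0]
    for t, s in sweep[1:]:
        if s.f1 >= best_summary.f1:  # later entries are more stringent
            best_threshold, best_summary = t, s
    return ThresholdSweepResult(
        caller_name=table.caller_name,
        sweep=sweep,
        best_threshold=best_threshold,
        best_f1=best_summary.f1,
    )


# ------------------------------------------------------------- concordance

def concordance(tables: list[CallTable]) -> dict[frozenset[str], int]:
    """Partition the union of variant keys by the exact calling subset.

    Returns counts for each of the 2^k - 1 possible non-empty caller
    subsets (zero-count classes included), summing to the union size.
    """
    if len(tables) < 2:
        raise ValueError("concordance needs at least two call tables")
    names = [t.caller_name for t in tables]
    if len(set(names)) != len(names):
        raise ValueError("caller names must be unique")
    membership: dict[Key, set[str]] = {}
    for t in tables:
        for k in t.keys:
            membership.setdefault(_norm_key(k), set()).add(t.caller_name)
    from itertools import combinations

    counts: dict[frozenset[str], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            counts[frozenset(combo)] = 0
    for subset in membership.values():
        counts[frozenset(subset)] += 1
    return counts


def concordance_percentages(counts: dict[frozenset[str], int]) -> dict[frozenset[str], float]:
    """Each class as a percentage of the union, rendered to 1 dp downstream."""
    union = sum(counts.values())
    if union == 0:
        return {k: 0.0 for k in counts}
    return {k: 100.0 * v / union for k, v in counts.items()}


# ------------------------------------------------------------- VAF profile

def vaf_depth_profile(
    table: CallTable,
    truth: list[TruthVariant] | set[Key],
    counts_father: list[AllelicCounts],
    counts_mother: list[AllelicCounts],
    counts_offspring: list[AllelicCounts],
) -> pd.DataFrame:
    """Per-call TP/FP label with trio VAFs and offspring depth.

    Counts must be supplied in call-record order; calls without counts at
    their position are flagged excluded and left out of group summaries.
    """
    if isinstance(truth, set):
        truth_keys = {_norm_key(k) for k in truth}
    else:
        truth_keys = {_norm_key(v.key) for v in truth}
    by_pos = {
        m: {(c.chrom, c.pos): c for c in counts}
        for m, counts in (
            ("father", counts_father),
            ("mother", counts_mother),
            ("offspring", counts_offspring),
        )
    }
    rows = []
    excluded = 0
    for r in table.records:
        loc = (r.chrom, r.pos)
        trio_counts = {m: by_pos[m].get(loc) for m in by_pos}
        if any(c is None for c in trio_counts.values()):
            excluded += 1
            rows.append(
                {"chrom": r.chrom, "pos": r.pos, "is_tp": _norm_key(r.key) in truth_keys,
                 "vaf_offspring": np.nan, "vaf_father": np.nan, "vaf_mother": np.nan,
                 "depth_offspring": np.nan, "excluded": True}
            )
            continue
        rows.append(
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "is_tp": _norm_key(r.key) in truth_keys,
                "vaf_offspring": trio_counts["offspring"].vaf,
                "vaf_father": trio_counts["father"].vaf,
                "vaf_mother": trio_counts["mother"].vaf,
                "depth_offspring": trio_counts["offspring"].depth,
                "excluded": False,
            }
        )
    if excluded:
        logger.warning(
            "%s: %d calls lacked allelic counts and are excluded from VAF summaries",
            table.caller_name, excluded,
        )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "is_tp", "vaf_offspring", "vaf_father",
                 "vaf_mother", "depth_offspring", "excluded"],
    )
    df.attrs["n_excluded"] = excluded
    return df


def profile_summary(profile: pd.DataFrame) -> pd.DataFrame:
    """Mean/sd of trio VAFs and offspring depth per TP/FP group."""
    usable = profile[~profile["excluded"]]
    out = []
    for is_tp, group in usable.groupby("is_tp"):
        out.append(
            {
                "group": "TP" if is_tp else "FP",
                "n": len(group),
                "vaf_offspring_mean": group["vaf_offspring"].mean(),
                "vaf_offspring_sd": group["vaf_offspring"].std(ddof=1),
                "vaf_father_mean": group["vaf_father"].mean(),
                "vaf_father_sd": group["vaf_father"].std(ddof=1),
                "vaf_mother_mean": group["vaf_mother"].mean(),
                "vaf_mother_sd": group["vaf_mother"].std(ddof=1),
                "depth_offspring_mean": group["depth_offspring"].mean(),
            }
        )
    return pd.DataFrame(out)


# ----------------------------------------------------------- score scaling

def normalize_scores(table: CallTable) -> CallTable:
    """Min-max scale scores to [0, 1], flipping lower-is-better tables.

    Ranking in the better-is-higher sense is preserved exactly. A single
    distinct score degenerates to 1.0 for every record (warned).
    """
    scores = np.array([r.score for r in table.records], dtype=float)
    lo, hi = scores.min(), scores.max()
    if lo == hi:
        logger.warning("%s: all scores identical; normalizing to 1.0", table.caller_name)
        scaled = np.ones_like(scores)
    else:
        scaled = (scores - lo) / (hi - lo)
        if table.score_orientation == "lower_is_better":
            scaled = 1.0 - scaled
    records = [
        replace(r, score=float(s), score_orientation="higher_is_better")
        for r, s in zip(table.records, scaled)
    ]
    return CallTable(table.caller_name, "higher_is_better", records, table.n_malformed)


# ----------------------------------------------------------------- reports

def write_report(
    outdir: str | os.PathLike,
    evaluations: dict[str, dict],
    concordance_counts: dict[frozenset[str], int] | None = None,
    plots: bool = False,
) -> str:
    """Write machine-readable TSVs plus a markdown summary.

    ``evaluations`` maps caller name to a dict with keys
    ``default_summary`` (ConfusionSummary at the declared default
    threshold), ``sweep`` (ThresholdSweepResult) and optionally
    ``profile`` (vaf_depth_profile frame). Returns the markdown path.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    perf_rows = []
    for caller, ev in evaluations.items():
        sweep: ThresholdSweepResult = ev["sweep"]
        best = next(s for t, s in sweep.sweep if t == sweep.best_threshold)
        row = {
            "caller": caller,
            "best_threshold": sweep.best_threshold,
            "tp": best.tp, "fn": best.fn, "fp": best.fp,
            "precision": best.precision, "recall": best.recall, "f1": best.f1,
        }
        default: ConfusionSummary | None = ev.get("default_summary")
        if default is not None:
            row.update(
                default_tp=default.tp, default_fn=default.fn,
                default_fp=default.fp, default_f1=default.f1,
            )
        perf_rows.append(row)
    perf = pd.DataFrame(perf_rows)
    perf.to_csv(os.path.join(outdir, "performance.tsv"), sep="\t", index=False)

    lines = ["# DNM benchmarking report", "", "## Performance (maximal-F1 threshold)", ""]
    lines.append(perf.to_markdown(index=False, floatfmt=".5f"))
    lines.append("")

    for caller, ev in evaluations.items():
        profile = ev.get("profile")
        if profile is not None:
            summary = profile_summary(profile)
            summary.to_csv(
                os.path.join(outdir, f"vaf_profile_{caller}.tsv"), sep="\t", index=False
            )
            lines += [f"## VAF/depth profile: {caller}", ""]
            if summary.empty or "FP" not in set(summary["group"]):
                lines.append("Zero FP records in the VAF profile.")
            lines.append(summary.to_markdown(index=False, floatfmt=".4f") if not summary.empty else "")
            lines.append("")

    if concordance_counts is not None:
        rows = [
            {"callers": "+".join(sorted(k)), "n_callers": len(k), "count": v,
             "percent": p}
            for (k, v), p in zip(
                sorted(concordance_counts.items(), key=lambda kv: ("+".join(sorted(kv[0])),)),
                [
                    concordance_percentages(concordance_counts)[k]
                    for k in sorted(concordance_counts, key=lambda k: "+".join(sorted(k)))
                ],
            )
        ]
        conc = pd.DataFrame(rows)
        conc.to_csv(os.path.join(outdir, "concordance.tsv"), sep="\t", index=False)
        lines += ["## Concordance", "",
                  f"{len(concordance_counts)} membership classes; union = "
                  f"{sum(concordance_counts.values())} variants.", "",
                  conc.to_markdown(index=False, floatfmt=".1f"), ""]

    if plots:
        _write_plots(outdir, evaluations)

    md_path = os.path.join(outdir, "report.md")
    with open(md_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return md_path


def _write_plots(outdir: str, evaluations: dict[str, dict]) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for caller, ev in evaluations.items():
        profile = ev.get("profile")
        if profile is None or profile.empty:
            continue
        usable = profile[~profile["excluded"]]
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        for is_tp, label, color in ((True, "TP", "tab:blue"), (False, "FP", "tab:red")):
            sub = usable[usable["is_tp"] == is_tp]
            if len(sub):
                axes[0].scatter(sub["depth_offspring"], sub["vaf_offspring"],
                                s=8, alpha=0.6, label=label, color=color)
                axes[1].hist(sub["vaf_offspring"], bins=20, alpha=0.5, label=label, color=color)
        axes[0].set_xlabel("offspring depth")
        axes[0].set_ylabel("offspring VAF")
        axes[1].set_xlabel("offspring VAF")
        for ax in axes:
            ax.legend()
        fig.suptitle(f"VAF profile: {caller}")
        fig.tight_layout()
        fig.savefig(os.path.join(outdir, f"vaf_profile_{caller}.png"), dpi=120)
        plt.close(fig)
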