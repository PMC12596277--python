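"""Population allele-frequency tables.

A bundled generator draws a U-shaped site-frequency spectrum (Beta(0.2, 0.2)
truncated to (0.01, 0.99)) over uniformly placed SNV sites, standing in for
a real population panel. A user-supplied TSV with columns
(chrom, pos, ref, alt, af) overrides it.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from ._seeding import stage_rng
from .types import AlleleFrequencyEntry

__all__ = [
    "sample_frequency_table",
    "write_frequency_table",
    "read_frequency_table",
    "validate_frequency_table",
]

_AF_COLUMNS = ["chrom", "pos", "ref", "alt", "af"]


def sample_frequency_table(
    reference: dict[str, str],
    n_sites: int,
    seed: int,
    beta_shape: float = 0.2,
    af_bounds: tuple[float, float] = (0.01, 0.99),
) -> list[AlleleFrequencyEntry]:
    """Draw *n_sites* polymorphic SNV sites with U-shaped allele frequencies.

    Positions are sampled uniformly without replacement per chromosome
    (proportionally to length), alternate alleles uniformly among the three
    non-reference bases. Frequencies are Beta(b, b) resampled until inside
    the open truncation interval.
    """
    rng = stage_rng(seed, "frequency-table")
    lengths = {c: len(s) for c, s in reference.items()}
    total = sum(lengths.values())
    if n_sites > total:
        raise ValueError(f"cannot place {n_sites} sites on {total} bases")
    entries: list[AlleleFrequencyEntry] = []
    remaining = n_sites
    chroms = sorted(lengths)
    for i, chrom in enumerate(chroms):
        if i == len(chroms) - 1:
            n_here = remaining
        else:
            n_here = int(round(n_sites * lengths[chrom] / total))
            n_here = min(n_here, remaining)
        remaining -= n_here
        if n_here == 0:
            continue
        positions = np.sort(rng.choice(lengths[chrom], size=n_here, replace=False)) + 1
        afs = rng.beta(beta_shape, beta_shape, size=n_here)
        lo, hi = af_bounds
        bad = (afs <= lo) | (afs >= hi)
        while bad.any():
            afs[bad] = rng.beta(beta_shape, beta_shape, size=int(bad.sum()))
            bad = (afs <= lo) | (afs >= hi)
        seq = reference[chrom]
        for pos, af in zip(positions.tolist(), afs.tolist()):
            ref_base = seq[pos - 1]
            alts = [b for b in "ACGT" if b != ref_base]
            alt = alts[int(rng.integers(3))]
            entries.append(AlleleFrequencyEntry(chrom, int(pos), ref_base, alt, float(af)))
    return entries


def validate_frequency_table(entries: list[AlleleFrequencyEntry]) -> None:
    """Raise on any malformed record, naming the offender."""
    last: dict[str, int] = {}
    for e in entries:
        e.validate()
        if e.chrom in last and e.pos <= last[e.chrom]:
            raise ValueError(
                f"positions not strictly increasing on {e.chrom}: {last[e.chrom]} then {e.pos}"
            )
        last[e.chrom] = e.pos


def write_frequency_table(entries: list[AlleleFrequencyEntry], path: str | os.PathLike) -> None:
    df = pd.DataFrame([vars(e) for e in entries], columns=_AF_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_frequency_table(path: str | os.PathLike) -> list[AlleleFrequencyEntry]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_AF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"frequency table missing columns: {sorted(missing)}")
    entries = [
        AlleleFrequencyEntry(str(r.chrom), int(r.pos), str(r.ref), str(r.alt), float(r.af))
        for r in df.itertuples()
    ]
    validate_frequency_table(entries)
    return entries
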