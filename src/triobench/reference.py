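"""Synthetic reference sequences standing in for a real genome build.

The simulator never ships real genome data; it draws a random autosome-like
sequence (human-like ~41% GC) of configurable length. Sequences are written
as indexed FASTA so downstream BAM/VCF tooling can use them directly.
"""

from __future__ import annotations

import os

import numpy as np
import pysam

from ._seeding import stage_rng

__all__ = ["synthesize_reference", "write_fasta", "read_fasta"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def synthesize_reference(
    length: int, seed: int, chrom: str = "chr1", gc_content: float = 0.41
) -> dict[str, str]:
    """Draw one random chromosome of *length* bases at the given GC content."""
    if length <= 0:
        raise ValueError(f"reference length must be positive, got {length}")
    rng = stage_rng(seed, f"reference:{chrom}")
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    seq = _BASES[idx].tobytes().decode("ascii")
    return {chrom: seq}


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    """Write sequences as FASTA (60-col wrapped) and build a .fai index."""
    path = os.fspath(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    pysam.faidx(path)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    with pysam.FastaFile(os.fspath(path)) as fa:
        return {name: fa.fetch(name) for name in fa.references}
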