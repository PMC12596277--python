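"""Stage-labelled random streams derived from one master seed.

Every stochastic stage (parental sampling, transmission, spiking, read
simulation per trio member) draws from its own ``numpy`` Generator keyed by
the master seed plus a CRC32 hash of the stage name, so stages are mutually
independent and adding a stage never perturbs an existing one.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng"]


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for *stage* deterministically derived from *master_seed*."""
    if master_seed < 0:
        raise ValueError(f"master seed must be non-negative, got {master_seed}")
    return np.random.default_rng([int(master_seed), zlib.crc32(stage.encode("utf-8"))])
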