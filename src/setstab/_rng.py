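"""Seed handling shared by all stochastic operations.

Every top-level operation accepts either an integer seed or an existing
:class:`numpy.random.Generator`.  Sub-streams (one per set, one per
replicate) are derived with ``Generator.spawn`` so results are reproducible
regardless of evaluation order.
"""

from __future__ import annotations

import zlib

import numpy as np

SeedLike = "int | np.random.Generator | None"


def as_generator(seed) -> np.random.Generator:
    """Return a Generator, passing one through untouched."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage integer seed (< 2**31) by stable hashing of the stage name."""
    return (int(master_seed) ^ zlib.crc32(stage.encode("utf-8"))) % (2**31)
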