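"""Seed plumbing: one master seed, per-stage child streams.

Child seeds are derived by stable hashing of (seed, stage name) so any
stage can be re-run in isolation and reproduce its output exactly.
"""

from __future__ import annotations

import zlib

import numpy as np


def stage_seed(master: int, stage: str) -> int:
    """Deterministic 31-bit child seed for a named pipeline stage."""
    return (int(master) * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1)


def stage_rng(master: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master, stage))
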