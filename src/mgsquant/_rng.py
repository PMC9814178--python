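"""Seeded random-generator plumbing.

Every stochastic stage derives its generator from a single user seed plus a
stage name, so stages are reproducible independently of call order and no
global numpy state is touched.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng"]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a ``Generator`` keyed by ``(seed, stage)``.

    The stage name is folded in through a CRC so that two stages sharing a
    seed never share a stream.
    """
    tag = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
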