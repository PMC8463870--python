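"""Deterministic per-stage, per-image random substreams.

A single global seed is combined with stable CRC32 hashes of (stage, key) into
a :class:`numpy.random.SeedSequence`, so adding images or stages never perturbs
the streams of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(global_seed: int, stage: str, key: str = "") -> np.random.Generator:
    """Return an independent generator for (stage, key) under ``global_seed``."""
    entropy = [
        int(global_seed),
        zlib.crc32(stage.encode("utf-8")),
        zlib.crc32(key.encode("utf-8")),
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))
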