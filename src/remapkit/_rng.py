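"""Deterministic seed splitting.

All randomness in a run flows from one session-level integer seed. Named
substreams are derived with :class:`numpy.random.SeedSequence` using a spawn
key built from CRC32 hashes of string tags, so adding a new consumer never
perturbs existing streams and every stream is reproducible across processes.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["seed_sequence", "rng_for"]


def seed_sequence(seed: int, *tags: object) -> np.random.SeedSequence:
    """Seed sequence for the substream identified by ``tags`` under ``seed``."""
    key = tuple(zlib.crc32(str(t).encode("utf8")) for t in tags)
    return np.random.SeedSequence(seed, spawn_key=key)


def rng_for(seed: int, *tags: object) -> np.random.Generator:
    """Generator for the substream identified by ``tags`` under ``seed``."""
    return np.random.default_rng(seed_sequence(seed, *tags))
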