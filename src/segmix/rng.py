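"""Deterministic named random streams.

A single master seed determines every random draw in a run. Each consumer
(validation split, instance initialization, per-round minibatch, ...) gets
its own child stream addressed by a path of names/indices, so adding more
instances or rounds never perturbs the draws of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed_sequence", "child_rng"]


def _key(part: str | int) -> int:
    if isinstance(part, (int, np.integer)):
        if part < 0:
            raise ValueError("stream path indices must be non-negative")
        return int(part)
    # stable, platform-independent hash of the stream name
    return zlib.crc32(part.encode("utf-8"))


def child_seed_sequence(seed: int, *path: str | int) -> np.random.SeedSequence:
    """Seed sequence for the stream addressed by ``path`` under ``seed``."""
    return np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(_key(p) for p in path))


def child_rng(seed: int, *path: str | int) -> np.random.Generator:
    """Generator for the named child stream."""
    return np.random.default_rng(child_seed_sequence(seed, *path))
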