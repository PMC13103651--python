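"""Deterministic random-stream plumbing.

All randomness in the package flows from one master seed. Named substreams
are derived by hashing a path of labels into a ``SeedSequence`` spawn key,
so e.g. ``rng_for(7, "cohort", "subject", 12)`` is reproducible regardless
of the order in which streams are created.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "rng_for"]


def _key(part: str | int) -> int:
    if isinstance(part, (int, np.integer)):
        if part < 0:
            raise ValueError("substream integers must be non-negative")
        return int(part)
    return zlib.crc32(str(part).encode("utf-8"))


def substream(master_seed: int, *path: str | int) -> np.random.SeedSequence:
    """SeedSequence for a named substream of ``master_seed``."""
    return np.random.SeedSequence(int(master_seed), spawn_key=tuple(_key(p) for p in path))


def rng_for(master_seed: int, *path: str | int) -> np.random.Generator:
    """Generator seeded from a named substream of ``master_seed``."""
    return np.random.default_rng(substream(master_seed, *path))
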