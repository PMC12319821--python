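"""Deterministic RNG substream derivation.

Every stochastic stage derives its generator from a master seed plus a
structured key (subject, ROI, scheme, repeat, searchlight center, ...) via
``numpy.random.SeedSequence`` spawn keys.  This makes results independent of
execution order and parallelism: the stream consumed at one (subject, ROI)
never depends on how many other units ran before it.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "key_to_int", "derive_seed"]


def key_to_int(part: int | str) -> int:
    """Map a key component to a stable non-negative integer (< 2**32)."""
    if isinstance(part, (int, np.integer)):
        if part < 0:
            raise ValueError("key components must be non-negative")
        return int(part)
    return zlib.crc32(str(part).encode("utf-8"))


def substream(master_seed: int, *key: int | str) -> np.random.Generator:
    """Return a Generator for the substream identified by ``key``.

    The same (master_seed, key) pair always yields the same stream; distinct
    keys yield statistically independent streams.
    """
    spawn_key = tuple(key_to_int(k) for k in key)
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=spawn_key))


def derive_seed(master_seed: int, *key: int | str) -> int:
    """Derive a child integer seed (< 2**31) for the given substream key."""
    spawn_key = tuple(key_to_int(k) for k in key)
    state = np.random.SeedSequence(master_seed, spawn_key=spawn_key).generate_state(1)
    return int(state[0] % 2**31)
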