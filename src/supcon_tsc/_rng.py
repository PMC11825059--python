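"""Seed fan-out: one user seed, independent per-stage streams.

A splitmix64-style hash maps (seed, stream name) to a 32-bit child seed,
so stages (data generation, weight init, shuffling, augmentation, folds)
get decorrelated reproducible generators.
"""

from __future__ import annotations

import numpy as np

MASK64 = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & MASK64
    return (x ^ (x >> 31)) & MASK64


def child_seed(seed: int, stream: str) -> int:
    """Deterministic 31-bit child seed for a named stream."""
    h = seed & MASK64
    for ch in stream:
        h = _splitmix64(h ^ ord(ch))
    return int(h & 0x7FFFFFFF)


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, stream))
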