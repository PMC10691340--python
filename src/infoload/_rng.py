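"""Deterministic seeding helpers.

Every stochastic operation in the package takes an explicit integer seed.
Derived streams (per trial, per pipeline stage) are split off deterministically
with :func:`derive_seed` so that a single top-level seed reproduces a whole
pipeline bit-for-bit.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31 - 1


def derive_seed(seed: int, *tags: int | str) -> int:
    """Derive a child seed (< 2**31) from ``seed`` and a sequence of tags.

    Tags may be integers (e.g. trial index) or strings (e.g. stage name); the
    mapping is stable across runs and platforms.
    """
    h = int(seed) % _MOD
    for tag in tags:
        data = str(tag).encode()
        h = (h * 1000003 + zlib.crc32(data)) % _MOD
    return h


def rng_from(seed: int | None, *tags: int | str) -> np.random.Generator:
    """Generator seeded from ``derive_seed(seed, *tags)`` (fresh if seed is None)."""
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(derive_seed(seed, *tags) if tags else int(seed))
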