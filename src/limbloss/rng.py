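"""Deterministic random-number management.

Every stochastic operation forks its own generator from the run seed and
its operation name, so adding a new operation never perturbs the draws of
an existing one, and the same (seed, name) pair yields byte-identical
streams on every platform.
"""

from __future__ import annotations

import zlib

import numpy as np


def fork_rng(seed: int, name: str) -> np.random.Generator:
    """Return a generator keyed by (seed, operation name)."""
    tag = zlib.crc32(name.encode("utf-8")) & 0xFFFFFFFF
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, tag])
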