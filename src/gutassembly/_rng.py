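"""Deterministic, splittable random streams.

All randomness in the package flows from a single integer seed.  Independent
streams for sub-tasks (one condition, one bootstrap, one permutation null)
are derived by hashing the seed together with string tokens, so adding or
reordering conditions never perturbs the stream of another.
"""

from __future__ import annotations

import hashlib

import numpy as np


def child_seed(seed: int, *tokens: object) -> int:
    """A stable 32-bit child seed derived from ``seed`` and string tokens."""
    h = hashlib.sha256()
    h.update(str(int(seed)).encode())
    for t in tokens:
        h.update(b"\x1f")
        h.update(str(t).encode())
    return int.from_bytes(h.digest()[:4], "big")


def child_rng(seed: int, *tokens: object) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, *tokens))
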