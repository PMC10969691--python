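"""Deterministic seed derivation.

All randomness in the package flows from a user-supplied master seed through
:func:`child_rng` / :func:`child_seed`; no global RNG state is ever touched.
String keys are hashed with blake2b so that streams for distinct purposes
("dag", "coeffs", ...) are independent, and content keys let two call sites
that see the same data draw the same stream regardless of argument order.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_rng", "child_seed", "content_key"]

_MOD = 2**31 - 1


def _key_to_int(key: int | str) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) % _MOD
    digest = hashlib.blake2b(str(key).encode(), digest_size=8).digest()
    return int.from_bytes(digest, "little") % _MOD


def child_seed(seed: int, *keys: int | str) -> int:
    """Derive a deterministic child seed (< 2**31) from a master seed and keys."""
    ss = np.random.SeedSequence([int(seed) % _MOD, *(_key_to_int(k) for k in keys)])
    return int(ss.generate_state(1)[0]) % _MOD


def child_rng(seed: int, *keys: int | str) -> np.random.Generator:
    """A fresh Generator on an independent stream identified by ``keys``."""
    return np.random.default_rng(child_seed(seed, *keys))


def content_key(values: np.ndarray) -> int:
    """Stable integer key derived from array contents (argument-order invariant)."""
    arr = np.ascontiguousarray(values, dtype=np.float64)
    digest = hashlib.blake2b(arr.tobytes() + str(arr.shape).encode(), digest_size=8).digest()
    return int.from_bytes(digest, "little") % _MOD
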