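"""Deterministic seed derivation.

Every random consumer in the package receives a seed derived from the
master seed through :func:`seed_sequence`, keyed by stable integers /
strings.  The scheme is ``SeedSequence([k0, k1, ...])`` where string keys
are hashed with BLAKE2 (stable across processes and platforms, unlike
``hash()``) and integer keys are reduced modulo 2**64.
"""

from __future__ import annotations

import hashlib

import numpy as np

_MASK = (1 << 64) - 1


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & _MASK
    if isinstance(key, str):
        digest = hashlib.blake2b(key.encode("utf-8"), digest_size=8).digest()
        return int.from_bytes(digest, "little")
    raise TypeError(f"seed keys must be int or str, got {type(key)!r}")


def seed_sequence(*keys) -> np.random.SeedSequence:
    return np.random.SeedSequence([_key_to_int(k) for k in keys])


def rng_for(*keys) -> np.random.Generator:
    """A fresh :class:`numpy.random.Generator` for the given key path."""
    return np.random.default_rng(seed_sequence(*keys))


def child_seed(*keys) -> int:
    """A 63-bit integer seed derived from the key path (fits in any API)."""
    return int(seed_sequence(*keys).generate_state(1, np.uint64)[0] >> 1)
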