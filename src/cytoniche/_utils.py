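"""Shared helpers: deterministic seed derivation and validation."""

from __future__ import annotations

import zlib

import numpy as np

_SEED_MOD = 2**31 - 1


def derive_seed(master_seed: int, *keys) -> int:
    """Derive a child seed from a master seed and arbitrary hashable keys.

    Uses CRC32 over the repr of the keys so derived seeds are stable across
    processes and independent of execution order; always < 2**31.
    """
    payload = repr(tuple(keys)).encode("utf-8")
    h = zlib.crc32(payload)
    return int((int(master_seed) * 2654435761 + h) % _SEED_MOD)


def rng_from(master_seed: int, *keys) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, *keys))


def check_finite_coords(x: np.ndarray, y: np.ndarray) -> None:
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("cell coordinates contain non-finite values")
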