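"""Deterministic hierarchical random streams.

Every stochastic component of the package (simulation, train/test splits,
forest bootstraps) draws from a named child stream of a single master seed,
so bins, repeats and cell lines can be processed in any order — or in
parallel — with identical results.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed_sequence", "child_rng"]


def _encode_key(key: int | str) -> int:
    """Map a stream key to a non-negative 32-bit integer.

    Integers use a zig-zag encoding so negative bin indices are legal keys;
    strings hash through crc32 (stable across platforms and sessions,
    unlike the built-in ``hash``).
    """
    if isinstance(key, bool):  # bool is an int subclass; reject silently odd keys
        raise TypeError("boolean stream keys are ambiguous")
    if isinstance(key, (int, np.integer)):
        k = int(key)
        return 2 * k if k >= 0 else -2 * k - 1
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    raise TypeError(f"unsupported stream key type: {type(key)!r}")


def child_seed_sequence(master_seed: int, *keys: int | str) -> np.random.SeedSequence:
    """Return the SeedSequence for the child stream named by ``keys``."""
    entropy = [int(master_seed)] + [_encode_key(k) for k in keys]
    return np.random.SeedSequence(entropy)


def child_rng(master_seed: int, *keys: int | str) -> np.random.Generator:
    """A fresh Generator for the child stream named by ``keys``.

    Examples
    --------
    >>> a = child_rng(7, "tracks", "H3K4me3", 1)
    >>> b = child_rng(7, "tracks", "H3K4me3", 1)
    >>> a.integers(1 << 30) == b.integers(1 << 30)
    True
    """
    return np.random.default_rng(child_seed_sequence(master_seed, *keys))
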