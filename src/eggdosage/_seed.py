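"""Deterministic seed splitting.

A single cohort/run seed is expanded into independent per-stage and
per-sample streams through :class:`numpy.random.SeedSequence` spawn keys,
so adding a sample (or stage) never perturbs the draws of earlier ones.
String keys are mapped to integers with CRC32, which is stable across
processes and platforms (unlike the builtin ``hash``).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed_sequence", "child_rng"]


def _key_to_int(key: int | str) -> int:
    if isinstance(key, bool):  # bool is an int subclass; reject to avoid surprises
        raise TypeError("seed keys must be int or str, not bool")
    if isinstance(key, int):
        if key < 0:
            raise ValueError("integer seed keys must be nonnegative")
        return key
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    raise TypeError(f"seed keys must be int or str, got {type(key).__name__}")


def child_seed_sequence(seed: int, *keys: int | str) -> np.random.SeedSequence:
    """SeedSequence for the stream identified by ``keys`` under root ``seed``."""
    return np.random.SeedSequence(entropy=seed, spawn_key=tuple(_key_to_int(k) for k in keys))


def child_rng(seed: int, *keys: int | str) -> np.random.Generator:
    """Generator for the stream identified by ``keys`` under root ``seed``."""
    return np.random.default_rng(child_seed_sequence(seed, *keys))
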