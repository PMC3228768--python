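"""Deterministic random-stream management.

All randomness in the package flows from an integer root seed.  Independent
streams for sub-computations (a realization, a direction cell, a schedule
draw) are derived by hashing string/number keys into a ``SeedSequence``
together with the root seed, so any cell of a large simulation can be
reproduced in isolation without re-running the rest.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed_sequence", "child_rng"]


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    if isinstance(key, float):
        key = repr(key)
    return zlib.crc32(str(key).encode("utf-8"))


def child_seed_sequence(root_seed: int, *keys) -> np.random.SeedSequence:
    """SeedSequence for the stream identified by ``keys`` under ``root_seed``."""
    return np.random.SeedSequence([int(root_seed)] + [_key_to_int(k) for k in keys])


def child_rng(root_seed: int, *keys) -> np.random.Generator:
    """Generator for the stream identified by ``keys`` under ``root_seed``."""
    return np.random.default_rng(child_seed_sequence(root_seed, *keys))
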