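"""Deterministic named random substreams.

All randomness in the package flows from a single root seed. Each module
stage draws from its own named substream so that, e.g., enlarging the
genome-wide panel does not perturb the clinical-delta draws.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(seed: int, name: str) -> int:
    """A stable, name-keyed child seed below 2**31."""
    return (int(seed) ^ zlib.crc32(name.encode("utf-8"))) & 0x7FFFFFFF


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for the substream `name` of root `seed`.

    Uses a SeedSequence spawn key derived from a CRC of the name, so streams
    for different names are statistically independent and reproducible.
    """
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
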