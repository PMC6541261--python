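"""Small shared helpers: seeding, logging, TSV conventions."""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger("coreseq")


def rng_from_seed(seed: int) -> np.random.Generator:
    """Deterministic generator; all package randomness flows through here."""
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    return np.random.default_rng(int(seed))


def child_seed(seed: int, tag: str) -> int:
    """Derive a stable sub-seed below 2**31 from a parent seed and a label."""
    h = np.uint64(seed & 0x7FFFFFFF)
    for ch in tag:
        h = np.uint64((int(h) * 1000003 + ord(ch)) % (2**31 - 1))
    return int(h)


class ParameterError(ValueError):
    """A simulation or analysis parameter is outside its valid range."""


class FormatError(ValueError):
    """An input file violates its declared format."""
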