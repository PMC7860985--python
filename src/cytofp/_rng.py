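"""Seed bookkeeping.

All randomness in the package flows from one experiment-level integer seed.
Child seeds for individual operations are derived with ``child_seed`` so that
every stage is independently reproducible and loggable.
"""

from __future__ import annotations

import zlib

import numpy as np


def _tag_to_int(tag) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag)
    if isinstance(tag, str):
        return zlib.crc32(tag.encode("utf-8"))
    raise TypeError(f"seed tag must be int or str, got {type(tag)!r}")


def child_seed(seed: int, *tags) -> int:
    """Derive a deterministic child seed from ``seed`` and a path of tags."""
    entropy = [int(seed)] + [_tag_to_int(t) for t in tags]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0])


def rng_from(seed: int, *tags) -> np.random.Generator:
    """A ``numpy`` Generator keyed by ``seed`` and a path of tags."""
    return np.random.default_rng(child_seed(seed, *tags))
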