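"""Deterministic random-number fan-out.

A single user-facing seed is expanded into independent, named substreams so
each pipeline stage (simulation, splitting, boosting, clustering, ...) can be
re-run in isolation and still reproduce the end-to-end run bit for bit.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _name_key(name: str) -> int:
    # CRC32 is stable across platforms and Python versions, unlike hash().
    return zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Return a Generator for the (seed, stage-name, repeat-index) triple."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _name_key(name), int(index)]))


def child_seed(seed: int, name: str, index: int = 0) -> int:
    """A derived scalar seed (< 2**31) for APIs that take plain integers."""
    ss = np.random.SeedSequence([int(seed), _name_key(name), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
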