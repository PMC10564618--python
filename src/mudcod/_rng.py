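"""Addressable, reproducible random streams.

A single root seed spawns an independent ``numpy`` Generator for every
named site (e.g. ``("labels", s, t)`` or ``("adjacency", s, t)``) via
``SeedSequence`` spawn keys.  Streams are therefore insensitive to the
order in which they are consumed, and sub-grids of a simulation are
unchanged when S or T grows.
"""

from __future__ import annotations

import numpy as np

__all__ = ["stream"]

# stable tag -> integer mapping, so spawn keys are pure integers
_TAGS = {
    "connectivity": 1,
    "degree": 2,
    "labels": 3,
    "adjacency": 4,
    "folds": 5,
    "kmeans": 6,
    "cv": 7,
    "benchmark": 8,
}


def stream(seed: int, tag: str, *key: int) -> np.random.Generator:
    """Return a Generator for the site ``(tag, *key)`` under ``seed``.

    Distinct ``(tag, *key)`` tuples yield statistically independent
    streams; the same tuple always yields the same stream.
    """
    if tag not in _TAGS:
        raise KeyError(f"unknown stream tag {tag!r}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_TAGS[tag], *map(int, key)))
    return np.random.default_rng(ss)


def subseed(seed: int, tag: str, *key: int) -> int:
    """A derived integer seed < 2**31 for libraries that take plain ints."""
    return int(stream(seed, tag, *key).integers(0, 2**31 - 1))
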