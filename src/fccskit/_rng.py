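"""Deterministic, splittable random-stream derivation.

Every stochastic routine in the package derives its generator from a single
integer seed plus a sequence of labels, so that independent components draw
from independent streams while the whole run stays reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng"]


def _label_to_int(label: object) -> int:
    if isinstance(label, (int, np.integer)):
        return int(label) & 0xFFFFFFFF
    return zlib.crc32(str(label).encode("utf-8"))


def derive_rng(seed: int, *stream: object) -> np.random.Generator:
    """Return a generator for the stream identified by ``(seed, *stream)``.

    Identical arguments always yield an identical generator; any change to
    the seed or to the stream labels yields a statistically independent one.
    """
    entropy = (int(seed),) + tuple(_label_to_int(s) for s in stream)
    return np.random.default_rng(np.random.SeedSequence(entropy))
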