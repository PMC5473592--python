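"""Deterministic random-stream derivation.

Every stochastic operation in the package draws from a generator derived
from a top-level seed plus a tuple of string/int keys (e.g. the dataset id,
the subsampling depth and the iteration index).  This makes results
reproducible bit-for-bit, independent of the order in which iterations or
grid points are evaluated, and lets two simulations that conceptually share
a draw (e.g. "subsample replicate d to r reads in iteration i") obtain the
*same* draw.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng"]


def derive_rng(seed: int, *keys) -> np.random.Generator:
    """Return a Generator deterministically derived from ``seed`` and ``keys``.

    Keys may be strings, ints or any object with a stable ``repr``.
    """
    entropy = [int(seed) & 0xFFFFFFFF]
    entropy.extend(zlib.crc32(repr(k).encode("utf8")) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(entropy))
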