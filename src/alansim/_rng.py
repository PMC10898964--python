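"""Deterministic counter-seeded PCG32 streams.

The engine and walker derive one independent stream per photon source /
per walker from a master seed via splitmix64 mixing.  The same generator
is implemented here in pure Python and again inside the numba kernels
(:mod:`alansim._kernels`), bit-for-bit identical, so results are
reproducible and independent of execution order, and the compiled and
interpreted code paths can be cross-checked exactly.
"""
from __future__ import annotations

import numpy as np

_MASK64 = 0xFFFFFFFFFFFFFFFF
_PCG_MULT = 6364136223846793005
_PCG_INC = 1442695040888963407


def splitmix64(x: int) -> int:
    """One splitmix64 step; used to derive stream seeds from a master seed."""
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return x ^ (x >> 31)


def stream_seed(master_seed: int, stream_id: int) -> int:
    """64-bit seed for stream ``stream_id`` under ``master_seed``."""
    return splitmix64(splitmix64(master_seed & _MASK64) ^ splitmix64((stream_id + 1) & _MASK64))


class PcgStream:
    """Minimal PCG32 with the `numpy.random.Generator.uniform`-ish surface
    the sampling operations need (``uniform`` and ``random``)."""

    def __init__(self, seed: int):
        self.state = (splitmix64(seed & _MASK64) | 1) & _MASK64

    def _next32(self) -> int:
        s = self.state
        self.state = (s * _PCG_MULT + _PCG_INC) & _MASK64
        xorshifted = ((s >> 18) ^ s) >> 27 & 0xFFFFFFFF
        rot = s >> 59
        return ((xorshifted >> rot) | (xorshifted << ((-rot) & 31))) & 0xFFFFFFFF

    def random(self, size=None):
        """Uniform draw(s) in the half-open interval [0, 1)."""
        if size is None:
            return self._next32() * 2.0**-32
        out = np.empty(int(size))
        for i in range(int(size)):
            out[i] = self._next32() * 2.0**-32
        return out

    def uniform(self, low=0.0, high=1.0, size=None):
        r = self.random(size)
        return low + (high - low) * r

    def open_unit(self) -> float:
        """Uniform in (0, 1]; safe as the argument of a logarithm."""
        return (self._next32() + 1.0) * 2.0**-32
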