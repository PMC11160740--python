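"""Nested-scheme HEALPix pixel centers for power-of-two nside.

Only the single primitive the pose-search grids need: mapping a nested pixel
index to the (theta, phi) of its center.  Formulas follow the standard
equal-area HEALPix construction (12 base faces, bit-interleaved in-face
coordinates); subdividing pixel p at nside n yields children 4p..4p+3 at 2n,
which is what makes the nested scheme the natural backbone of a hierarchical
orientation search.
"""

from __future__ import annotations

import numpy as np

__all__ = ["nest2ang", "npix"]

_JRLL = np.array([2, 2, 2, 2, 3, 3, 3, 3, 4, 4, 4, 4])
_JPLL = np.array([1, 3, 5, 7, 0, 2, 4, 6, 1, 3, 5, 7])


def npix(nside: int) -> int:
    return 12 * nside * nside


def _compress_bits(v: np.ndarray) -> np.ndarray:
    """Keep even-position bits of v and pack them contiguously."""
    out = np.zeros_like(v)
    for i in range(32):
        out |= ((v >> (2 * i)) & 1) << i
    return out


def nest2ang(nside: int, ipix) -> tuple[np.ndarray, np.ndarray]:
    """Center (theta, phi) in radians of nested pixels at resolution nside."""
    if nside < 1 or (nside & (nside - 1)):
        raise ValueError("nside must be a positive power of two")
    ipix = np.atleast_1d(np.asarray(ipix, dtype=np.int64))
    if np.any((ipix < 0) | (ipix >= npix(nside))):
        raise ValueError("pixel index out of range")
    npface = nside * nside
    face = ipix // npface
    within = ipix % npface
    ix = _compress_bits(within)
    iy = _compress_bits(within >> 1)

    jr = _JRLL[face] * nside - ix - iy - 1  # ring index, 1 .. 4 nside - 1
    nr = np.empty_like(jr)
    z = np.empty(jr.shape, dtype=np.float64)
    kshift = np.zeros_like(jr)

    north = jr < nside
    south = jr > 3 * nside
    eq = ~(north | south)
    nr[north] = jr[north]
    z[north] = 1.0 - (nr[north] ** 2) / (3.0 * nside * nside)
    nr[south] = 4 * nside - jr[south]
    z[south] = (nr[south] ** 2) / (3.0 * nside * nside) - 1.0
    nr[eq] = nside
    z[eq] = (2 * nside - jr[eq]) * 2.0 / (3.0 * nside)
    kshift[eq] = (jr[eq] - nside) & 1

    jp = (_JPLL[face] * nr + ix - iy + 1 + kshift) // 2
    jp = np.where(jp > 4 * nr, jp - 4 * nr, jp)
    jp = np.where(jp < 1, jp + 4 * nr, jp)

    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = (jp - (kshift + 1) * 0.5) * (np.pi / (2.0 * nr))
    return theta, phi
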