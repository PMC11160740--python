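"""Six-parameter rotation representation and its backward pass.

A rotation is parameterized by two unconstrained 3-vectors (a1, a2); the
rows of R are obtained by Gram-Schmidt: e1 = a1/|a1|, e2 = normalized
(a2 - (e1·a2) e1), e3 = e1 × e2.  The map is surjective onto SO(3), smooth
away from degenerate inputs, and initializing a = (R row 1, R row 2)
reproduces R exactly — which is what lets stochastic gradient refinement
start precisely from a grid-search pose.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rot6d_to_matrix", "rot6d_backward", "matrix_to_rot6d", "geodesic_angle"]


def rot6d_to_matrix(a: np.ndarray) -> np.ndarray:
    """(..., 6) -> (..., 3, 3); rows of R are the orthonormalized frame."""
    a = np.asarray(a, dtype=np.float64)
    a1, a2 = a[..., :3], a[..., 3:]
    e1 = a1 / np.linalg.norm(a1, axis=-1, keepdims=True)
    u2 = a2 - np.sum(e1 * a2, axis=-1, keepdims=True) * e1
    e2 = u2 / np.linalg.norm(u2, axis=-1, keepdims=True)
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=-2)


def matrix_to_rot6d(R: np.ndarray) -> np.ndarray:
    """Exact preimage: the first two rows of R."""
    R = np.asarray(R, dtype=np.float64)
    return np.concatenate([R[..., 0, :], R[..., 1, :]], axis=-1)


def _normalize_backward(u, e, g):
    """Backward of e = u/|u| given upstream d/de = g."""
    n = np.linalg.norm(u, axis=-1, keepdims=True)
    return (g - np.sum(g * e, axis=-1, keepdims=True) * e) / n


def rot6d_backward(a: np.ndarray, gR: np.ndarray) -> np.ndarray:
    """d(loss)/da given d(loss)/dR (..., 3, 3); verified by finite differences."""
    a = np.asarray(a, dtype=np.float64)
    a1, a2 = a[..., :3], a[..., 3:]
    n1 = np.linalg.norm(a1, axis=-1, keepdims=True)
    e1 = a1 / n1
    d12 = np.sum(e1 * a2, axis=-1, keepdims=True)
    u2 = a2 - d12 * e1
    e2 = u2 / np.linalg.norm(u2, axis=-1, keepdims=True)

    g1 = gR[..., 0, :].copy()
    g2 = gR[..., 1, :].copy()
    g3 = gR[..., 2, :]
    # e3 = e1 x e2:  d/de1 += e2 x g3,  d/de2 += g3 x e1
    g1 += np.cross(e2, g3)
    g2 += np.cross(g3, e1)
    # e2 normalization
    gu2 = _normalize_backward(u2, e2, g2)
    # u2 = a2 - (e1·a2) e1
    dot_g_e1 = np.sum(gu2 * e1, axis=-1, keepdims=True)
    ga2 = gu2 - dot_g_e1 * e1
    g1 += -(dot_g_e1 * a2 + d12 * gu2)
    # e1 normalization
    ga1 = _normalize_backward(a1, e1, g1)
    return np.concatenate([ga1, ga2], axis=-1)


def geodesic_angle(Ra: np.ndarray, Rb: np.ndarray) -> np.ndarray:
    """Geodesic distance on SO(3) in radians, broadcast over leading axes."""
    tr = np.einsum("...ij,...ij->...", Ra, Rb)
    return np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))
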