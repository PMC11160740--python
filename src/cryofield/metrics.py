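"""Evaluation metrics: FSC, per-image FSC, pose accuracy, quaternion loss.

Pose accuracy follows the standard protocol for ab initio methods: the
estimated rotations are first globally aligned to the reference set (the
reconstruction is only defined up to a global rotation), then errors are
split into an out-of-plane part (angle between viewing directions) and an
in-plane part (spin about the viewing axis).  Translations are compared
after solving for the unknown 3D origin shift that best explains the
systematic part of the discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .rotations import geodesic_angle

__all__ = [
    "FscCurve",
    "PoseErrorReport",
    "fsc",
    "per_image_fsc",
    "align_rotations",
    "decompose_errors",
    "optimal_shift",
    "quaternion_loss",
]


@dataclass
class FscCurve:
    """Fourier shell correlation per one-pixel-wide shell."""

    radii: np.ndarray  # shell radii, cycles per image length
    correlation: np.ndarray

    def crossing(self, threshold: float) -> float:
        """First radius where the curve drops below ``threshold``.

        Linear interpolation between shells; returns the Nyquist radius if
        the curve never crosses.
        """
        c = self.correlation
        r = self.radii
        below = np.where(c < threshold)[0]
        if below.size == 0:
            return float(r[-1])
        j = below[0]
        if j == 0:
            return float(r[0])
        f = (c[j - 1] - threshold) / (c[j - 1] - c[j])
        return float(r[j - 1] + f * (r[j] - r[j - 1]))


@dataclass
class PoseErrorReport:
    alignment: np.ndarray  # global 3x3 rotation applied to the estimates
    out_of_plane_deg: np.ndarray
    in_plane_deg: np.ndarray
    geodesic_deg: np.ndarray
    optimal_shift: np.ndarray | None = None
    translation_residuals: np.ndarray | None = None


def fsc(map_a: np.ndarray, map_b: np.ndarray) -> FscCurve:
    """Fourier shell correlation between two cubic maps.

    Shells are one Fourier pixel wide, DC included; correlation is the
    normalized cross-correlation of the complex Fourier coefficients per
    shell.  Symmetric in its arguments.
    """
    map_a = np.asarray(map_a, dtype=np.float64)
    map_b = np.asarray(map_b, dtype=np.float64)
    if map_a.shape != map_b.shape or map_a.ndim != 3:
        raise ValueError("maps must be cubic arrays of identical shape")
    D = map_a.shape[0]
    fa = np.fft.fftshift(np.fft.fftn(map_a))
    fb = np.fft.fftshift(np.fft.fftn(map_b))
    g = np.arange(D) - D // 2
    zz, yy, xx = np.meshgrid(g, g, g, indexing="ij")
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    shells = np.minimum(r.round().astype(int), D // 2)
    n_shell = D // 2 + 1
    num = np.zeros(n_shell)
    da = np.zeros(n_shell)
    db = np.zeros(n_shell)
    cross = (fa * np.conj(fb)).real
    np.add.at(num, shells.ravel(), cross.ravel())
    np.add.at(da, shells.ravel(), (np.abs(fa) ** 2).ravel())
    np.add.at(db, shells.ravel(), (np.abs(fb) ** 2).ravel())
    denom = np.sqrt(da * db)
    corr = np.divide(num, denom, out=np.ones_like(num), where=denom > 0)
    return FscCurve(np.arange(n_shell, dtype=float),
                    np.clip(corr, -1.0, 1.0))


def per_image_fsc(gt_maps, field, latents: np.ndarray, D: int,
                  gain: float = 1.0, subset: np.ndarray | None = None) -> FscCurve:
    """Mean FSC between each image's decoded map and its ground-truth map.

    ``gt_maps`` is either an (n_img,) sequence of maps or a callable
    index -> map; decoding renders the field at the image's latent.
    """
    from .volume_model import render_map

    n = latents.shape[0]
    idx = np.arange(n) if subset is None else np.asarray(subset)
    acc = None
    for i in idx:
        gt = gt_maps(i) if callable(gt_maps) else gt_maps[i]
        pred = render_map(field, latents[i], D, gain=gain)
        c = fsc(gt, pred)
        acc = c.correlation if acc is None else acc + c.correlation
    return FscCurve(np.arange(D // 2 + 1, dtype=float), acc / len(idx))


_MIRROR = np.diag([1.0, 1.0, -1.0])


def align_rotations(est: np.ndarray, ref: np.ndarray,
                    allow_flip: bool = False):
    """Globally align estimated to reference rotations.

    Candidate global rotations are {rᵢ⁻¹ Rᵢ} from the first min(N, 100)
    particles; the minimizer of the mean Frobenius distance ‖Rᵢ − rᵢ R‖
    wins.  Returns (R_align, per-particle geodesic errors in degrees after
    alignment).

    With ``allow_flip`` the mirror hand is also tried (reference set
    conjugated by diag(1, 1, −1)): projection data cannot distinguish a
    structure from its mirror image, so an ab initio run lands on either
    hand; evaluation against ground truth must try both.
    """
    est = np.asarray(est)
    ref = np.asarray(ref)
    if est.shape != ref.shape or est.ndim != 3:
        raise ValueError("expected matching (N, 3, 3) arrays")

    def _align(reference):
        n = est.shape[0]
        best = None
        for i in range(min(n, 100)):
            cand = est[i].T @ reference[i]
            aligned = np.einsum("nij,jk->nik", est, cand)
            cost = float(np.mean(np.linalg.norm(reference - aligned,
                                                axis=(1, 2))))
            if best is None or cost < best[0]:
                best = (cost, cand)
        return best

    best = _align(ref)
    used_ref = ref
    if allow_flip:
        mirr = np.einsum("ij,njk,kl->nil", _MIRROR, ref, _MIRROR)
        alt = _align(mirr)
        if alt[0] < best[0]:
            best = alt
            used_ref = mirr
    R_align = best[1]
    aligned = np.einsum("nij,jk->nik", est, R_align)
    errs = np.rad2deg(geodesic_angle(aligned, used_ref))
    if allow_flip:
        return R_align, errs, used_ref
    return R_align, errs


def _viewing_dir(R: np.ndarray) -> np.ndarray:
    """Unit viewing direction of a pose: third column of R (R ẑ).

    Rotations act on frequency coordinates as k ↦ R k, so the central-slice
    plane normal is R ẑ; the in-plane spin composes on the right (R Rz(ψ))
    and leaves this direction unchanged — which is exactly the invariance
    the out-of-plane/in-plane split requires.
    """
    return R[..., :, 2]


def decompose_errors(aligned_est: np.ndarray, ref: np.ndarray):
    """Split rotation errors into out-of-plane and in-plane parts (degrees).

    Out-of-plane: angle between viewing directions.  In-plane: wrapped
    difference of the ZYZ-intrinsic spin angle; near-degenerate views
    (viewing direction within ~0.1° of the pole of the Euler chart) fall
    back to the relative spin extracted from the residual quaternion.
    """
    aligned_est = np.asarray(aligned_est)
    ref = np.asarray(ref)
    va = _viewing_dir(aligned_est)
    vr = _viewing_dir(ref)
    dot = np.clip(np.sum(va * vr, axis=-1), -1.0, 1.0)
    oop = np.rad2deg(np.arccos(dot))

    ea = Rotation.from_matrix(aligned_est).as_euler("ZYZ")
    er = Rotation.from_matrix(ref).as_euler("ZYZ")
    dpsi = ea[..., 2] - er[..., 2]
    inp = np.rad2deg(np.abs((dpsi + np.pi) % (2 * np.pi) - np.pi))

    # gimbal fallback: beta ~ 0 makes the first/last Euler angles degenerate
    degen = (np.abs(ea[..., 1]) < np.deg2rad(0.1)) | \
            (np.abs(er[..., 1]) < np.deg2rad(0.1))
    if np.any(degen):
        rel = Rotation.from_matrix(
            np.einsum("nij,nkj->nik", aligned_est[degen], ref[degen]))
        angles = rel.magnitude()
        inp = np.asarray(inp)
        inp[degen] = np.rad2deg(angles)
    return oop, inp


def optimal_shift(est_t: np.ndarray, ref_T: np.ndarray, est_R: np.ndarray):
    """Solve for the unknown 3D origin shift behind 2D translation errors.

        u* = argmin_u Σ‖ Tᵢ − tᵢ − P rᵢ u ‖²,   P = [[1,0,0],[0,1,0]]

    by linear least squares; corrected translations tᵢ' = tᵢ + P rᵢ u* then
    minimize the residual against the reference (post-correction MSE ≤
    pre-correction MSE).  A rank-deficient system falls back to the
    minimum-norm solution and sets ``rank_deficient``.
    Returns (u*, corrected_t, rank_deficient flag).
    """
    est_t = np.asarray(est_t, dtype=np.float64)
    ref_T = np.asarray(ref_T, dtype=np.float64)
    est_R = np.asarray(est_R, dtype=np.float64)
    n = est_t.shape[0]
    if n < 2:
        raise ValueError("need at least two particles")
    P = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    A = np.einsum("ij,njk->nik", P, est_R).reshape(2 * n, 3)
    b = (ref_T - est_t).reshape(2 * n)
    u, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    corrected = est_t + np.einsum("ij,njk,k->ni", P, est_R, u)
    return u, corrected, rank < 3


def quaternion_loss(q: np.ndarray, q_prime: np.ndarray) -> float:
    """Double-cover-invariant rotation loss L(q, q') = 1 − (q·q')².

    0 for identical rotations (q' = ±q), 1 for orthogonal quaternions.
    Non-unit inputs are normalized.
    """
    q = np.asarray(q, dtype=np.float64)
    qp = np.asarray(q_prime, dtype=np.float64)
    nq, nqp = np.linalg.norm(q), np.linalg.norm(qp)
    if abs(nq - 1.0) > 1e-6 or abs(nqp - 1.0) > 1e-6:
        import warnings

        warnings.warn("non-unit quaternion input; normalizing", stacklevel=2)
    q = q / nq
    qp = qp / nqp
    return float(1.0 - np.dot(q, qp) ** 2)
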