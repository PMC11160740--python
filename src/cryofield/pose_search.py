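"""Hierarchical pose search (HPS) over SO(3) × R².

Orientations are gridded with the Hopf-fibration product of a HEALPix sphere
grid (viewing direction) and a regular circle grid (in-plane spin): the base
level uses nside 4 (192 sphere pixels) × 24 spins at 15° spacing = 4,608
rotations, paired with 49 translations on a 7×7 grid spanning [-10, +10] px.

Search proceeds by exhaustive evaluation of the band-limited reprojection
error on the base grid, keeping the top 8 rotations, then five local
refinement rounds; each round scores the 8 HEALPix/spin children of every
kept rotation at half the angular spacing, with the translation grid extent
halved and recentered on the incumbent shift.  All ties break by
(error, node id), making the search bitwise deterministic.

Images are band-limited during search with a hard radial mask at a cutoff
that ramps linearly from k_min = 6 to k_max = 16 cycles per image length
over the duration of the search phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import healpix
from .forward_model import (
    FrequencyLattice,
    GriddedHartleyVolume,
    Pose,
    dht,
    translate_hartley,
)

__all__ = [
    "BASE_NSIDE",
    "N_PSI_BASE",
    "PSI_SPACING_DEG",
    "TRANSLATION_EXTENT",
    "N_REFINEMENT_ROUNDS",
    "TOP_K",
    "BandLimitSchedule",
    "SearchGrid",
    "base_grid",
    "node_rotation",
    "refine_candidates",
    "cutoff_at",
    "reprojection_error",
    "hps",
    "hps_tilt",
]

BASE_NSIDE = 4
N_PSI_BASE = 24
PSI_SPACING_DEG = 15.0
TRANSLATION_EXTENT = 10.0  # px, half-width of the base 7x7 grid
N_TRANS_SIDE = 7
N_REFINEMENT_ROUNDS = 5  # 1 base-adjacent + "4 additional steps"
TOP_K = 8


@dataclass(frozen=True)
class BandLimitSchedule:
    """Linear ramp of the radial frequency cutoff during the search phase."""

    k_min: int = 6
    k_max: int = 16
    phase_length: int = 500_000  # images

    def __post_init__(self):
        if self.k_min > self.k_max or self.phase_length <= 0:
            raise ValueError("invalid band-limit schedule")


def cutoff_at(images_processed: int, schedule: BandLimitSchedule) -> int:
    """Cutoff (cycles/image length) after a given number of processed images."""
    if images_processed < 0:
        raise ValueError("images_processed must be non-negative")
    frac = min(1.0, images_processed / schedule.phase_length)
    return int(round(schedule.k_min + (schedule.k_max - schedule.k_min) * frac))


# --------------------------------------------------------------------------
# grids
# --------------------------------------------------------------------------

def _psi_offset(level: int) -> float:
    """Index offset of the spin grid at a refinement level (0 at base)."""
    off = 0.0
    for _ in range(level):
        off = 2.0 * off - 0.5
    return off


def _psi_value(level: int, psi_idx: np.ndarray) -> np.ndarray:
    spacing = PSI_SPACING_DEG / (2**level)
    return np.deg2rad((np.asarray(psi_idx, dtype=np.float64) + _psi_offset(level)) * spacing)


def node_rotation(level: int, pix, psi_idx) -> np.ndarray:
    """Rotation matrices R = Rz(φ) Ry(θ) Rz(ψ) for grid nodes at a level."""
    nside = BASE_NSIDE * (2**level)
    pix = np.atleast_1d(np.asarray(pix, dtype=np.int64))
    theta, phi = healpix.nest2ang(nside, pix)
    psi = np.atleast_1d(_psi_value(level, psi_idx))
    ct, st = np.cos(theta), np.sin(theta)
    cf, sf = np.cos(phi), np.sin(phi)
    cp, sp = np.cos(psi), np.sin(psi)
    n = pix.shape[0]
    R = np.empty((n, 3, 3))
    # Rz(phi) @ Ry(theta) @ Rz(psi)
    R[:, 0, 0] = cf * ct * cp - sf * sp
    R[:, 0, 1] = -cf * ct * sp - sf * cp
    R[:, 0, 2] = cf * st
    R[:, 1, 0] = sf * ct * cp + cf * sp
    R[:, 1, 1] = -sf * ct * sp + cf * cp
    R[:, 1, 2] = sf * st
    R[:, 2, 0] = -st * cp
    R[:, 2, 1] = st * sp
    R[:, 2, 2] = ct
    return R


def _node_id(level: int, pix: np.ndarray, psi_idx: np.ndarray) -> np.ndarray:
    n_psi = N_PSI_BASE * (2**level)
    return pix * n_psi + (psi_idx % n_psi)


def _translation_grid(center: np.ndarray, extent: float) -> np.ndarray:
    """7×7 translation offsets around ``center`` with half-width ``extent``."""
    g = np.linspace(-extent, extent, N_TRANS_SIDE)
    ty, tx = np.meshgrid(g, g, indexing="ij")
    return np.stack([tx.ravel(), ty.ravel()], axis=1) + np.asarray(center)


@dataclass
class SearchGrid:
    """Candidate nodes of one search level."""

    level: int
    pix: np.ndarray
    psi_idx: np.ndarray
    rotations: np.ndarray
    translations: np.ndarray

    @property
    def n_rotations(self) -> int:
        return self.rotations.shape[0]

    @property
    def n_translations(self) -> int:
        return self.translations.shape[0]

    @property
    def psi_spacing_deg(self) -> float:
        return PSI_SPACING_DEG / (2**self.level)

    @property
    def translation_extent(self) -> float:
        return TRANSLATION_EXTENT / (2**self.level)


def base_grid() -> SearchGrid:
    """Level-0 grid: 4,608 rotations (192 HEALPix × 24 spins) × 49 shifts."""
    n_pix = healpix.npix(BASE_NSIDE)
    pix = np.repeat(np.arange(n_pix, dtype=np.int64), N_PSI_BASE)
    psi = np.tile(np.arange(N_PSI_BASE, dtype=np.int64), n_pix)
    return SearchGrid(
        level=0,
        pix=pix,
        psi_idx=psi,
        rotations=node_rotation(0, pix, psi),
        translations=_translation_grid(np.zeros(2), TRANSLATION_EXTENT),
    )


def refine_candidates(node: tuple[int, int], level: int):
    """The 8 children of a rotation node: 4 HEALPix sub-pixels × 2 half-spins.

    ``node`` is (pix, psi_idx) at ``level``; children live at level + 1.
    Returns (pix_children, psi_children, rotations).
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    pix, psi = node
    cp = 4 * pix + np.arange(4, dtype=np.int64)
    cs = 2 * psi + np.arange(2, dtype=np.int64)
    pix_c = np.repeat(cp, 2)
    psi_c = np.tile(cs, 4)
    return pix_c, psi_c, node_rotation(level + 1, pix_c, psi_c)


# --------------------------------------------------------------------------
# scoring
# --------------------------------------------------------------------------

class _SliceSource:
    """Uniform slicing interface over a gridded volume or a neural field."""

    def __init__(self, source, z, D: int, cutoff: int):
        self.D = D
        if isinstance(source, GriddedHartleyVolume):
            self.vol = source
        elif hasattr(source, "evaluate"):  # neural field: rasterize the band
            from .volume_model import VolumeField  # local to avoid cycle

            assert isinstance(source, VolumeField)
            lat3 = FrequencyLattice(D, ndim=3)
            coords = lat3.coords.reshape(-1, 3)
            rad = np.linalg.norm(coords, axis=1) * D
            sel = rad <= min(cutoff + 3, D)  # interpolation margin
            grid = np.zeros(D**3, dtype=np.float64)
            grid[sel] = source.evaluate(z, coords[sel])
            self.vol = GriddedHartleyVolume(grid.reshape(D, D, D))
        else:
            self.vol = GriddedHartleyVolume(np.asarray(source, dtype=np.float64))

    def slices(self, rotations: np.ndarray, k2d: np.ndarray, order: int) -> np.ndarray:
        """Band-limited slices for a batch of rotations.

        ``k2d``: (n_k, 3) in-plane frequency coords (kz = 0); returns
        (n_R, n_k).  ``order`` selects linear (coarse, exhaustive stage) or
        cubic (refinement) interpolation.
        """
        pts = np.einsum("rij,kj->rki", rotations, k2d)
        D = self.D
        idx = np.stack(
            [
                D / 2 + D * pts[..., 2],
                D / 2 + D * pts[..., 1],
                D / 2 + D * pts[..., 0],
            ]
        )
        src = self.vol._filtered if order > 1 else self.vol._ext
        vals = ndimage.map_coordinates(
            src, idx.reshape(3, -1), order=order, prefilter=False,
            mode="constant", cval=0.0,
        )
        return vals.reshape(rotations.shape[0], k2d.shape[0])


_N_POLAR_ANGLES = N_PSI_BASE  # ring sampling commensurate with the spin grid


def _polar_band(cutoff: int):
    """Ring sampling of the band: radii 1..cutoff × 24 angles.

    Returns (points (n, 2) in grid units — cycles per image length —,
    per-point quadrature weights matching the lattice point density
    2πr/24, and the (24, n) roll-index table mapping spin m to sample
    positions).
    """
    radii = np.arange(1, cutoff + 1)
    ang = np.deg2rad(np.arange(_N_POLAR_ANGLES) * PSI_SPACING_DEG)
    rr, aa = np.meshgrid(radii, ang, indexing="ij")
    pts = np.stack([rr * np.cos(aa), rr * np.sin(aa)], axis=-1)
    n = pts.reshape(-1, 2)
    weights = np.repeat(2.0 * np.pi * radii / _N_POLAR_ANGLES, _N_POLAR_ANGLES)
    base = np.arange(cutoff)[:, None] * _N_POLAR_ANGLES
    j = np.arange(_N_POLAR_ANGLES)[None, :]
    roll = np.stack([(base + (j + m) % _N_POLAR_ANGLES).reshape(-1)
                     for m in range(_N_POLAR_ANGLES)])
    return n, weights, roll


def _sample_image_polar(arr: np.ndarray, polar_pts: np.ndarray) -> np.ndarray:
    """Bilinear sampling of a centered D×D frequency array at ring points.

    ``polar_pts`` are in grid units (cycles per image length); the array is
    periodically extended so the Nyquist ring stays in bounds.
    """
    D = arr.shape[-1]
    ext = np.pad(arr, [(0, 1), (0, 1)], mode="wrap")
    idx = np.stack([D / 2 + polar_pts[:, 1], D / 2 + polar_pts[:, 0]])
    return ndimage.map_coordinates(ext, idx, order=1, mode="constant", cval=0.0)


def _polar_translated_refs(hp: np.ndarray, polar_pts: np.ndarray, D: int,
                           translations: np.ndarray) -> np.ndarray:
    """T_{-t} H(I) evaluated on the ring samples for each candidate shift.

    Uses the antipodal ring sample for H(−k); exact because the ring grid
    contains its own negation (angle + 180°).
    """
    n_ang = _N_POLAR_ANGLES
    n = hp.shape[0]
    anti = (np.arange(n) // n_ang) * n_ang + (np.arange(n) + n_ang // 2) % n_ang
    hneg = hp[anti]
    theta = 2.0 * np.pi * (translations @ (polar_pts.T / D))  # (n_t, n)
    return np.cos(theta) * hp - np.sin(theta) * hneg


def _mask_and_coords(lattice: FrequencyLattice, cutoff: int):
    rad = lattice.radius()
    mask = rad <= cutoff
    c2 = lattice.coords[mask]
    k2d = np.concatenate([c2, np.zeros((c2.shape[0], 1))], axis=1)
    return mask, k2d


def reprojection_error(image: np.ndarray, source, z, pose: Pose,
                       ctf_array: np.ndarray | None, cutoff: int | None,
                       gain: float = 1.0) -> float:
    """Band-limited squared residual ‖H(I) − Ĉ ⊙ T_t S_R V̂‖² for one pose.

    Computed exactly (direct field evaluation or cubic slicing), over
    lattice points with |k| ≤ cutoff in cycles per image length;
    ``cutoff=None`` selects the full sub-Nyquist band |k| < D/2 used by the
    training loss, making the two quantities identical there.
    """
    D = image.shape[-1]
    lattice = FrequencyLattice(D, ndim=2)
    from .forward_model import slice_volume

    s = np.sqrt(D) * gain * slice_volume(source, pose.rotation, lattice=lattice, z=z)
    s = translate_hartley(s, pose.translation, lattice)
    if ctf_array is not None:
        s = s * ctf_array
    h = dht(image)
    rad = lattice.radius()
    mask = rad < D / 2 if cutoff is None else rad <= cutoff
    r = (h - s)[mask]
    return float(np.dot(r, r))


def _translated_references(h_m: np.ndarray, hneg_m: np.ndarray,
                           k_pix: np.ndarray,
                           translations: np.ndarray) -> np.ndarray:
    """T_{-t} H(I) on the band, one row per candidate shift.

    ``h_m``/``hneg_m`` are the masked Hartley image and its −k partner;
    ``k_pix`` the masked frequency coords in cycles/pixel.
    """
    theta = 2.0 * np.pi * (np.atleast_2d(translations) @ k_pix.T)
    return np.cos(theta) * h_m - np.sin(theta) * hneg_m


def _score(cs: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """Squared errors (n_R, n_t) from slices×CTF (n_R, n_k) and references."""
    e = -2.0 * (cs @ refs.T)
    e += np.sum(cs * cs, axis=1)[:, None]
    e += np.sum(refs * refs, axis=1)[None, :]
    return e


def hps(image: np.ndarray, source, z, ctf_array: np.ndarray | None,
        cutoff: int, gain: float = 1.0) -> Pose:
    """Hierarchical search for the pose minimizing the reprojection error.

    Exhaustive scoring of the 4,608 × 49 base grid followed by
    ``N_REFINEMENT_ROUNDS`` top-8 refinement rounds; returns the best pose
    seen anywhere in the search (rotation and translation).
    """
    return _hps_multi([image], source, z,
                      [ctf_array], [np.eye(3)], cutoff, gain)


def hps_tilt(subtilt_images, source, z, ctf_arrays, tilt_rotations,
             cutoff: int, gain: float = 1.0) -> Pose:
    """Tilt-constrained HPS: one particle pose scored against J subtilts.

    Each candidate particle pose φ is composed with the known tilt scheme,
    φ_ij = tilt_rotation_j ∘ φ, and the per-subtilt errors are summed
    (the in-plane shift is shared across subtilts during search).
    """
    J = len(subtilt_images)
    if not (len(ctf_arrays) == len(tilt_rotations) == J):
        raise ValueError("inconsistent subtilt count across images/CTFs/tilts")
    return _hps_multi(list(subtilt_images), source, z, list(ctf_arrays),
                      [np.asarray(Rt) for Rt in tilt_rotations], cutoff, gain)


def _hps_multi(images, source, z, ctf_arrays, tilt_rotations,
               cutoff: int, gain: float) -> Pose:
    D = images[0].shape[-1]
    lattice = FrequencyLattice(D, ndim=2)
    mask, k2d = _mask_and_coords(lattice, cutoff)
    scale = np.sqrt(D) * gain
    src = _SliceSource(source, z, D, cutoff)

    ctfs = [np.ones(int(mask.sum())) if c is None else np.asarray(c)[mask]
            for c in ctf_arrays]
    hs = [dht(np.asarray(img, dtype=np.float64)) for img in images]
    # masked observations and their -k partners, for vectorized shifts
    py, px = lattice.neg_index()[:2]
    k_pix = lattice.coords[mask]
    h_ms = [h[mask] for h in hs]
    hneg_ms = [h[py[:, None], px[None, :]][mask] for h in hs]

    grid = base_grid()
    n_rot = grid.n_rotations

    # ---- base stage: polar-ring scoring of the exhaustive grid ----------
    # Slices for the 24 in-plane spins of one viewing direction are
    # index-rolls of a single ring sampling of that direction's plane, so
    # only 192 planes are interpolated; ring weights reproduce the lattice
    # point density.  The stage ranks candidates; kept nodes are re-scored
    # on the lattice metric used by the refinement rounds.
    trans0 = _translation_grid(np.zeros(2), TRANSLATION_EXTENT)
    err = np.zeros((n_rot, trans0.shape[0]))
    polar, weights, roll_idx = _polar_band(cutoff)
    dirs = node_rotation(0, np.arange(healpix.npix(BASE_NSIDE)),
                         np.zeros(healpix.npix(BASE_NSIDE), dtype=np.int64))
    sqw = np.sqrt(weights)
    for h, ctf_m_full, Rt in zip(hs, [np.asarray(c) if c is not None else None
                                      for c in ctf_arrays], tilt_rotations):
        hp = _sample_image_polar(h, polar)
        cp = (np.ones_like(hp) if ctf_m_full is None
              else _sample_image_polar(ctf_m_full, polar))
        refs = _polar_translated_refs(hp, polar, D, trans0) * sqw
        planes = np.einsum("ij,rjk->rik", Rt, dirs)
        k3 = np.concatenate([polar / D, np.zeros((polar.shape[0], 1))], axis=1)
        pv = src.slices(planes, k3, order=1)  # (192, n_polar)
        cs_all = pv[:, roll_idx].reshape(n_rot, polar.shape[0])
        cs_all = cs_all * (scale * cp * sqw)
        err += _score(cs_all, refs)

    best_t_idx = np.argmin(err, axis=1)
    rot_err = err[np.arange(n_rot), best_t_idx]
    ids = _node_id(0, grid.pix, grid.psi_idx)
    order_keys = np.lexsort((ids, rot_err))
    keep = order_keys[:TOP_K]

    best = None  # (error, node_id, Pose)

    def consider(e, nid, R, t):
        nonlocal best
        key = (e, int(nid))
        if best is None or key < (best[0], best[1]):
            best = (e, int(nid), Pose(R, t))

    # re-score the kept nodes on the lattice metric for a commensurate
    # global-best comparison with the refinement rounds
    for j in keep:
        e_lat = 0.0
        for hm, hn, ctf_m, Rt in zip(h_ms, hneg_ms, ctfs, tilt_rotations):
            refs1 = _translated_references(hm, hn, k_pix,
                                           trans0[best_t_idx[j]][None])
            rot1 = (Rt @ grid.rotations[j])[None]
            cs1 = src.slices(rot1, k2d, order=3) * (scale * ctf_m)
            e_lat += float(_score(cs1, refs1)[0, 0])
        consider(e_lat, ids[j], grid.rotations[j], trans0[best_t_idx[j]])

    # ---- refinement rounds ---------------------------------------------
    parents = [((int(grid.pix[j]), int(grid.psi_idx[j])),
                trans0[best_t_idx[j]]) for j in keep]
    for level in range(N_REFINEMENT_ROUNDS):
        cand_pix, cand_psi, cand_rot, cand_tgrid = [], [], [], []
        for (node, t_center) in parents:
            pc, sc, rc = refine_candidates(node, level)
            cand_pix.append(pc)
            cand_psi.append(sc)
            cand_rot.append(rc)
            cand_tgrid.append(
                _translation_grid(t_center, TRANSLATION_EXTENT / (2 ** (level + 1)))
            )
        pix_all = np.concatenate(cand_pix)
        psi_all = np.concatenate(cand_psi)
        rot_all = np.concatenate(cand_rot)
        n_cand = rot_all.shape[0]
        n_t = cand_tgrid[0].shape[0]
        err = np.zeros((n_cand, n_t))
        for hm, hn, ctf_m, Rt in zip(h_ms, hneg_ms, ctfs, tilt_rotations):
            rots = np.einsum("ij,rjk->rik", Rt, rot_all)
            cs = src.slices(rots, k2d, order=3) * (scale * ctf_m)
            for gi, tg in enumerate(cand_tgrid):
                refs = _translated_references(hm, hn, k_pix, tg)
                blk = slice(gi * TOP_K, (gi + 1) * TOP_K)
                err[blk] += _score(cs[blk], refs)

        tgrid_all = np.stack(cand_tgrid)  # (TOP_K, n_t, 2)
        bt = np.argmin(err, axis=1)
        re = err[np.arange(n_cand), bt]
        ids_l = _node_id(level + 1, pix_all, psi_all)
        order_keys = np.lexsort((ids_l, re))
        keep = order_keys[:TOP_K]
        parents = []
        for j in keep:
            t_best = tgrid_all[j // TOP_K, bt[j]]
            consider(re[j], ids_l[j], rot_all[j], t_best)
            parents.append(((int(pix_all[j]), int(psi_all[j])), t_best))

    return best[2]
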