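"""Joint optimization of volume, poses and conformations (autodecoder).

The objective is the Hartley-space reconstruction error

    L(θ, {φ_i}, {z_i}) = Σ_i ‖ H(I_i) − Ĉ_i ⊙ T_{t_i} S_{R_i} V̂_θ(z_i) ‖²

minimized in three phases:

1. **pretrain** — decoder weights θ only, with poses drawn once uniformly
   over SO(3) (translations zero) and latents frozen at their Gaussian
   init; 10,000 image visits by default, Adam lr 1e-4, batch 32.  A single
   global intensity gain between the decoder output and the normalized
   images is fitted in closed form during this phase and frozen afterwards.
2. **hierarchical pose search (HPS)** — per batch, each image's pose is
   re-estimated by grid search against the current decoder, then θ
   (lr 1e-4) and the per-image latents (lr 1e-2) take an Adam step; batch
   8, until max(2N, 5×10⁵) image visits by default.  The search band-limit
   ramps linearly from k_min = 6 to k_max = 16 cycles/image over the phase.
3. **pose SGD** — poses become free parameters (rotations via the
   6-parameter two-row representation, translations as raw pixel shifts)
   optimized jointly with θ and z; Adam lr 1e-3 for poses, batch 256.

The tilt-series (subtomogram averaging) variant ties the J subtilts of a
particle to one pose during HPS via the known tilt scheme, resamples
latents from N(0, 0.1²) per epoch for the first 50,000 particle visits,
and relaxes to an independent pose per subtilt during SGD (lr 1e-5,
batch 32).

The loss residual is restricted to the open in-band disk |k| < Nyquist
(corners and the Nyquist ring excluded), where the translation operator is
exactly orthogonal.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.spatial.transform import Rotation

from .forward_model import FrequencyLattice, dht, eval_ctf, tilt_weights
from .io_formats import ParticleStack
from .nn import Adam
from .pose_search import BandLimitSchedule, cutoff_at, hps, hps_tilt
from .rotations import matrix_to_rot6d, rot6d_backward, rot6d_to_matrix
from .simulate import tilt_rotation
from .volume_model import (
    FEATURE_DIM,
    N_BASE_FREQUENCIES,
    ConformationTable,
    VolumeField,
)

__all__ = ["TrainConfig", "TrainState", "loss", "pretrain", "train_spa",
           "train_sta"]

_CHUNK = 32  # images per gradient micro-batch (memory ceiling)


@dataclass
class TrainConfig:
    """Schedule and hyper-parameters of a training run.

    Defaults are the standard single-particle settings; tests and small
    runs shrink the phase lengths, never the model.
    """

    n_images: int
    d: int = 8
    seed: int = 0
    pretrain_images: int = 10_000
    hps_images: int | None = None  # default max(2N, 5e5)
    sgd_images: int | None = None  # extent of phase 3; default 2N
    lr_field: float = 1e-4
    lr_latent: float = 1e-2
    lr_pose: float = 1e-3
    batch_pretrain: int = 32
    batch_hps: int = 8
    batch_sgd: int = 256
    k_min: int = 6
    k_max: int = 16
    # tilt-series settings
    n_tilts: int = 11
    lr_pose_sta: float = 1e-5
    batch_sgd_sta: int = 32
    hps_particles: int | None = None  # default max(2N, 1.5e5)
    sta_resample_particles: int = 50_000
    freq_subsample: float = 1.0  # fraction of band coords sampled per step
    z_delay_images: int = 0  # HPS visits before latents start optimizing
    log_path: str | None = None
    log_interval: int = 512

    def __post_init__(self):
        if self.hps_images is None:
            self.hps_images = max(2 * self.n_images, 500_000)
        if self.sgd_images is None:
            self.sgd_images = 2 * self.n_images
        if min(self.pretrain_images, self.hps_images, self.sgd_images) < 0:
            raise ValueError("phase lengths must be non-negative")
        if self.hps_images < self.n_images:
            raise ValueError("HPS phase must visit every image at least once")


@dataclass
class TrainState:
    """Everything the optimizer touches, plus progress counters."""

    field: VolumeField
    latents: ConformationTable
    rotations: np.ndarray  # (N, 3, 3)
    translations: np.ndarray  # (N, 2)
    gain: float = 1.0
    images_processed: int = 0
    phase: str = "pretrain"
    pose_params: np.ndarray | None = None  # (N, 6), SGD phase
    history: list = dc_field(default_factory=list)


class _PerRowAdam:
    """Adam over rows of a table, stepping only the rows in each batch."""

    def __init__(self, table: np.ndarray, lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.table = table
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = np.zeros_like(table)
        self.v = np.zeros_like(table)
        self.t = np.zeros(table.shape[0], dtype=np.int64)

    def step(self, rows: np.ndarray, grads: np.ndarray) -> None:
        self.t[rows] += 1
        t = self.t[rows][:, None] if self.table.ndim == 2 else \
            self.t[rows].reshape(-1, *([1] * (self.table.ndim - 1)))
        self.m[rows] = self.b1 * self.m[rows] + (1 - self.b1) * grads
        self.v[rows] = self.b2 * self.v[rows] + (1 - self.b2) * grads * grads
        mh = self.m[rows] / (1 - self.b1**t)
        vh = self.v[rows] / (1 - self.b2**t)
        self.table[rows] -= self.lr * mh / (np.sqrt(vh) + self.eps)


# --------------------------------------------------------------------------
# loss machinery
# --------------------------------------------------------------------------

class _Bands:
    """Cached in-band lattice data and per-image Hartley observations."""

    def __init__(self, stack: ParticleStack):
        D = stack.D
        self.D = D
        lat = FrequencyLattice(D, ndim=2)
        rad = lat.radius()
        self.mask = rad < D / 2  # open disk; Nyquist ring excluded
        c2 = lat.coords[self.mask]
        self.k2d = np.concatenate(
            [c2, np.zeros((c2.shape[0], 1))], axis=1
        ).astype(np.float32)
        py, px = lat.neg_index()[:2]
        h = dht(stack.images.astype(np.float64), axes=(1, 2))
        hneg = h[:, py[:, None], px[None, :]]
        self.h = np.ascontiguousarray(h[:, self.mask], dtype=np.float32)
        self.hneg = np.ascontiguousarray(hneg[:, self.mask], dtype=np.float32)
        self.scale = np.sqrt(D)

    def ctf_rows(self, stack: ParticleStack, pixel_size: float) -> np.ndarray:
        lat = FrequencyLattice(self.D, ndim=2)
        rows = np.empty((stack.n_images, int(self.mask.sum())), dtype=np.float32)
        full = np.empty((stack.n_images, self.D, self.D), dtype=np.float64)
        for i in range(stack.n_images):
            if stack.tilt is not None:
                c = tilt_weights(stack.ctf[i], stack.tilt[i], lat, pixel_size)
            else:
                c = eval_ctf(stack.ctf[i], lat, pixel_size)
            rows[i] = c[self.mask]
            full[i] = c
        self.ctf_full = full
        return rows


def _translated_obs(bands: _Bands, idx: np.ndarray, trans: np.ndarray,
                    sel=None):
    """T_{-t} H(I) on the band for a batch, plus the phase pieces for ∂/∂t."""
    k = bands.k2d[:, :2] if sel is None else bands.k2d[sel][:, :2]
    theta = 2.0 * np.pi * (trans.astype(np.float32) @ k.T)  # (B, n_k)
    ct, st = np.cos(theta), np.sin(theta)
    if sel is None:
        h, hneg = bands.h[idx], bands.hneg[idx]
    else:
        h, hneg = bands.h[np.ix_(idx, sel)], bands.hneg[np.ix_(idx, sel)]
    y = ct * h - st * hneg
    dy_dtheta = -st * h - ct * hneg
    return y, dy_dtheta


def _batch_residuals(bands: _Bands, ctf_rows, idx, rotations, trans, z,
                     sel=None):
    """Model and residual for a batch; returns pieces reused by backprop.

    ``sel`` optionally restricts the loss sum to a subset of band
    coordinates (stochastic frequency minibatching for scaled-down runs).
    """
    k2d = bands.k2d if sel is None else bands.k2d[sel]
    n_k = k2d.shape[0]
    pts = np.einsum("bij,kj->bki", rotations, k2d.astype(np.float64))
    coords = pts.reshape(-1, 3).astype(np.float32)
    zb = np.repeat(z.astype(np.float32), n_k, axis=0)
    y, dy_dtheta = _translated_obs(bands, idx, trans, sel)
    c = ctf_rows[idx] if sel is None else ctf_rows[np.ix_(idx, sel)]
    return coords, zb, y, dy_dtheta, c, k2d


def loss(field: VolumeField, gain: float, stack: ParticleStack,
         bands: _Bands, ctf_rows: np.ndarray, idx: np.ndarray,
         rotations: np.ndarray, trans: np.ndarray, z: np.ndarray) -> float:
    """Eq-for-eq batch loss: Σ_i ‖T_{−t_i} H(I_i) − Ĉ_i ⊙ S_{R_i} V̂(z_i)‖².

    Equals the sum of band-limited reprojection errors of the batch at the
    full (sub-Nyquist) band.
    """
    total = 0.0
    n_k = bands.k2d.shape[0]
    for lo in range(0, len(idx), _CHUNK):
        sl = slice(lo, lo + _CHUNK)
        coords, zb, y, _, c, _ = _batch_residuals(
            bands, ctf_rows, idx[sl], rotations[sl], trans[sl], z[sl])
        s = field.evaluate(zb, coords).reshape(-1, n_k)
        model = gain * bands.scale * c * s
        r = y - model
        total += float(np.sum(r.astype(np.float64) ** 2))
    return total


def _grad_step(field, gain, bands, ctf_rows, idx, rotations, trans, z,
               want_pose_grads: bool, sel=None):
    """Loss + gradients for one batch (chunked).

    Returns (loss, field_grads, z_grads, rot_mat_grads, trans_grads).
    ``sel`` restricts the residual sum to a band-coordinate subset.
    """
    n_k = bands.k2d.shape[0] if sel is None else len(sel)
    total = 0.0
    fg = None
    zg = np.zeros_like(z, dtype=np.float32)
    rg = np.zeros((len(idx), 3, 3)) if want_pose_grads else None
    tg = np.zeros((len(idx), 2), dtype=np.float32) if want_pose_grads else None
    for lo in range(0, len(idx), _CHUNK):
        sl = slice(lo, lo + min(_CHUNK, len(idx) - lo))
        B = len(idx[sl])
        coords, zb, y, dy_dtheta, c, k2d = _batch_residuals(
            bands, ctf_rows, idx[sl], rotations[sl], trans[sl], z[sl], sel)
        sc = np.float32(gain * bands.scale)
        # forward+backward through the field
        # upstream: dL/ds = -2 * sc * c * r
        sflat, cache = field.mlp.forward(
            field._assemble(zb, coords), want_cache=True)
        oob = np.any(np.abs(coords) > 0.5, axis=1)
        if oob.any():
            sflat = np.where(oob, np.float32(0.0), sflat)
        s = sflat.reshape(B, n_k)
        model = sc * c * s
        r = y - model
        total += float(np.sum(r.astype(np.float64) ** 2))
        gs = (-2.0 * sc) * (c * r)  # dL/ds, (B, n_k)
        gflat = gs.reshape(-1)
        if oob.any():
            gflat = np.where(oob, np.float32(0.0), gflat)
        grads, gx = field.mlp.backward(cache, gflat)
        if fg is None:
            fg = grads
        else:
            for k in fg:
                fg[k] += grads[k]
        gfeat = gx[:, :FEATURE_DIM]
        zg[sl] += gx[:, FEATURE_DIM:].reshape(B, n_k, -1).sum(axis=1)
        if want_pose_grads:
            ang = 2.0 * np.pi * (coords @ field.B_scaled.T)
            gsin = gfeat[:, :N_BASE_FREQUENCIES] * np.cos(ang)
            gcos = gfeat[:, N_BASE_FREQUENCIES:] * np.sin(ang)
            gcoords = 2.0 * np.pi * ((gsin - gcos) @ field.B)  # (B*n_k, 3)
            gc = gcoords.reshape(B, n_k, 3).astype(np.float64)
            # pts = R @ k for each row: dL/dR = Σ_k outer(dL/dpt, k)
            rg[sl] += np.einsum("bki,bkj->bij", gc,
                                np.broadcast_to(k2d.astype(np.float64),
                                                (B, n_k, 3)))
            # translation: dL/dy = 2 r ; y depends on t via theta = 2π t·k
            dldtheta = 2.0 * r * dy_dtheta  # (B, n_k)
            tg[sl] += 2.0 * np.pi * (dldtheta @ k2d[:, :2])
    return total, fg, zg, rg, tg


# --------------------------------------------------------------------------
# phases
# --------------------------------------------------------------------------

def _band_sampler(cfg: TrainConfig, bands: _Bands, seed_offset: int):
    """Per-step random subsets of band coordinates (scaled-run loss minibatch).

    Returns a callable yielding index arrays, or one yielding None when the
    full band is used (freq_subsample = 1).
    """
    n_k = bands.k2d.shape[0]
    m = int(round(cfg.freq_subsample * n_k))
    if m >= n_k:
        return lambda: None
    rng = np.random.default_rng(cfg.seed + seed_offset)
    return lambda: np.sort(rng.choice(n_k, m, replace=False))


def _log(state: TrainState, cfg: TrainConfig, record: dict) -> None:
    record = {"images_processed": state.images_processed,
              "phase": state.phase, "time": time.time(), **record}
    state.history.append(record)
    if cfg.log_path:
        with open(cfg.log_path, "a") as fh:
            fh.write(json.dumps(record) + "\n")


def init_state(stack: ParticleStack, cfg: TrainConfig) -> TrainState:
    field = VolumeField(cfg.d, cfg.seed, coord_scale=stack.D / 4)
    n_part = stack.n_particles if stack.tilt is not None else stack.n_images
    latents = ConformationTable(n_part, cfg.d, cfg.seed + 1)
    N = stack.n_images
    rot = np.broadcast_to(np.eye(3), (N, 3, 3)).copy()
    return TrainState(field=field, latents=latents, rotations=rot,
                      translations=np.zeros((N, 2)))


def pretrain(state: TrainState, stack: ParticleStack, cfg: TrainConfig,
             bands: _Bands, ctf_rows: np.ndarray,
             opt_field: Adam) -> None:
    """Phase 1: fit θ against fixed random poses and frozen latents."""
    rng = np.random.default_rng(cfg.seed + 10)
    N = stack.n_images
    subset = np.arange(min(N, cfg.pretrain_images))
    fixed_rot = Rotation.random(
        len(subset), random_state=np.random.RandomState(cfg.seed + 11)
    ).as_matrix()
    fixed_t = np.zeros((len(subset), 2))
    state.phase = "pretrain"
    pe_idx = (
        stack.particle_index if stack.tilt is not None
        else np.arange(N)
    )
    visits = 0
    pos = 0
    run_loss = []
    sample_band = _band_sampler(cfg, bands, 40)
    while visits < cfg.pretrain_images:
        take = min(cfg.batch_pretrain, cfg.pretrain_images - visits)
        sel = (pos + np.arange(take)) % len(subset)
        pos = (pos + take) % len(subset)
        idx = subset[sel]
        z = state.latents.z[pe_idx[idx]]
        rot = fixed_rot[sel]
        tr = fixed_t[sel]
        bsel = sample_band()
        lval, fg, _, _, _ = _grad_step(
            state.field, state.gain, bands, ctf_rows, idx, rot, tr, z,
            want_pose_grads=False, sel=bsel)
        opt_field.step(fg)
        visits += take
        state.images_processed += take
        run_loss.append(lval / take)
        if visits % cfg.log_interval < take:
            _log(state, cfg, {"loss_per_image": float(np.mean(run_loss[-10:]))})
    if run_loss:
        _log(state, cfg, {"loss_per_image": float(np.mean(run_loss[-10:]))})
    # single closed-form least-squares fit of the global intensity gain at
    # the end of the phase; frozen for the rest of the run.  (Refitting per
    # batch lets the decoder scale and the gain drift in opposite
    # directions, which is numerically legal but useless.)
    fit_n = min(len(subset), 8 * cfg.batch_pretrain)
    idx = subset[:fit_n]
    rot = fixed_rot[:fit_n]
    n_k = bands.k2d.shape[0]
    num = den = 0.0
    for lo in range(0, fit_n, _CHUNK):
        sl = slice(lo, lo + _CHUNK)
        pts = np.einsum("bij,kj->bki", rot[sl], bands.k2d.astype(np.float64))
        zc = state.latents.z[pe_idx[idx[sl]]]
        sv = state.field.evaluate(
            np.repeat(zc, n_k, axis=0), pts.reshape(-1, 3)
        ).reshape(len(idx[sl]), n_k)
        cs = bands.scale * ctf_rows[idx[sl]] * sv
        y, _ = _translated_obs(bands, idx[sl], fixed_t[sl])
        num += float(np.sum(cs.astype(np.float64) * y.astype(np.float64)))
        den += float(np.sum(cs.astype(np.float64) ** 2))
    if den > 1e-12:
        state.gain = num / den


def _hps_phase_spa(state, stack, cfg, bands, ctf_rows, opt_field, opt_z,
                   schedule, search: bool = True) -> None:
    state.phase = "hps"
    rng = np.random.default_rng(cfg.seed + 20)
    N = stack.n_images
    processed = 0
    order = rng.permutation(N)
    pos = 0
    sample_band = _band_sampler(cfg, bands, 41)
    while processed < cfg.hps_images:
        if pos >= N:
            order = rng.permutation(N)
            pos = 0
        idx = order[pos:pos + cfg.batch_hps]
        pos += len(idx)
        cutoff = cutoff_at(processed, schedule)
        # entanglement guard: while delayed, every particle shares one
        # latent (zero), so the conformation space cannot absorb pose
        # errors; afterwards the per-particle latents optimize normally
        delayed = processed < cfg.z_delay_images
        if search:
            for i in idx:
                zi = (np.zeros(cfg.d, np.float32) if delayed
                      else state.latents.z[i])
                pose = hps(stack.images[i], state.field, zi,
                           bands.ctf_full[i], cutoff, gain=state.gain)
                state.rotations[i] = pose.rotation
                state.translations[i] = pose.translation
        z = (np.zeros((len(idx), cfg.d), np.float32) if delayed
             else state.latents.z[idx])
        lval, fg, zg, _, _ = _grad_step(
            state.field, state.gain, bands, ctf_rows, idx,
            state.rotations[idx], state.translations[idx], z,
            want_pose_grads=False, sel=sample_band())
        opt_field.step(fg)
        if not delayed:
            opt_z.step(idx, zg)
        processed += len(idx)
        state.images_processed += len(idx)
        if processed % cfg.log_interval < len(idx):
            _log(state, cfg, {"loss_per_image": lval / len(idx),
                              "cutoff": cutoff})


def _sgd_phase(state, stack, cfg, bands, ctf_rows, opt_field, opt_z,
               batch_size, lr_pose, per_particle_latents=False) -> None:
    state.phase = "sgd"
    rng = np.random.default_rng(cfg.seed + 30)
    N = stack.n_images
    state.pose_params = matrix_to_rot6d(state.rotations)
    opt_rot = _PerRowAdam(state.pose_params, lr_pose)
    opt_tr = _PerRowAdam(state.translations, lr_pose)
    pe_idx = stack.particle_index if per_particle_latents else np.arange(N)
    processed = 0
    order = rng.permutation(N)
    pos = 0
    sample_band = _band_sampler(cfg, bands, 42)
    while processed < cfg.sgd_images:
        if pos >= N:
            order = rng.permutation(N)
            pos = 0
        idx = order[pos:pos + batch_size]
        pos += len(idx)
        rot = rot6d_to_matrix(state.pose_params[idx])
        state.rotations[idx] = rot
        rows = pe_idx[idx]
        z = state.latents.z[rows]
        lval, fg, zg, rg, tg = _grad_step(
            state.field, state.gain, bands, ctf_rows, idx, rot,
            state.translations[idx], z, want_pose_grads=True,
            sel=sample_band())
        opt_field.step(fg)
        if per_particle_latents:
            urows, inv = np.unique(rows, return_inverse=True)
            zacc = np.zeros((len(urows), zg.shape[1]), dtype=zg.dtype)
            np.add.at(zacc, inv, zg)
            opt_z.step(urows, zacc)
        else:
            opt_z.step(idx, zg)
        ga = rot6d_backward(state.pose_params[idx], rg)
        opt_rot.step(idx, ga)
        opt_tr.step(idx, tg.astype(np.float64))
        processed += len(idx)
        state.images_processed += len(idx)
        if processed % cfg.log_interval < len(idx):
            _log(state, cfg, {"loss_per_image": lval / len(idx)})
    state.rotations[:] = rot6d_to_matrix(state.pose_params)


def train_spa(stack: ParticleStack, cfg: TrainConfig,
              poses: tuple[np.ndarray, np.ndarray] | None = None) -> TrainState:
    """Full three-phase single-particle training run.

    With ``poses`` — a (rotations (N,3,3), translations (N,2)) pair — the
    run operates in fixed-pose mode: the grid-search phase keeps the given
    poses and optimizes only θ and the latents (standard heterogeneous
    training with known consensus poses); the SGD phase still refines the
    poses by gradient.  Without it the run is fully ab initio.
    """
    if stack.tilt is not None:
        raise ValueError("train_spa expects a single-particle stack")
    state = init_state(stack, cfg)
    if poses is not None:
        rot, trans = poses
        state.rotations[:] = np.asarray(rot, dtype=np.float64)
        state.translations[:] = np.asarray(trans, dtype=np.float64)
    bands = _Bands(stack)
    ctf_rows = bands.ctf_rows(stack, stack.pixel_size)
    opt_field = Adam(state.field.params, cfg.lr_field)
    opt_z = _PerRowAdam(state.latents.z, cfg.lr_latent)
    schedule = BandLimitSchedule(cfg.k_min, cfg.k_max, cfg.hps_images)
    pretrain(state, stack, cfg, bands, ctf_rows, opt_field)
    _hps_phase_spa(state, stack, cfg, bands, ctf_rows, opt_field, opt_z,
                   schedule, search=poses is None)
    _sgd_phase(state, stack, cfg, bands, ctf_rows, opt_field, opt_z,
               cfg.batch_sgd, cfg.lr_pose)
    return state


def train_sta(stack: ParticleStack, cfg: TrainConfig) -> TrainState:
    """Tilt-series training: tied subtilt poses in HPS, relaxed in SGD."""
    if stack.tilt is None:
        raise ValueError("train_sta requires tilt metadata")
    state = init_state(stack, cfg)
    bands = _Bands(stack)
    ctf_rows = bands.ctf_rows(stack, stack.pixel_size)
    opt_field = Adam(state.field.params, cfg.lr_field)
    opt_z = _PerRowAdam(state.latents.z, cfg.lr_latent)
    n_part = stack.n_particles
    J = min(stack.tilts_per_particle, cfg.n_tilts)
    hps_particles = cfg.hps_particles or max(2 * n_part, 150_000)
    schedule = BandLimitSchedule(cfg.k_min, cfg.k_max, hps_particles)
    pretrain(state, stack, cfg, bands, ctf_rows, opt_field)

    # group subtilt rows per particle, ordered by tilt_order
    groups = []
    for pid in np.unique(stack.particle_index):
        rows = np.where(stack.particle_index == pid)[0]
        rows = rows[np.argsort([stack.tilt[r].tilt_order for r in rows])]
        groups.append(rows[:J])
    tilt_mats = {}
    for rows in groups:
        for r in rows:
            a = stack.tilt[r].tilt_angle
            if a not in tilt_mats:
                tilt_mats[a] = tilt_rotation(a)

    state.phase = "hps"
    rng = np.random.default_rng(cfg.seed + 20)
    processed = 0
    order = rng.permutation(n_part)
    pos = 0
    sample_band = _band_sampler(cfg, bands, 41)
    epoch_z = None
    while processed < hps_particles:
        if pos >= n_part or epoch_z is None:
            order = rng.permutation(n_part)
            pos = 0
            epoch_z = rng.normal(0.0, 0.1, size=state.latents.z.shape).astype(
                np.float32)
        pb = order[pos:pos + max(1, cfg.batch_hps)]
        pos += len(pb)
        cutoff = cutoff_at(processed, schedule)
        resample = processed < cfg.sta_resample_particles
        img_idx = []
        for p in pb:
            rows = groups[p]
            z = epoch_z[p] if resample else state.latents.z[p]
            trots = [tilt_mats[stack.tilt[r].tilt_angle] for r in rows]
            pose = hps_tilt([stack.images[r] for r in rows], state.field, z,
                            [bands.ctf_full[r] for r in rows], trots,
                            cutoff, gain=state.gain)
            for r, Rt in zip(rows, trots):
                state.rotations[r] = Rt @ pose.rotation
                state.translations[r] = pose.translation
            img_idx.extend(rows.tolist())
        img_idx = np.asarray(img_idx)
        prow = stack.particle_index[img_idx]
        z = (epoch_z if resample else state.latents.z)[prow]
        lval, fg, zg, _, _ = _grad_step(
            state.field, state.gain, bands, ctf_rows, img_idx,
            state.rotations[img_idx], state.translations[img_idx], z,
            want_pose_grads=False, sel=sample_band())
        opt_field.step(fg)
        if not resample:
            urows, inv = np.unique(prow, return_inverse=True)
            zacc = np.zeros((len(urows), zg.shape[1]), dtype=zg.dtype)
            np.add.at(zacc, inv, zg)
            opt_z.step(urows, zacc)
        processed += len(pb)
        state.images_processed += len(img_idx)
        if processed % cfg.log_interval < len(pb):
            _log(state, cfg, {"loss_per_image": lval / len(img_idx),
                              "cutoff": cutoff})

    # SGD: independent pose per subtilt, initialized from the tied poses
    cfg_sgd = cfg
    _sgd_phase(state, stack, cfg_sgd, bands, ctf_rows, opt_field, opt_z,
               cfg.batch_sgd_sta, cfg.lr_pose_sta, per_particle_latents=True)
    return state


def batch_loss(field: VolumeField, gain: float, stack: ParticleStack,
               idx, rotations, translations, z) -> float:
    """Eq-8 style loss of a batch, built directly from a particle stack.

    Convenience wrapper used for cross-checks: equals the sum over the
    batch of band-limited reprojection errors at the full sub-Nyquist band.
    """
    idx = np.asarray(idx)
    bands = _Bands(stack)
    ctf_rows = bands.ctf_rows(stack, stack.pixel_size)
    return loss(field, gain, stack, bands, ctf_rows, idx,
                np.asarray(rotations), np.asarray(translations),
                np.asarray(z))
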