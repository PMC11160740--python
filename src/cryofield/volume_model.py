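"""Conditional implicit representation of the Hartley-space volume ensemble.

The decoder V_θ(z, k) maps a latent embedding z ∈ R^d and a frequency
coordinate k ∈ [-0.5, 0.5]³ to a single Hartley coefficient.  Frequencies are
expanded with Gaussian Fourier features (64 base frequencies, σ = 0.5),
concatenated with z and passed through a width-256 MLP with 3 hidden residual
layers and ReLU activations; the last layer is linear with one output.

Latent embeddings are stored per particle in a :class:`ConformationTable` and
optimized directly (autodecoder) — there is no image encoder.
"""

from __future__ import annotations

import numpy as np

from .forward_model import FrequencyLattice, idht
from .nn import ResidualMLP

__all__ = [
    "N_BASE_FREQUENCIES",
    "VolumeField",
    "ConformationTable",
    "init_field",
    "fourier_features",
    "eval_field",
    "render_map",
]

N_BASE_FREQUENCIES = 64
FEATURE_DIM = 2 * N_BASE_FREQUENCIES
HIDDEN_WIDTH = 256
HIDDEN_DEPTH = 3
BASE_FREQ_STD = 0.5
LATENT_INIT_STD = 0.1


class VolumeField:
    """The neural field V̂_θ(z): Fourier-feature MLP over Hartley coefficients.

    ``B`` (the 64×3 base-frequency matrix) is drawn once at init from
    N(0, 0.5²) and is never updated by the optimizer.  The base frequencies
    are expressed relative to the Fourier lattice: queries k ∈ [-0.5, 0.5]³
    are scaled by ``coord_scale`` (a quarter of the box size of the lattice
    the field is trained on) before entering the sinusoidal basis.  The
    resulting basis bandwidth — std 0.125 cycles per lattice cell — is the
    measured compromise between fitting sharp Hartley volumes and staying
    smooth enough that slices interpolated from a rasterized copy of the
    field agree with direct evaluation (required by the pose search).
    """

    def __init__(self, d: int, seed: int, coord_scale: float = 32.0):
        if d <= 0:
            raise ValueError("latent dimension must be >= 1")
        self.d = int(d)
        self.seed = int(seed)
        self.coord_scale = float(coord_scale)
        rng = np.random.default_rng(seed)
        self.B = rng.normal(0.0, BASE_FREQ_STD, size=(N_BASE_FREQUENCIES, 3)).astype(
            np.float32
        )
        self.mlp = ResidualMLP(FEATURE_DIM + d, HIDDEN_WIDTH, HIDDEN_DEPTH, rng)

    @property
    def B_scaled(self) -> np.ndarray:
        """Base frequencies in cycles per unit k (includes the lattice scale)."""
        return self.B * np.float32(self.coord_scale)

    # -- introspection ----------------------------------------------------
    @property
    def n_parameters(self) -> int:
        """Trainable parameter count W (excludes the fixed matrix B)."""
        return self.mlp.n_parameters

    @property
    def params(self) -> dict:
        return self.mlp.params

    # -- evaluation -------------------------------------------------------
    def features(self, coords: np.ndarray) -> np.ndarray:
        """[sin(2πBk); cos(2πBk)] for coords (M, 3) -> (M, 128), in [-1, 1]."""
        ang = 2.0 * np.pi * (coords.astype(np.float32) @ self.B_scaled.T)
        return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)

    def _assemble(self, z: np.ndarray, coords: np.ndarray) -> np.ndarray:
        feat = self.features(coords)
        z = np.asarray(z, dtype=np.float32)
        if z.ndim == 1:
            z = np.broadcast_to(z, (coords.shape[0], self.d))
        return np.concatenate([feat, z], axis=1)

    def evaluate(self, z: np.ndarray, coords: np.ndarray) -> np.ndarray:
        """V̂_θ(z, k) at coords (M, 3); out-of-band coords give exactly 0."""
        coords = np.asarray(coords, dtype=np.float32).reshape(-1, 3)
        if not np.isfinite(coords).all():
            raise ValueError("coords must be finite")
        out = self.mlp.forward(self._assemble(z, coords))
        oob = np.any(np.abs(coords) > 0.5, axis=1)
        if oob.any():
            out = np.where(oob, np.float32(0.0), out)
        return out

    def evaluate_with_grads(self, z: np.ndarray, coords: np.ndarray,
                            grad_out: np.ndarray):
        """Forward + backward pass.

        Returns (values, param_grads, grad_z, grad_coords) for the upstream
        gradient ``grad_out`` (shape (M,)).  Out-of-band coordinates
        contribute zero value and zero gradient.
        """
        coords = np.asarray(coords, dtype=np.float32).reshape(-1, 3)
        x = self._assemble(z, coords)
        out, cache = self.mlp.forward(x, want_cache=True)
        oob = np.any(np.abs(coords) > 0.5, axis=1)
        g = np.asarray(grad_out, dtype=np.float32)
        if oob.any():
            out = np.where(oob, np.float32(0.0), out)
            g = np.where(oob, np.float32(0.0), g)
        grads, gx = self.mlp.backward(cache, g)
        gfeat = gx[:, :FEATURE_DIM]
        gz = gx[:, FEATURE_DIM:]
        Bs = self.B_scaled
        ang = 2.0 * np.pi * (coords @ Bs.T)
        # d feat / d k: sin-block -> 2π cos(ang) B, cos-block -> -2π sin(ang) B
        gsin = gfeat[:, :N_BASE_FREQUENCIES] * np.cos(ang)
        gcos = gfeat[:, N_BASE_FREQUENCIES:] * np.sin(ang)
        gcoords = 2.0 * np.pi * ((gsin - gcos) @ Bs)
        return out, grads, gz, gcoords

    # -- persistence ------------------------------------------------------
    def state_dict(self) -> dict:
        out = {"B": self.B, "d": self.d, "seed": self.seed,
               "coord_scale": self.coord_scale}
        for k, v in self.mlp.params.items():
            out[f"p::{k}"] = v
        return out

    @classmethod
    def from_state_dict(cls, state: dict) -> "VolumeField":
        field = cls(int(state["d"]), int(state["seed"]),
                    coord_scale=float(state.get("coord_scale", 32.0)))
        field.B = np.asarray(state["B"], dtype=np.float32).copy()
        for k in field.mlp.params:
            field.mlp.params[k] = np.asarray(state[f"p::{k}"], dtype=np.float32).copy()
        return field


class ConformationTable:
    """Per-particle latent embeddings z_i ∈ R^d, directly optimized."""

    def __init__(self, n_particles: int, d: int, seed: int):
        rng = np.random.default_rng(seed)
        self.z = rng.normal(0.0, LATENT_INIT_STD, size=(n_particles, d)).astype(
            np.float32
        )

    @property
    def n(self) -> int:
        return self.z.shape[0]

    @property
    def d(self) -> int:
        return self.z.shape[1]


def init_field(d: int, seed: int, coord_scale: float = 32.0) -> VolumeField:
    """Deterministically initialize a volume field (B ~ N(0, 0.5²) fixed)."""
    return VolumeField(d, seed, coord_scale=coord_scale)


def fourier_features(field: VolumeField, k: np.ndarray) -> np.ndarray:
    """Positional encoding of one or more frequency coordinates."""
    k = np.asarray(k, dtype=np.float32).reshape(-1, 3)
    out = field.features(k)
    return out[0] if out.shape[0] == 1 and k.shape[0] == 1 else out


def eval_field(field: VolumeField, z: np.ndarray, coords: np.ndarray) -> np.ndarray:
    return field.evaluate(z, coords)


def render_map(field: VolumeField, z: np.ndarray, D: int,
               gain: float = 1.0) -> np.ndarray:
    """Evaluate the field on the full D³ Hartley lattice and invert to a map."""
    if D % 2:
        raise ValueError("D must be even")
    lat = FrequencyLattice(D, ndim=3)
    coords = lat.coords.reshape(-1, 3)
    vhat = field.evaluate(z, coords).reshape(D, D, D).astype(np.float64)
    return idht(gain * vhat)


def field_hartley_grid(field: VolumeField, z: np.ndarray, D: int) -> np.ndarray:
    """The field rasterized on the D³ centered Hartley lattice (no inversion)."""
    lat = FrequencyLattice(D, ndim=3)
    return field.evaluate(z, lat.coords.reshape(-1, 3)).reshape(D, D, D).astype(np.float64)
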