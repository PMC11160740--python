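"""Image formation model in real and Hartley space.

The forward model for a particle image is

    I = C * P_{R,t}(V) + eta

where ``C`` is the contrast transfer function (CTF), ``P_{R,t}`` an
orthographic projection of the 3D potential ``V`` after rotation ``R`` and
in-plane translation ``t``, and ``eta`` white Gaussian noise.  All heavy
lifting happens in Hartley space, where the Fourier slice theorem turns the
projection into a central-slice lookup and the whole pipeline stays
real-valued:

    H(I) = C_hat  ⊙  T_t  S_R  V_hat  +  eta

``S_R`` samples the 3D Hartley volume on the rotated central plane and
``T_t`` is the Hartley-space translation operator.

Conventions (fixed here, asserted by the test-suite):

* arrays are C-ordered with axis order ``(z, y, x)`` for volumes and
  ``(y, x)`` for images;
* frequency lattices are centered (``fftshift`` layout), with coordinates in
  cycles/pixel in ``[-0.5, 0.5)``; the ``-k`` partner of a lattice point is
  obtained by index negation mod D (periodic extension of the grid);
* the discrete Hartley transform is unitary, hence an involution;
* rotations act on frequency coordinates as ``k -> R k``; a translation by
  ``t`` moves image content by ``+t`` pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "FrequencyLattice",
    "Pose",
    "dht",
    "idht",
    "eval_ctf",
    "slice_volume",
    "translate_hartley",
    "project_real",
    "tilt_weights",
    "dose_weights",
    "simulate_observation",
    "critical_exposure",
]


# --------------------------------------------------------------------------
# lattices and poses
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyLattice:
    """Centered grid of frequency coordinates for a D×D image (or D³ volume).

    ``coords`` has shape (D, D, 2) for 2D — last axis is (kx, ky) — or
    (D, D, D, 3) for 3D with last axis (kx, ky, kz); values are in
    cycles/pixel, spanning [-0.5, 0.5) in steps of 1/D.
    """

    size: int
    ndim: int = 2

    def __post_init__(self):
        if self.size < 2 or self.size % 2:
            raise ValueError(f"lattice size must be even and >= 2, got {self.size}")

    @property
    def freqs(self) -> np.ndarray:
        """1D centered frequency values, length D."""
        return np.fft.fftshift(np.fft.fftfreq(self.size))

    @property
    def coords(self) -> np.ndarray:
        f = self.freqs
        if self.ndim == 2:
            ky, kx = np.meshgrid(f, f, indexing="ij")
            return np.stack([kx, ky], axis=-1)
        kz, ky, kx = np.meshgrid(f, f, f, indexing="ij")
        return np.stack([kx, ky, kz], axis=-1)

    def neg_index(self) -> tuple[np.ndarray, ...]:
        """Per-axis index arrays mapping each lattice point to its -k partner.

        The point at centered index m has frequency (m - D/2)/D; its negation
        lives at index (D - m) mod D (the Nyquist row is its own partner under
        the periodic extension of the grid).
        """
        idx = (-np.arange(self.size)) % self.size
        # centered layout: value at position m is freq (m - D/2)/D, so the
        # partner of position m is D - m for m >= 1 and 0 for m = 0.
        m = np.arange(self.size)
        part = (self.size - m) % self.size
        del idx
        return tuple(part for _ in range(self.ndim))

    def radius(self) -> np.ndarray:
        """|k| in cycles per image length (grid units), shape D^ndim."""
        c = self.coords
        return np.linalg.norm(c, axis=-1) * self.size


@dataclass
class Pose:
    """Rigid pose: rotation R in SO(3) plus in-plane translation in pixels."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64).reshape(2)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6 or np.linalg.det(R) < 0:
            raise ValueError("rotation is not a proper orthonormal matrix")
        self.rotation = R
        self.translation = t


# --------------------------------------------------------------------------
# discrete Hartley transform
# --------------------------------------------------------------------------

def dht(x: np.ndarray, axes: tuple[int, ...] | None = None) -> np.ndarray:
    """Unitary discrete Hartley transform, centered in both domains.

    H = Re(F) - Im(F) with F the orthonormal DFT.  Being unitary and
    symmetric, the transform is an involution: dht(dht(x)) == x.
    Input must be real.
    """
    x = np.asarray(x)
    if np.iscomplexobj(x):
        raise TypeError("dht expects a real-valued array")
    if axes is None:
        axes = tuple(range(x.ndim))
    f = np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )
    return np.ascontiguousarray(f.real - f.imag)


def idht(h: np.ndarray, axes: tuple[int, ...] | None = None) -> np.ndarray:
    """Inverse DHT (identical to the forward transform)."""
    return dht(h, axes=axes)


# --------------------------------------------------------------------------
# contrast transfer function
# --------------------------------------------------------------------------

def _wavelength_angstrom(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Å for an accelerating voltage in kV."""
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v + 0.97845e-6 * v * v)


def eval_ctf(ctf, lattice: FrequencyLattice, pixel_size: float) -> np.ndarray:
    """Evaluate the CTF on a frequency lattice (CTFFIND-style convention).

        C(k) = -( sqrt(1-w²) sin γ(k) + w cos γ(k) ) · exp(-B|k|²/4)

    with phase γ = π λ Δz(α) |k|² − (π/2) Cs λ³ |k|⁴ + phase_shift and the
    astigmatic defocus Δz(α) = ½(du+dv + (du−dv) cos 2(α−α_ast)).
    |k| is in Å⁻¹ (lattice coordinates divided by the pixel size).  The
    result is an even function of k; values lie in [-1, 1] before the
    optional B-factor envelope.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    coords = lattice.coords[..., :2] / pixel_size  # Å^-1
    kx, ky = coords[..., 0], coords[..., 1]
    k2 = kx * kx + ky * ky
    alpha = np.arctan2(ky, kx)

    lam = _wavelength_angstrom(ctf.voltage)
    ang = np.deg2rad(ctf.astigmatism_angle)
    dz = 0.5 * (
        ctf.defocus_u + ctf.defocus_v
        + (ctf.defocus_u - ctf.defocus_v) * np.cos(2.0 * (alpha - ang))
    )
    cs_a = ctf.cs * 1e7  # mm -> Å
    gamma = (
        np.pi * lam * dz * k2
        - 0.5 * np.pi * cs_a * lam**3 * k2 * k2
        + np.deg2rad(ctf.phase_shift)
    )
    w = ctf.amplitude_contrast
    c = -(np.sqrt(1.0 - w * w) * np.sin(gamma) + w * np.cos(gamma))
    b = getattr(ctf, "b_factor", 0.0) or 0.0
    if b:
        c = c * np.exp(-b * k2 / 4.0)
    return c


# --------------------------------------------------------------------------
# slicing, translation, projection
# --------------------------------------------------------------------------

def _extend_periodic(vol: np.ndarray) -> np.ndarray:
    """Pad a centered D³ Hartley volume to (D+1)³ by periodic wrap.

    Adds the +0.5 frequency plane (equal to the stored -0.5 plane) so that
    trilinear interpolation is defined on all of [-0.5, 0.5]³.
    """
    return np.pad(vol, [(0, 1)] * vol.ndim, mode="wrap")


def rotated_plane_coords(lattice: FrequencyLattice, R: np.ndarray) -> np.ndarray:
    """3D frequency coordinates of the central plane rotated by R, shape (D, D, 3)."""
    c2 = lattice.coords  # (D, D, 2), (kx, ky)
    k = np.concatenate([c2, np.zeros_like(c2[..., :1])], axis=-1)
    return k @ np.asarray(R).T  # rows k -> R k


class GriddedHartleyVolume:
    """A D³ Hartley volume sampled off-grid by cubic B-spline interpolation.

    Caches the spline prefilter of the periodically extended (D+1)³ array so
    repeated slicing (e.g. during pose search) pays the filter cost once.
    Cubic interpolation is used because the slice-theorem accuracy of plain
    trilinear lookup is insufficient at small box sizes.
    """

    def __init__(self, vhat: np.ndarray, order: int = 3):
        vhat = np.asarray(vhat, dtype=np.float64)
        if vhat.ndim != 3 or len(set(vhat.shape)) != 1:
            raise ValueError("expected a cubic Hartley volume")
        self.D = vhat.shape[0]
        self.order = order
        self._ext = _extend_periodic(vhat)
        if order > 1:
            self._filtered = ndimage.spline_filter(self._ext, order=order, mode="constant")
        else:
            self._filtered = self._ext

    def evaluate(self, z, pts: np.ndarray) -> np.ndarray:
        """Sample at frequency points (..., 3), (kx, ky, kz) in cycles/pixel.

        ``z`` is ignored (present for interface parity with the neural
        field).  Points outside [-0.5, 0.5]³ evaluate to 0.
        """
        D = self.D
        idx = np.stack(
            [
                D / 2 + D * pts[..., 2],
                D / 2 + D * pts[..., 1],
                D / 2 + D * pts[..., 0],
            ]
        )
        vals = ndimage.map_coordinates(
            self._filtered, idx.reshape(3, -1), order=self.order,
            prefilter=False, mode="constant", cval=0.0,
        )
        out = vals.reshape(pts.shape[:-1])
        oob = np.any(np.abs(pts) > 0.5, axis=-1)
        if np.any(oob):
            out = np.where(oob, 0.0, out)
        return out


def interpolate_hartley(vhat: np.ndarray, pts: np.ndarray, order: int = 3) -> np.ndarray:
    """Interpolate a centered Hartley volume at frequency points.

    ``pts`` has shape (..., 3) with (kx, ky, kz) in cycles/pixel; points
    outside [-0.5, 0.5]³ evaluate to 0 (band limit).
    """
    return GriddedHartleyVolume(vhat, order=order).evaluate(None, pts)


def slice_volume(vhat, R: np.ndarray, lattice: FrequencyLattice | None = None,
                 z: np.ndarray | None = None) -> np.ndarray:
    """Central slice of a Hartley volume: samples V_hat at R·(kx, ky, 0)ᵀ.

    ``vhat`` is either a gridded D³ Hartley volume (trilinear interpolation)
    or a conditional volume field with an ``evaluate`` method (direct
    evaluation, ``z`` passed through).  Returns a (D, D) Hartley image.
    """
    if hasattr(vhat, "evaluate"):
        if lattice is None:
            if hasattr(vhat, "D"):
                lattice = FrequencyLattice(vhat.D, ndim=2)
            else:
                raise ValueError("a lattice is required when slicing a volume field")
        pts = rotated_plane_coords(lattice, R)
        return vhat.evaluate(z, pts.reshape(-1, 3)).reshape(pts.shape[:2])
    vhat = np.asarray(vhat)
    if lattice is None:
        lattice = FrequencyLattice(vhat.shape[0], ndim=2)
    pts = rotated_plane_coords(lattice, R)
    return interpolate_hartley(vhat, pts)


def translate_hartley(h: np.ndarray, t, lattice: FrequencyLattice | None = None) -> np.ndarray:
    """Hartley-space translation operator.

        (T_t H)(k) = cos(2π t·k) H(k) + sin(2π t·k) H(−k)

    Moves real-space content by +t pixels.  The −k partner is the index
    negation mod D, exact on the centered lattice.  The operator is
    orthogonal (‖T_t H‖ = ‖H‖) and composes additively in t.
    """
    h = np.asarray(h, dtype=np.float64)
    D = h.shape[-1]
    if h.shape[-2] != D:
        raise ValueError("Hartley image must be square")
    if lattice is None:
        lattice = FrequencyLattice(D, ndim=2)
    t = np.asarray(t, dtype=np.float64).reshape(2)
    c = lattice.coords
    theta = 2.0 * np.pi * (t[0] * c[..., 0] + t[1] * c[..., 1])
    py, px = lattice.neg_index()[:2]
    hneg = h[..., py[:, None], px[None, :]]
    return np.cos(theta) * h + np.sin(theta) * hneg


def project_real(volume: np.ndarray, pose: Pose) -> np.ndarray:
    """Real-space projection oracle: rotate, shift by t, integrate along z.

    Defined so that its 2D Hartley transform equals the central slice of the
    volume's 3D Hartley transform at the same pose (the slice theorem);
    used as the independent reference for the Hartley pipeline.
    """
    volume = np.asarray(volume, dtype=np.float64)
    D = volume.shape[0]
    if volume.shape != (D, D, D):
        raise ValueError("volume must be cubic")
    R = pose.rotation
    # W(x) = V(R x) in centered coordinates; array axes are (z, y, x) so the
    # matrix acting on index vectors is R reversed on both axes.
    P = R[::-1, ::-1]
    c = D // 2
    center = np.full(3, c, dtype=np.float64)
    rotated = ndimage.affine_transform(
        volume, P, offset=center - P @ center, order=1, mode="constant", cval=0.0
    )
    img = rotated.sum(axis=0)
    tx, ty = pose.translation
    if tx or ty:
        img = ndimage.shift(img, (ty, tx), order=1, mode="constant", cval=0.0)
    return img


# --------------------------------------------------------------------------
# tomography weighting
# --------------------------------------------------------------------------

def critical_exposure(k_inv_angstrom: np.ndarray) -> np.ndarray:
    """Critical exposure N_e(k) = 0.245 k^-1.665 + 2.81 (k in Å⁻¹, e⁻/Å²)."""
    k = np.asarray(k_inv_angstrom, dtype=np.float64)
    out = np.full(k.shape, np.inf)
    pos = k > 0
    out[pos] = 0.245 * np.power(k[pos], -1.665) + 2.81
    return out


def dose_weights(lattice: FrequencyLattice, pixel_size: float,
                 cumulative_dose: float) -> np.ndarray:
    """Frequency-dependent radiation-damage attenuation exp(−d / 2N_e(k))."""
    k = np.linalg.norm(lattice.coords[..., :2], axis=-1) / pixel_size
    return np.exp(-cumulative_dose / (2.0 * critical_exposure(k)))


def tilt_weights(ctf, tilt, lattice: FrequencyLattice, pixel_size: float) -> np.ndarray:
    """Per-subtilt CTF: eval_ctf × cos(tilt angle) × dose attenuation.

    The cosine factor models the SNR loss from increased effective sample
    thickness at high tilt; the dose term down-weights high frequencies in
    later (higher cumulative exposure) tilt images.
    """
    if abs(tilt.tilt_angle) >= 90.0:
        raise ValueError("tilt angle must satisfy |angle| < 90 degrees")
    if tilt.cumulative_dose < 0:
        raise ValueError("cumulative dose must be non-negative")
    c = eval_ctf(ctf, lattice, pixel_size)
    return c * np.cos(np.deg2rad(tilt.tilt_angle)) * dose_weights(
        lattice, pixel_size, tilt.cumulative_dose
    )


# --------------------------------------------------------------------------
# observation synthesis
# --------------------------------------------------------------------------

def simulate_observation(vhat_source, pose: Pose, ctf_array: np.ndarray | None,
                         noise_std: float, rng: np.random.Generator,
                         lattice: FrequencyLattice | None = None,
                         z: np.ndarray | None = None) -> np.ndarray:
    """Draw one image from the forward model: idht(C ⊙ T_t S_R V_hat) + noise.

    ``ctf_array`` is a pre-evaluated (possibly tilt-weighted) CTF on the
    lattice, or None for a unit CTF.  ``noise_std`` is the standard deviation
    of the additive white Gaussian pixel noise.

    Under the unitary DHT the slice theorem carries a factor √D
    (H₂(proj V) = √D · S_R H₃(V)); that factor is applied here so that the
    slicing operator itself stays a pure central-plane lookup.
    """
    if noise_std < 0:
        raise ValueError("noise_std must be non-negative")
    if lattice is None:
        if hasattr(vhat_source, "evaluate"):
            D = getattr(vhat_source, "D", None)
        else:
            D = vhat_source.shape[0]
        if D is None:
            raise ValueError("a lattice is required for a volume field source")
        lattice = FrequencyLattice(D, ndim=2)
    s = np.sqrt(lattice.size) * slice_volume(vhat_source, pose.rotation, lattice=lattice, z=z)
    s = translate_hartley(s, pose.translation, lattice=lattice)
    if ctf_array is not None:
        s = s * ctf_array
    img = idht(s)
    if noise_std > 0:
        img = img + rng.normal(0.0, noise_std, size=img.shape)
    return img
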