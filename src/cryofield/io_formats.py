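"""Cryo-EM file formats and run-state persistence.

Covers exactly what the tool touches: MRC/MRCS (mode-2 float32) image
stacks and volumes, STAR particle metadata in both the flat legacy dialect
and the RELION 3.1 optics-group dialect, and checkpointing of a training
run (field parameters, poses, latents, optimizer state, RNG state).

Angles are degrees in all on-disk metadata and radians internally; the
conversion happens in exactly one place per boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .forward_model import dht, idht

__all__ = [
    "CtfParams",
    "TiltMetadata",
    "ParticleStack",
    "read_mrc",
    "write_mrc",
    "write_volume",
    "read_volume",
    "read_star",
    "write_star",
    "read_particle_stack",
    "fourier_crop",
    "save_state",
    "load_state",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class CtfParams:
    """Microscope contrast-transfer parameters for one particle image."""

    defocus_u: float  # Å
    defocus_v: float  # Å
    astigmatism_angle: float = 0.0  # degrees
    voltage: float = 300.0  # kV
    cs: float = 2.7  # mm
    amplitude_contrast: float = 0.07  # unitless, [0, 1]
    phase_shift: float = 0.0  # degrees
    b_factor: float = 0.0  # Å²

    def __post_init__(self):
        if self.defocus_u <= 0 or self.defocus_v <= 0:
            raise ValueError("defocus must be positive")
        if self.voltage <= 0:
            raise ValueError("voltage must be positive")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude contrast must lie in [0, 1]")


@dataclass
class TiltMetadata:
    """Per-subtilt acquisition metadata for tomographic data."""

    tilt_angle: float  # degrees
    cumulative_dose: float  # e-/Å²
    tilt_order: int


@dataclass
class ParticleStack:
    """Particle images plus per-image metadata; the observations I_i.

    For tilt series, ``particle_index`` groups the subtilt images of one
    physical particle and every group must have the same subtilt count.
    """

    images: np.ndarray  # (N, D, D) float32
    pixel_size: float  # Å/px
    ctf: list  # CtfParams per image
    tilt: list | None = None  # TiltMetadata per image, or None for SPA
    particle_index: np.ndarray | None = None

    def __post_init__(self):
        imgs = np.asarray(self.images, dtype=np.float32)
        if imgs.ndim != 3 or imgs.shape[1] != imgs.shape[2]:
            raise ValueError("images must be (N, D, D) with square frames")
        D = imgs.shape[1]
        if D < 16 or D % 2:
            raise ValueError(f"image size must be even and >= 16, got {D}")
        if not np.isfinite(imgs).all():
            raise ValueError("images contain non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if len(self.ctf) != imgs.shape[0]:
            raise ValueError("one CtfParams required per image")
        if self.particle_index is None:
            self.particle_index = np.arange(imgs.shape[0], dtype=np.int64)
        else:
            self.particle_index = np.asarray(self.particle_index, dtype=np.int64)
        if self.tilt is not None:
            if len(self.tilt) != imgs.shape[0]:
                raise ValueError("one TiltMetadata required per image")
            counts = np.bincount(self.particle_index)
            counts = counts[counts > 0]
            if len(set(counts.tolist())) > 1:
                raise ValueError("all particle groups must share one tilt count")
            for pid in np.unique(self.particle_index):
                rows = np.where(self.particle_index == pid)[0]
                order = sorted(rows, key=lambda r: self.tilt[r].tilt_order)
                doses = [self.tilt[r].cumulative_dose for r in order]
                if any(b < a for a, b in zip(doses, doses[1:])):
                    raise ValueError(
                        "cumulative dose must be non-decreasing with tilt order"
                    )
        self.images = imgs

    @property
    def n_images(self) -> int:
        return self.images.shape[0]

    @property
    def D(self) -> int:
        return self.images.shape[1]

    @property
    def n_particles(self) -> int:
        return int(np.unique(self.particle_index).size)

    @property
    def tilts_per_particle(self) -> int:
        if self.tilt is None:
            return 1
        return self.n_images // self.n_particles


# --------------------------------------------------------------------------
# MRC / MRCS
# --------------------------------------------------------------------------

_MRC_HEADER_SIZE = 1024


def _build_mrc_header(shape_zyx, pixel_size: float, is_stack: bool,
                      stats: tuple[float, float, float, float]) -> bytes:
    nz, ny, nx = shape_zyx
    h = np.zeros(256, dtype=np.int32)
    hf = h.view(np.float32)
    h[0:3] = (nx, ny, nz)
    h[3] = 2  # mode 2: float32
    h[7:10] = (nx, ny, nz)  # mx, my, mz
    hf[10] = nx * pixel_size
    hf[11] = ny * pixel_size
    hf[12] = nz * pixel_size
    hf[13:16] = (90.0, 90.0, 90.0)
    h[16:19] = (1, 2, 3)  # axis mapping
    dmin, dmax, dmean, rms = stats
    hf[19] = dmin
    hf[20] = dmax
    hf[21] = dmean
    h[22] = 0 if is_stack else 1  # ispg
    buf = bytearray(h.tobytes())
    buf[208:212] = b"MAP "
    buf[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian stamp
    np.frombuffer(buf, dtype=np.float32, count=1, offset=216)  # noqa: rms slot
    buf[216:220] = np.float32(rms).tobytes()
    return bytes(buf)


def write_mrc(data: np.ndarray, pixel_size: float, path, is_stack: bool = True) -> None:
    """Write a float32 MRC/MRCS file (mode 2) with the voxel size in header."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError("expected a 2D image, 3D volume, or image stack")
    if not np.isfinite(data).all():
        raise ValueError("refusing to write non-finite voxel values")
    stats = (float(data.min()), float(data.max()), float(data.mean()),
             float(data.std()))
    header = _build_mrc_header(data.shape, pixel_size, is_stack, stats)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(np.ascontiguousarray(data).tobytes())


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read a mode-2 MRC/MRCS file; returns (data (nz, ny, nx), pixel size)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _MRC_HEADER_SIZE:
        raise ValueError(f"{path}: truncated MRC header")
    h = np.frombuffer(raw[:_MRC_HEADER_SIZE], dtype=np.int32)
    hf = h.view(np.float32)
    nx, ny, nz, mode = int(h[0]), int(h[1]), int(h[2]), int(h[3])
    if mode != 2:
        raise ValueError(f"{path}: only mode-2 (float32) MRC supported, got {mode}")
    nsymbt = int(h[23])
    mx = int(h[7]) or nx
    pixel_size = float(hf[10]) / mx if hf[10] > 0 else 1.0
    count = nx * ny * nz
    data = np.frombuffer(
        raw, dtype="<f4", count=count, offset=_MRC_HEADER_SIZE + nsymbt
    ).reshape(nz, ny, nx)
    return data.copy(), pixel_size


def write_volume(volume: np.ndarray, pixel_size: float, path) -> None:
    """Write a cubic 3D map as MRC (ispg 1)."""
    volume = np.asarray(volume)
    if volume.ndim != 3 or len(set(volume.shape)) != 1:
        raise ValueError("volume must be a cubic 3D array")
    write_mrc(volume, pixel_size, path, is_stack=False)


def read_volume(path) -> tuple[np.ndarray, float]:
    return read_mrc(path)


# --------------------------------------------------------------------------
# STAR
# --------------------------------------------------------------------------

def read_star(path) -> dict[str, pd.DataFrame]:
    """Parse a STAR file into one DataFrame per data block.

    Handles loop_ tables and bare key-value blocks; values are converted to
    numeric dtypes where possible.
    """
    blocks: dict[str, pd.DataFrame] = {}
    name = None
    columns: list[str] = []
    rows: list[list[str]] = []
    kv: dict[str, str] = {}
    in_loop = False

    def flush():
        nonlocal columns, rows, kv, in_loop
        if name is not None and (columns or kv):
            if columns:
                df = pd.DataFrame(rows, columns=columns)
            else:
                df = pd.DataFrame([kv])
            for c in df.columns:
                try:
                    df[c] = pd.to_numeric(df[c])
                except (ValueError, TypeError):
                    pass
            blocks[name] = df
        columns, rows, kv, in_loop = [], [], {}, False

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("data_"):
                flush()
                name = line[5:] or "data"
                continue
            if line == "loop_":
                in_loop = True
                continue
            if line.startswith("_"):
                parts = line.split()
                tag = parts[0].lstrip("_").split("#")[0].strip()
                if in_loop:
                    columns.append(parts[0].lstrip("_"))
                else:
                    kv[parts[0].lstrip("_")] = parts[1] if len(parts) > 1 else ""
                del tag
                continue
            if in_loop:
                vals = line.split()
                if len(vals) == len(columns):
                    rows.append(vals)
    flush()
    return blocks


def write_star(blocks: dict[str, pd.DataFrame], path) -> None:
    with open(path, "w") as fh:
        for name, df in blocks.items():
            fh.write(f"\ndata_{name}\n\nloop_\n")
            for i, c in enumerate(df.columns, start=1):
                fh.write(f"_{c} #{i}\n")
            for _, row in df.iterrows():
                fh.write(" ".join(str(v) for v in row.values) + "\n")


def _particles_table(blocks: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Flatten legacy or RELION-3.1 optics-group STAR metadata to one table."""
    if "particles" in blocks:
        df = blocks["particles"]
        if "optics" in blocks and "rlnOpticsGroup" in df.columns:
            df = df.merge(blocks["optics"], on="rlnOpticsGroup",
                          how="left", suffixes=("", "_optics"))
        return df
    # flat legacy: first (often only) block
    return next(iter(blocks.values()))


def read_particle_stack(mrcs_path, star_path, normalize: bool = True,
                        dose_per_tilt: float | None = None) -> ParticleStack:
    """Load an MRCS image stack with STAR metadata into a ParticleStack.

    STAR rows must align 1:1 with the stack images (by order).  CTF
    parameters come from the standard RELION tags; tilt metadata is read
    from tilt-angle/dose columns when present, with the cumulative dose
    optionally computed from ``dose_per_tilt`` × tilt order if the file
    carries no dose column.  Images are normalized to zero mean and unit
    standard deviation per image unless ``normalize=False``.
    """
    images, pixel_size = read_mrc(mrcs_path)
    blocks = read_star(star_path)
    df = _particles_table(blocks)
    if len(df) != images.shape[0]:
        raise ValueError(
            f"metadata/stack mismatch: STAR has {len(df)} rows, "
            f"MRCS has {images.shape[0]} images"
        )
    if images.shape[1] != images.shape[2]:
        raise ValueError("non-square images are unsupported")
    if "rlnPixelSize" in df.columns:
        pixel_size = float(df["rlnPixelSize"].iloc[0])
    elif "rlnImagePixelSize" in df.columns:
        pixel_size = float(df["rlnImagePixelSize"].iloc[0])

    def col(tag, default):
        return df[tag].to_numpy(dtype=float) if tag in df.columns \
            else np.full(len(df), default)

    du = col("rlnDefocusU", 10000.0)
    dv = col("rlnDefocusV", 10000.0)
    dang = col("rlnDefocusAngle", 0.0)
    volt = col("rlnVoltage", 300.0)
    cs = col("rlnSphericalAberration", 2.7)
    w = col("rlnAmplitudeContrast", 0.07)
    ps = col("rlnPhaseShift", 0.0)
    ctf = [CtfParams(du[i], dv[i], dang[i], volt[i], cs[i], w[i], ps[i])
           for i in range(len(df))]

    tilt = None
    tilt_cols = [c for c in ("rlnTiltAngle", "rlnTomoNominalStageTiltAngle")
                 if c in df.columns]
    if tilt_cols:
        ang = df[tilt_cols[0]].to_numpy(dtype=float)
        order = col("rlnTiltOrder", 0.0).astype(int)
        if "rlnCumulativeDose" in df.columns:
            dose = df["rlnCumulativeDose"].to_numpy(dtype=float)
        elif dose_per_tilt is not None:
            dose = order * dose_per_tilt
        else:
            dose = np.zeros(len(df))
        tilt = [TiltMetadata(ang[i], dose[i], int(order[i]))
                for i in range(len(df))]

    pidx = None
    if "rlnParticleIndex" in df.columns:
        pidx = df["rlnParticleIndex"].to_numpy(dtype=np.int64)
    elif "rlnGroupNumber" in df.columns and tilt is not None:
        pidx = df["rlnGroupNumber"].to_numpy(dtype=np.int64)

    imgs = images.astype(np.float32)
    if normalize:
        mean = imgs.mean(axis=(1, 2), keepdims=True)
        std = imgs.std(axis=(1, 2), keepdims=True)
        std[std == 0] = 1.0
        imgs = (imgs - mean) / std
    return ParticleStack(imgs, pixel_size, ctf, tilt, pidx)


# --------------------------------------------------------------------------
# Fourier cropping
# --------------------------------------------------------------------------

def fourier_crop(stack: ParticleStack, D_new: int) -> ParticleStack:
    """Band-limit a stack by central cropping in Hartley space.

    Keeps the centered D_new×D_new block of each image's Hartley transform
    and rescales so that the real-space amplitude of every retained
    harmonic — including the mean (DC) — is preserved; the pixel size
    scales by D/D_new.  Cropping to the current size is the identity.
    """
    D = stack.D
    if D_new % 2 or D_new > D:
        raise ValueError(f"D_new must be even and <= {D}, got {D_new}")
    if D_new == D:
        return stack
    h = dht(stack.images.astype(np.float64), axes=(1, 2))
    lo = (D - D_new) // 2
    cropped = h[:, lo:lo + D_new, lo:lo + D_new] * (D_new / D)
    imgs = idht(cropped, axes=(1, 2)).astype(np.float32)
    return ParticleStack(imgs, stack.pixel_size * D / D_new, stack.ctf,
                         stack.tilt, stack.particle_index)


# --------------------------------------------------------------------------
# run state
# --------------------------------------------------------------------------

_STATE_VERSION = 1


def save_state(run_dir, field_state: dict, poses: dict, latents: np.ndarray,
               config: dict, rng: np.random.Generator,
               optim_state: dict | None = None, extra: dict | None = None) -> None:
    """Persist everything needed to resume a run bit-for-bit."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    arrays = {f"field::{k}": v for k, v in field_state.items()
              if isinstance(v, np.ndarray)}
    scalars = {k: v for k, v in field_state.items()
               if not isinstance(v, np.ndarray)}
    for k, v in poses.items():
        arrays[f"pose::{k}"] = v
    arrays["latents"] = latents
    if optim_state:
        for k, v in optim_state.items():
            if isinstance(v, np.ndarray):
                arrays[f"optim::{k}"] = v
            else:
                scalars[f"optim::{k}"] = v
    if extra:
        for k, v in extra.items():
            if isinstance(v, np.ndarray):
                arrays[f"extra::{k}"] = v
            else:
                scalars[f"extra::{k}"] = v
    np.savez(run_dir / "state.npz", **arrays)
    meta = {
        "version": _STATE_VERSION,
        "scalars": scalars,
        "config": config,
        "rng_state": rng.bit_generator.state,
    }
    (run_dir / "state.json").write_text(json.dumps(meta, indent=1))


def load_state(run_dir):
    """Load a saved run; raises on missing files or version mismatch."""
    run_dir = Path(run_dir)
    npz_path = run_dir / "state.npz"
    json_path = run_dir / "state.json"
    if not npz_path.exists() or not json_path.exists():
        raise FileNotFoundError(f"no saved state under {run_dir}")
    meta = json.loads(json_path.read_text())
    if meta.get("version") != _STATE_VERSION:
        raise ValueError(
            f"state version mismatch: file has {meta.get('version')}, "
            f"expected {_STATE_VERSION}"
        )
    with np.load(npz_path) as z:
        arrays = {k: z[k] for k in z.files}
    field_state = {k.split("::", 1)[1]: v for k, v in arrays.items()
                   if k.startswith("field::")}
    field_state.update({k: v for k, v in meta["scalars"].items()
                        if "::" not in k})
    poses = {k.split("::", 1)[1]: v for k, v in arrays.items()
             if k.startswith("pose::")}
    optim = {k.split("::", 1)[1]: v for k, v in arrays.items()
             if k.startswith("optim::")}
    optim.update({k.split("::", 1)[1]: v for k, v in meta["scalars"].items()
                  if k.startswith("optim::")})
    extra = {k.split("::", 1)[1]: v for k, v in arrays.items()
             if k.startswith("extra::")}
    extra.update({k.split("::", 1)[1]: v for k, v in meta["scalars"].items()
                  if k.startswith("extra::")})
    rng = np.random.default_rng()
    rng.bit_generator.state = meta["rng_state"]
    return field_state, poses, arrays["latents"], meta["config"], rng, optim, extra
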