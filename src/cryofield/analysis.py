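"""Latent-space analysis of a trained run.

Standard post-hoc workflow: inspect the per-particle latent embeddings in
2D (PCA; UMAP optionally if installed), cluster with k-means, decode
density maps at cluster centroids, and walk linear latent-space
trajectories between states.  Particle filtering between training rounds
is supported by selecting clusters and writing the subset stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io_formats import ParticleStack, write_volume
from .volume_model import render_map

__all__ = [
    "LatentAnalysis",
    "kmeans_latents",
    "pca_latents",
    "sample_maps",
    "traverse",
    "filter_by_cluster",
]


@dataclass
class LatentAnalysis:
    labels: np.ndarray
    centroids: np.ndarray
    pca_projections: np.ndarray | None = None
    explained_variance_ratio: np.ndarray | None = None
    map_paths: list = field(default_factory=list)


def kmeans_latents(Z: np.ndarray, k: int, seed: int = 0):
    """k-means over latent embeddings; deterministic under the seed."""
    Z = np.asarray(Z, dtype=np.float64)
    if k > Z.shape[0]:
        raise ValueError("k must not exceed the number of particles")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Z)
    return km.labels_, km.cluster_centers_


def pca_latents(Z: np.ndarray, n_components: int = 2):
    """Mean-centered principal components of the latent embeddings.

    Returns (projections, components, explained variance ratios).
    """
    Z = np.asarray(Z, dtype=np.float64)
    n_components = min(n_components, *Z.shape)
    p = PCA(n_components=n_components, svd_solver="full").fit(Z)
    return p.transform(Z), p.components_, p.explained_variance_ratio_


def sample_maps(field, z_list, D: int, outdir=None, pixel_size: float = 1.0,
                gain: float = 1.0) -> list:
    """Decode one density map per latent; optionally write indexed MRC files.

    Returns the maps (and writes ``outdir/map_000.mrc`` … when requested).
    """
    maps = []
    paths = []
    for i, z in enumerate(np.atleast_2d(np.asarray(z_list))):
        m = render_map(field, z.astype(np.float32), D, gain=gain)
        maps.append(m)
        if outdir is not None:
            p = Path(outdir) / f"map_{i:03d}.mrc"
            write_volume(m, pixel_size, p)
            paths.append(p)
    return maps if outdir is None else (maps, paths)


def traverse(field, z_a, z_b, n_steps: int, D: int, gain: float = 1.0) -> list:
    """Decode maps along the line segment between two latents.

    ``n_steps`` maps at equally spaced convex combinations including both
    endpoints (n_steps = 1 gives the midpoint).
    """
    z_a = np.asarray(z_a, dtype=np.float64)
    z_b = np.asarray(z_b, dtype=np.float64)
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if n_steps == 1:
        ws = np.array([0.5])
    else:
        ws = np.linspace(0.0, 1.0, n_steps)
    zs = [(1 - w) * z_a + w * z_b for w in ws]
    return sample_maps(field, zs, D, gain=gain)


def filter_by_cluster(stack: ParticleStack, labels: np.ndarray,
                      keep: list) -> tuple[ParticleStack, np.ndarray]:
    """Subset a stack to the particles whose cluster label is in ``keep``.

    Returns the subset stack and the retained particle indices, ready for a
    second training round.
    """
    labels = np.asarray(labels)
    keep_mask = np.isin(labels, np.asarray(keep))
    part_ids = np.unique(stack.particle_index)[keep_mask] \
        if labels.shape[0] != stack.n_images else None
    if labels.shape[0] == stack.n_images:
        rows = np.where(keep_mask)[0]
    else:  # labels per particle (tilt series)
        rows = np.where(np.isin(stack.particle_index, part_ids))[0]
    sub = ParticleStack(
        stack.images[rows], stack.pixel_size,
        [stack.ctf[r] for r in rows],
        None if stack.tilt is None else [stack.tilt[r] for r in rows],
        stack.particle_index[rows],
    )
    return sub, rows
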