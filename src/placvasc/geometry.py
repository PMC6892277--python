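"""Cord-insertion-centred geometry.

The spatial reference frame of the analysis is the in-plane distance from
the umbilical cord insertion, normalised per direction by the distance from
the cord to the placental edge: 0 at the cord, 100 at the edge, for every
one of 360 rays.  Block locations measured on the chorionic-plate
photograph use the same normalisation (distance to block over distance to
edge through the block, x100).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .stackio import VolumeImage


@dataclass
class PlacentaGeometry:
    """Planar placenta mask with its cord-normalised distance map."""

    mask: np.ndarray  # 2D boolean
    cord_point: tuple[float, float]  # (y, x)
    distance_map: np.ndarray  # float in [0, 100]; NaN outside the mask
    ray_edge_distance: np.ndarray  # (n_rays,) pixel distance cord -> edge
    n_rays: int = 360


def max_intensity_projection(volume: VolumeImage | np.ndarray) -> np.ndarray:
    """Per-pixel maximum over z."""
    vox = volume.voxels if isinstance(volume, VolumeImage) else np.asarray(volume)
    if vox.size == 0:
        raise DataError("empty volume")
    return vox.max(axis=0)


def placenta_mask(tissue_mask: np.ndarray) -> np.ndarray:
    """Planar placenta mask from a 3D tissue mask.

    Projects along z, keeps the largest connected component and fills
    holes — the deterministic surrogate for a manually drawn mask, robust
    to isolated noise voxels above the tissue threshold.
    """
    from scipy import ndimage

    proj = np.asarray(tissue_mask, dtype=bool)
    if proj.ndim == 3:
        proj = proj.any(axis=0)
    labels, n = ndimage.label(proj)
    if n == 0:
        raise DataError("tissue mask is empty")
    largest = 1 + np.argmax(ndimage.sum_labels(proj, labels, np.arange(1, n + 1)))
    return ndimage.binary_fill_holes(labels == largest)


def _ray_edge_distances(
    mask: np.ndarray, cord: tuple[float, float], n_rays: int, step: float = 0.5
) -> np.ndarray:
    """March each ray outwards; edge distance = radial distance of the
    outermost in-mask pixel sample along the ray (nearest-pixel sampling,
    outermost crossing for non-convex masks)."""
    h, w = mask.shape
    cy, cx = cord
    t_max = float(np.hypot(h, w)) + 1.0
    ts = np.arange(0.0, t_max, step)
    angles = np.arange(n_rays) * (2.0 * np.pi / n_rays)
    edges = np.zeros(n_rays)
    for k, ang in enumerate(angles):
        ys = np.rint(cy + ts * np.sin(ang)).astype(int)
        xs = np.rint(cx + ts * np.cos(ang)).astype(int)
        ok = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        hit = np.zeros(ts.shape, dtype=bool)
        hit[ok] = mask[ys[ok], xs[ok]]
        if hit.any():
            last = np.flatnonzero(hit)[-1]
            # radial distance of that pixel's centre, not of the sample point
            edges[k] = float(np.hypot(ys[last] - cy, xs[last] - cx))
    return edges


def compute_distance_map(
    mask: np.ndarray, cord_point: tuple[float, float], n_rays: int = 360
) -> PlacentaGeometry:
    """Normalised (0-100) distance from the cord insertion for every
    in-mask pixel, measured through ``n_rays`` directions.

    Each pixel is assigned the ray nearest its angular position; its value
    is 100 x (radial distance from cord) / (edge distance of its ray).
    """
    mask = np.asarray(mask, dtype=bool)
    cy, cx = cord_point
    iy, ix = int(round(cy)), int(round(cx))
    if not (0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1]) or not mask[iy, ix]:
        raise DataError("cord point lies outside the placenta mask")

    edges = _ray_edge_distances(mask, cord_point, n_rays)
    if np.any(edges <= 0):
        raise DataError("placenta edge coincides with the cord point on some rays")

    yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]].astype(float)
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx)
    ang = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    sector = np.mod(np.rint(ang / (2.0 * np.pi / n_rays)).astype(int), n_rays)
    nd = 100.0 * r / edges[sector]
    nd = np.minimum(nd, 100.0)
    nd[~mask] = np.nan
    return PlacentaGeometry(
        mask=mask,
        cord_point=(float(cy), float(cx)),
        distance_map=nd,
        ray_edge_distance=edges,
        n_rays=n_rays,
    )


def normalise_block_location(d_block_mm: float, d_edge_mm: float) -> float:
    """Normalised block location: 100 x d(cord->block) / d(cord->edge)."""
    if d_edge_mm <= 0:
        raise DataError("cord-to-edge distance must be positive")
    if not 0 <= d_block_mm <= d_edge_mm:
        raise DataError("block distance must lie between 0 and the edge distance")
    return 100.0 * d_block_mm / d_edge_mm
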