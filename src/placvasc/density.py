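"""Vascular density: per-region maps, the 100-bin radial profile, and
block-level density in the basal-third region of interest.

Density is everywhere the vessel volume as a percentage of the tissue
volume (vessels are a subset of tissue under midpoint thresholding, so the
denominator is "tissue plus vessel").  The radial profile bins every
tissue voxel by the integer part of its cord-normalised distance
(half-open bins [b, b+1); bin 99 also takes the value 100) and averages
vessel occupancy per bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .geometry import PlacentaGeometry
from .segmentation import ThresholdPair, segment
from .stackio import ChunkGrid, VolumeImage, split_chunks

N_BINS = 100


@dataclass
class DensityProfile:
    """Mean vascular density (%) per normalised-distance bin 0-99.

    Bins containing no tissue voxels carry NaN density (flagged, never
    zero-filled) and a zero voxel count.
    """

    placenta_id: str
    mean_density_pct: np.ndarray  # (100,)
    n_voxels: np.ndarray  # (100,) tissue voxels per bin

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "placenta_id": self.placenta_id,
                "bin": np.arange(N_BINS),
                "mean_density_pct": self.mean_density_pct,
                "n_voxels": self.n_voxels,
            }
        )

    @property
    def global_density_pct(self) -> float:
        """Voxel-weighted mean over bins == global density of binned tissue."""
        ok = self.n_voxels > 0
        return float(
            np.sum(self.mean_density_pct[ok] * self.n_voxels[ok])
            / np.sum(self.n_voxels[ok])
        )


@dataclass
class BlockDensity:
    """Villous vascular density of one tissue block (basal-third ROI)."""

    placenta_id: str
    block_id: str
    normalised_location: float
    vessel_volume: int
    tissue_plus_vessel_volume: int
    density_pct: float


def _region_counts(mask: np.ndarray, labels: np.ndarray, n_regions: int) -> np.ndarray:
    sel = labels[mask]
    sel = sel[sel >= 0]
    return np.bincount(sel, minlength=n_regions)[:n_regions].astype(np.int64)


def density_map(
    vessel_mask: np.ndarray,
    tissue_mask: np.ndarray,
    region_labels: np.ndarray,
    n_regions: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-region density % and tissue voxel counts.

    ``region_labels`` is an integer array congruent with the masks
    (negative = unassigned).  Regions with no tissue get NaN density.
    """
    if vessel_mask.shape != tissue_mask.shape:
        raise DataError("masks must be congruent")
    if region_labels.shape != tissue_mask.shape:
        region_labels = np.broadcast_to(region_labels, tissue_mask.shape)
    if n_regions is None:
        n_regions = int(region_labels.max()) + 1
    t = _region_counts(tissue_mask, region_labels, n_regions)
    v = _region_counts(vessel_mask & tissue_mask, region_labels, n_regions)
    with np.errstate(invalid="ignore", divide="ignore"):
        dens = np.where(t > 0, 100.0 * v / np.maximum(t, 1), np.nan)
    return dens, t


def density_map_chunked(
    vessel_mask: np.ndarray,
    tissue_mask: np.ndarray,
    region_labels: np.ndarray,
    n_regions: int | None = None,
    grid: ChunkGrid = ChunkGrid(),
) -> tuple[np.ndarray, np.ndarray]:
    """Chunk-wise per-region density; exactly equals :func:`density_map`
    (per-region counting is a pointwise reduction, so no halo is needed)."""
    if region_labels.shape != tissue_mask.shape:
        region_labels = np.broadcast_to(region_labels, tissue_mask.shape).copy()
    if n_regions is None:
        n_regions = int(region_labels.max()) + 1
    t = np.zeros(n_regions, dtype=np.int64)
    v = np.zeros(n_regions, dtype=np.int64)
    lab_chunks = {c.label: c for c in split_chunks(region_labels, grid)}
    ves_chunks = {c.label: c for c in split_chunks(vessel_mask, grid)}
    for c in split_chunks(tissue_mask, grid):
        lab = lab_chunks[c.label].core_view()
        tis = c.core_view()
        ves = ves_chunks[c.label].core_view() & tis
        t += _region_counts(tis, lab, n_regions)
        v += _region_counts(ves, lab, n_regions)
    with np.errstate(invalid="ignore", divide="ignore"):
        dens = np.where(t > 0, 100.0 * v / np.maximum(t, 1), np.nan)
    return dens, t


def chunk_grid_labels(shape_yx: tuple[int, int], grid: ChunkGrid = ChunkGrid()) -> np.ndarray:
    """In-plane region labels of the 10x10 chunk grid (for density maps)."""
    h, w = shape_yx
    sy = -(-h // grid.ny)
    sx = -(-w // grid.nx)
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy // sy) * grid.nx + (xx // sx)


def radial_bins(geometry: PlacentaGeometry) -> np.ndarray:
    """2D bin labels from a normalised distance map (-1 outside the mask)."""
    nd = geometry.distance_map
    bins = np.full(nd.shape, -1, dtype=int)
    ok = np.isfinite(nd)
    bins[ok] = np.minimum(nd[ok].astype(int), N_BINS - 1)
    return bins


def radial_profile(
    vessel_mask: np.ndarray,
    tissue_mask: np.ndarray,
    geometry: PlacentaGeometry,
    placenta_id: str = "phantom",
) -> DensityProfile:
    """Mean vascular density per normalised-distance bin (0 = cord,
    99/100 = edge).  The 2D distance map applies column-wise to all slices."""
    bins = radial_bins(geometry)
    dens, counts = density_map(vessel_mask, tissue_mask, bins, n_regions=N_BINS)
    return DensityProfile(placenta_id, dens, counts)


def global_density_pct(vessel_mask: np.ndarray, tissue_mask: np.ndarray) -> float:
    """Overall vessel volume as % of tissue(-plus-vessel) volume."""
    t = int(tissue_mask.sum())
    if t == 0:
        raise DataError("tissue mask is empty")
    return 100.0 * float((vessel_mask & tissue_mask).sum()) / t


def basal_third_roi(tissue_mask: np.ndarray) -> slice:
    """z-slice range covering the basal (high z) third of the tissue extent."""
    zs = np.flatnonzero(tissue_mask.any(axis=(1, 2)))
    if len(zs) < 3:
        raise DataError("tissue occupies fewer than 3 slices")
    z_lo, z_hi = int(zs[0]), int(zs[-1]) + 1
    extent = z_hi - z_lo
    third = int(np.ceil(extent / 3))
    return slice(z_hi - third, z_hi)


def block_density(
    block_volume: VolumeImage,
    thresholds: ThresholdPair,
    placenta_id: str = "",
    block_id: str = "",
    normalised_location: float = np.nan,
) -> BlockDensity:
    """Villous vascular density of a block: vessel volume over tissue-plus-
    vessel volume, inside the basal-third ROI along z."""
    tissue, vessel = segment(block_volume, thresholds)
    roi = basal_third_roi(tissue)
    t = int(tissue[roi].sum())
    v = int((vessel & tissue)[roi].sum())
    if t == 0:
        raise DataError("no tissue in the basal-third ROI")
    return BlockDensity(
        placenta_id=placenta_id,
        block_id=block_id,
        normalised_location=float(normalised_location),
        vessel_volume=v,
        tissue_plus_vessel_volume=t,
        density_pct=100.0 * v / t,
    )
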