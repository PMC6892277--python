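"""TIFF slice-stack I/O and chunked processing of large volumes.

Volumes are stored as one 2D TIFF per z slice (``slice_0000.tif`` ...) with a
YAML sidecar recording the physical voxel size and stack orientation.  The
z axis runs from the chorionic plate (slice 0) towards the basal plate, so
slices lie parallel to the chorionic plate.

For whole-placenta volumes too large to hold comfortably in memory the
in-plane extent is tiled into a 10 x 10 grid of full-depth chunks.  Chunks
carry their grid label so that any processing order can be re-merged into
the original volume bit-exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml

from .errors import DataError

SIDECAR_NAME = "stack.yaml"
_SLICE_RE = re.compile(r"slice_(\d+)\.tif{1,2}$")


@dataclass
class VolumeImage:
    """A 3D greyscale image with isotropic physical voxel size.

    ``voxels`` is indexed (z, y, x); z increases chorionic -> basal.
    """

    voxels: np.ndarray
    voxel_size_um: float
    orientation: str = "chorionic_to_basal"

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3:
            raise DataError(f"volume must be 3D, got shape {self.voxels.shape}")
        if not self.voxel_size_um > 0:
            raise DataError("voxel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)


def write_stack(volume: VolumeImage, path: str | Path) -> Path:
    """Write ``volume`` as numbered single-slice TIFFs plus a YAML sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for z in range(volume.voxels.shape[0]):
        tifffile.imwrite(path / f"slice_{z:04d}.tif", volume.voxels[z])
    sidecar = {
        "voxel_size_um": float(volume.voxel_size_um),
        "orientation": volume.orientation,
        "n_slices": int(volume.voxels.shape[0]),
    }
    (path / SIDECAR_NAME).write_text(yaml.safe_dump(sidecar))
    return path


def read_stack(path: str | Path, voxel_size_um: float | None = None) -> VolumeImage:
    """Read a numbered TIFF slice stack written by :func:`write_stack`.

    ``voxel_size_um`` overrides (or substitutes for a missing) sidecar value.
    """
    path = Path(path)
    entries = []
    for p in sorted(path.glob("slice_*.tif*")):
        m = _SLICE_RE.search(p.name)
        if m:
            entries.append((int(m.group(1)), p))
    if not entries:
        raise DataError(f"no slices found in {path}")
    entries.sort()
    slices = [tifffile.imread(p) for _, p in entries]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise DataError(f"mismatched slice shapes in {path}: {sorted(shapes)}")
    dtypes = {s.dtype for s in slices}
    if len(dtypes) != 1:
        raise DataError(f"mismatched slice dtypes in {path}")

    orientation = "chorionic_to_basal"
    sidecar_path = path / SIDECAR_NAME
    if sidecar_path.exists():
        meta = yaml.safe_load(sidecar_path.read_text()) or {}
        orientation = meta.get("orientation", orientation)
        if voxel_size_um is None:
            voxel_size_um = meta.get("voxel_size_um")
    if voxel_size_um is None:
        raise DataError(
            f"missing scale metadata: no {SIDECAR_NAME} sidecar in {path} "
            "and no voxel_size_um given"
        )
    return VolumeImage(np.stack(slices, axis=0), float(voxel_size_um), orientation)


@dataclass(frozen=True)
class ChunkGrid:
    """In-plane tiling of a volume into ``ny x nx`` full-depth chunks."""

    ny: int = 10
    nx: int = 10

    def __post_init__(self) -> None:
        if self.ny < 1 or self.nx < 1:
            raise DataError("chunk grid dimensions must be >= 1")


@dataclass
class Chunk:
    """One labelled tile of a volume, optionally with a surrounding halo.

    ``core`` bounds are half-open (z, y, x) ranges in original-volume
    coordinates; ``data`` covers the core plus the (edge-clipped) halo.
    """

    label: tuple[int, int]
    data: np.ndarray
    core: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    halo_lo: tuple[int, int, int]
    volume_shape: tuple[int, int, int]
    halo: int = 0
    extra: dict = field(default_factory=dict)

    def core_view(self) -> np.ndarray:
        """The chunk's own (halo-free) voxels."""
        (z0, z1), (y0, y1), (x0, x1) = self.core
        hz, hy, hx = self.halo_lo
        return self.data[
            hz : hz + (z1 - z0),
            hy : hy + (y1 - y0),
            hx : hx + (x1 - x0),
        ]


def _bounds(extent: int, n: int) -> list[tuple[int, int]]:
    """Half-open tile bounds covering [0, extent) with ceil-sized tiles."""
    size = -(-extent // n)  # ceil division; last tile may be short
    out = []
    for i in range(n):
        lo = i * size
        hi = min(extent, lo + size)
        if lo >= extent:  # degenerate tile when n > extent
            lo = hi = extent
        out.append((lo, hi))
    return out


def split_chunks(
    array: np.ndarray | VolumeImage,
    grid: ChunkGrid = ChunkGrid(),
    halo: int = 0,
) -> list[Chunk]:
    """Tile a volume in-plane into labelled full-depth chunks.

    Halos are clipped at the volume boundary (no padding is introduced:
    tiles that do not divide evenly simply end short at the high edge, and
    :func:`merge_chunks` restores the exact original extent).
    """
    vox = array.voxels if isinstance(array, VolumeImage) else np.asarray(array)
    nz, ny, nx = vox.shape
    chunks: list[Chunk] = []
    for i, (y0, y1) in enumerate(_bounds(ny, grid.ny)):
        for j, (x0, x1) in enumerate(_bounds(nx, grid.nx)):
            if y1 <= y0 or x1 <= x0:
                continue
            gy0, gy1 = max(0, y0 - halo), min(ny, y1 + halo)
            gx0, gx1 = max(0, x0 - halo), min(nx, x1 + halo)
            chunks.append(
                Chunk(
                    label=(i, j),
                    data=vox[:, gy0:gy1, gx0:gx1].copy(),
                    core=((0, nz), (y0, y1), (x0, x1)),
                    halo_lo=(0, y0 - gy0, x0 - gx0),
                    volume_shape=(nz, ny, nx),
                    halo=halo,
                )
            )
    return chunks


def merge_chunks(chunks: Sequence[Chunk]) -> np.ndarray:
    """Recombine labelled chunks (any order) into the original volume.

    Halos are discarded; chunk labels govern placement.  Raises on
    duplicate labels, inconsistent shapes or incomplete coverage.
    """
    if not chunks:
        raise DataError("no chunks to merge")
    shapes = {c.volume_shape for c in chunks}
    if len(shapes) != 1:
        raise DataError("chunks disagree on the parent volume shape")
    labels = [c.label for c in chunks]
    if len(set(labels)) != len(labels):
        raise DataError("duplicate chunk labels on merge")
    out = np.zeros(chunks[0].volume_shape, dtype=chunks[0].data.dtype)
    filled = np.zeros(chunks[0].volume_shape[1:], dtype=bool)
    for c in chunks:
        (z0, z1), (y0, y1), (x0, x1) = c.core
        out[z0:z1, y0:y1, x0:x1] = c.core_view()
        filled[y0:y1, x0:x1] = True
    if not filled.all():
        raise DataError("chunks do not tile the volume")
    return out


def chunked_histogram(
    array: np.ndarray | VolumeImage,
    grid: ChunkGrid = ChunkGrid(),
) -> tuple[np.ndarray, np.ndarray]:
    """Integer-intensity histogram accumulated chunk-wise (exactly equal to
    the whole-volume histogram; no halo needed for a pointwise reduction)."""
    vox = array.voxels if isinstance(array, VolumeImage) else np.asarray(array)
    lo = int(vox.min())
    hi = int(vox.max())
    values = np.arange(lo, hi + 1)
    counts = np.zeros(values.size, dtype=np.int64)
    for c in split_chunks(vox, grid, halo=0):
        core = c.core_view()
        counts += np.bincount(
            (core.astype(np.int64) - lo).ravel(), minlength=values.size
        )[: values.size]
    return values, counts


def chunked_edt(
    mask: np.ndarray,
    grid: ChunkGrid = ChunkGrid(),
    halo: int = 7,
) -> np.ndarray:
    """Euclidean distance transform computed chunk-wise with a halo.

    Values are exact wherever the true distance does not exceed the halo
    width; larger distances are clamped to the halo (sufficient for the
    downstream radius filter, whose threshold is below the default halo).
    """
    from scipy import ndimage

    out = np.zeros(mask.shape, dtype=np.float64)
    for c in split_chunks(mask, grid, halo=halo):
        d = ndimage.distance_transform_edt(c.data)
        (z0, z1), (y0, y1), (x0, x1) = c.core
        hz, hy, hx = c.halo_lo
        out[z0:z1, y0:y1, x0:x1] = d[
            hz : hz + (z1 - z0), hy : hy + (y1 - y0), hx : hx + (x1 - x0)
        ]
    return np.minimum(out, float(halo))
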