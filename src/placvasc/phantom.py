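"""Synthetic phantoms with voxel/pixel-exact ground truth.

Two generators are provided:

* a 3D "whole placenta" phantom: a disc of tissue (slices parallel to the
  chorionic plate, z increasing chorionic -> basal) containing branching
  vessel trees perfused with a bright contrast agent.  The grey-level
  histogram is trimodal (air / tissue / contrast), trees taper across
  branch generations, a controllable fraction of terminal segments can be
  left unperfused (rendered at tissue intensity, i.e. invisible to
  thresholding, as incompletely filled vessels are), and tree placement
  can carry a radial density gradient;

* a 2D "micrograph" phantom: elliptical perfused lumens (bright contrast
  core inside a pale shrinkage rim), unperfused lumens (red-cell filled)
  and villous tissue regions of known analytic area on a pale background.

Trees use recursive branching with per-segment midpoint displacement: the
simplest generative model that yields visually tree-like masks with
controllable density.  No haemodynamic realism is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.draw import ellipse as _draw_ellipse

from .errors import DataError
from .stackio import VolumeImage

# ---------------------------------------------------------------------------
# 3D phantom
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec3D:
    """Parameters of a 3D placental-volume phantom.

    Geometry is a tissue disc of radius ``disc_radius_vox`` and thickness
    ``disc_thickness_vox`` centred in the voxel grid.  ``cord_point`` is an
    in-plane (y, x) coordinate on the chorionic face; defaults to the disc
    centre.  ``fill_fraction`` is the fraction of terminal segments rendered
    at contrast intensity; the rest stay at tissue intensity.
    ``density_gradient`` in [0, 1] linearly thins tree placement towards the
    disc edge (0 = statistically homogeneous).
    """

    shape: tuple[int, int, int] = (40, 128, 128)
    voxel_size_um: float = 116.5
    disc_radius_vox: float = 56.0
    disc_thickness_vox: int = 28
    cord_point: tuple[float, float] | None = None
    n_trees: int = 80
    branch_generations: int = 3
    root_radius_vox: float = 1.6
    taper: float = 0.9
    fill_fraction: float = 1.0
    density_gradient: float = 0.0
    grey_levels: tuple[float, float, float] = (30.0, 120.0, 240.0)
    noise_sd: float | None = None  # default: 10% of the tissue-air gap
    seed: int = 0
    lateral_jitter: float = 0.55
    trunk_length_vox: float | None = None
    root_points: Sequence[tuple[float, float]] | None = None

    def validate(self) -> None:
        air, tissue, contrast = self.grey_levels
        if not air < tissue < contrast:
            raise DataError("grey levels must satisfy air < tissue < contrast")
        if self.root_radius_vox < 1:
            raise DataError("root_radius_vox must be >= 1")
        if not 0.0 <= self.fill_fraction <= 1.0:
            raise DataError("fill_fraction must lie in [0, 1]")
        if not 0.0 < self.taper < 1.0:
            raise DataError("taper must lie in (0, 1)")
        if self.root_radius_vox >= self.disc_thickness_vox:
            raise DataError("vessels cannot fit inside the disc "
                            "(root radius >= disc thickness)")
        nz = self.shape[0]
        if self.disc_thickness_vox > nz:
            raise DataError("disc thicker than the volume")
        if not 0.0 <= self.density_gradient <= 1.0:
            raise DataError("density_gradient must lie in [0, 1]")

    @property
    def effective_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return float(self.noise_sd)
        air, tissue, _ = self.grey_levels
        return 0.1 * (tissue - air)


@dataclass
class GroundTruth3D:
    """Exact ground truth accompanying a 3D phantom."""

    tissue_mask: np.ndarray
    vessel_mask: np.ndarray  # perfused segments only
    centreline_voxels: np.ndarray  # (N, 3) int, (z, y, x)
    radius_vox: np.ndarray  # (N,)
    radius_um: np.ndarray  # (N,)
    true_density_by_bin: np.ndarray  # (100,) vessel-volume fraction, NaN if empty
    bin_tissue_voxels: np.ndarray  # (100,) int
    cord_point: tuple[float, float]
    disc_centre: tuple[float, float]
    disc_radius_vox: float
    z_range: tuple[int, int]
    segments: list = field(default_factory=list, repr=False)

    @property
    def global_density(self) -> float:
        """Vessel-volume fraction of the tissue disc (0-1)."""
        return float(self.vessel_mask.sum()) / float(self.tissue_mask.sum())


@dataclass
class _Segment:
    p0: np.ndarray
    p1: np.ndarray
    radius: float
    generation: int
    tree: int
    terminal: bool
    perfused: bool = True


def rasterise_cylinder(
    mask: np.ndarray, p0, p1, radius: float, value: bool = True
) -> None:
    """Rasterise a finite cylinder (no end caps) into a boolean volume.

    Voxel centres within ``radius`` of the axis segment, with axial
    projection inside [0, |p1-p0|], are set.  A zero-length segment is
    rasterised as a ball.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    lo = np.floor(np.minimum(p0, p1) - radius - 1).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + radius + 1).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, mask.shape)
    if np.any(hi <= lo):
        return
    grids = np.meshgrid(
        *[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij"
    )
    pts = np.stack(grids, axis=-1).astype(float)
    v = p1 - p0
    L2 = float(v @ v)
    rel = pts - p0
    eps = 1e-9 * (1.0 + radius**2)  # absorb cancellation noise at the boundary
    if L2 == 0.0:
        inside = (rel**2).sum(axis=-1) <= radius**2 + eps
    else:
        t = (rel @ v) / L2
        d2 = (rel**2).sum(axis=-1) - (t**2) * L2
        inside = (t >= 0.0) & (t <= 1.0) & (d2 <= radius**2 + eps)
    region = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    region[inside] = value


def analytic_normalised_distance(
    shape_yx: tuple[int, int],
    cord_point: tuple[float, float],
    centre: tuple[float, float],
    radius: float,
) -> np.ndarray:
    """Exact cord-normalised distance (0-100) for a circular disc mask.

    For each pixel, the distance from the cord point is divided by the
    distance from the cord point to the circle edge along the same
    direction.  NaN outside the disc.
    """
    yy, xx = np.mgrid[0 : shape_yx[0], 0 : shape_yx[1]].astype(float)
    cy, cx = cord_point
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx)
    wy, wx = cy - centre[0], cx - centre[1]
    w2 = wy * wy + wx * wx
    with np.errstate(invalid="ignore", divide="ignore"):
        wu = (wy * dy + wx * dx) / r
        t_edge = -wu + np.sqrt(np.maximum(wu * wu + radius**2 - w2, 0.0))
        nd = 100.0 * r / t_edge
    nd[r == 0] = 0.0
    planar_r = np.hypot(yy - centre[0], xx - centre[1])
    nd[planar_r > radius] = np.nan
    return np.minimum(nd, 100.0)


def _radial_sample(rng, n, r_max, gradient):
    """Sample planar radii with pdf proportional to r*(1 - gradient*r/r_max).

    Stratified (jittered) inverse-CDF sampling: the realised radial
    placement intensity tracks the requested profile closely instead of
    carrying full Poisson variance, so the phantom's density gradient (or
    its absence) is a controlled property rather than a noisy one.
    """
    grid = np.linspace(0.0, r_max, 2048)
    pdf = grid * np.clip(1.0 - gradient * grid / r_max, 0.0, None)
    cdf = np.cumsum(pdf)
    cdf /= cdf[-1]
    u = (rng.permutation(n) + rng.random(n)) / n
    return np.interp(u, cdf, grid)


def _perpendicular(rng, d):
    """A random unit vector perpendicular to unit vector d."""
    while True:
        v = rng.normal(size=3)
        v -= (v @ d) * d
        n = np.linalg.norm(v)
        if n > 1e-8:
            return v / n


def _grow_trees(spec: PhantomSpec3D, rng, z_top: float) -> list[_Segment]:
    t = spec.disc_thickness_vox
    gens = spec.branch_generations
    shrink = 0.75
    total = sum(shrink**g for g in range(gens + 1))
    trunk_len = (
        spec.trunk_length_vox
        if spec.trunk_length_vox is not None
        else 0.95 * t / total
    )
    cy = (spec.shape[1] - 1) / 2.0
    cx = (spec.shape[2] - 1) / 2.0

    if spec.root_points is not None:
        roots = [np.array([z_top, y, x]) for y, x in spec.root_points]
    else:
        # Roots are sown in a disc dilated by the expected lateral tree
        # extent so that, after clipping to the tissue disc, coverage is
        # statistically stationary out to the very edge (homogeneous case).
        margin = spec.lateral_jitter * t if spec.density_gradient == 0 else 0.0
        radii = _radial_sample(
            rng, spec.n_trees, spec.disc_radius_vox + margin, spec.density_gradient
        )
        phis = rng.uniform(0.0, 2 * np.pi, spec.n_trees)
        roots = [
            np.array([z_top, cy + r * np.sin(p), cx + r * np.cos(p)])
            for r, p in zip(radii, phis)
        ]

    segments: list[_Segment] = []
    for tree_id, root in enumerate(roots):
        stack = [(root, np.array([1.0, 0.0, 0.0]), 0)]
        while stack:
            p0, d, g = stack.pop()
            length = trunk_len * shrink**g
            radius = spec.root_radius_vox * spec.taper**g
            p1 = p0 + d * length
            segments.append(
                _Segment(p0, p1, radius, g, tree_id, terminal=(g == gens))
            )
            if g < gens:
                perp = _perpendicular(rng, d)
                for sign in (+1.0, -1.0):
                    child = d + sign * spec.lateral_jitter * perp
                    child /= np.linalg.norm(child)
                    if child[0] < 0.2:  # keep growth heading basally
                        child[0] = 0.2
                        child /= np.linalg.norm(child)
                    stack.append((p1, child, g + 1))
    return segments


def _segment_pieces(seg: _Segment, rng, jitter: float):
    """Split a segment at a laterally displaced midpoint (two pieces)."""
    v = seg.p1 - seg.p0
    L = np.linalg.norm(v)
    if L == 0 or jitter == 0:
        return [(seg.p0, seg.p1)]
    d = v / L
    perp = _perpendicular(rng, d)
    mid = (seg.p0 + seg.p1) / 2.0 + perp * (0.15 * jitter * L * rng.normal())
    return [(seg.p0, mid), (mid, seg.p1)]


def generate_volume_phantom(
    spec: PhantomSpec3D,
) -> tuple[VolumeImage, GroundTruth3D]:
    """Render a 3D phantom and its exact ground truth.

    Deterministic for a fixed seed (bit-identical volumes).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    cord = spec.cord_point if spec.cord_point is not None else (cy, cx)
    z0 = (nz - spec.disc_thickness_vox) // 2
    z1 = z0 + spec.disc_thickness_vox

    # tissue disc
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    in_disc_2d = np.hypot(yy - cy, xx - cx) <= spec.disc_radius_vox
    tissue = np.zeros(spec.shape, dtype=bool)
    tissue[z0:z1] = in_disc_2d

    segments = _grow_trees(spec, rng, z_top=float(z0))

    # decide perfusion of terminal segments (exact count, random choice)
    terminals = [s for s in segments if s.terminal]
    n_unperf = int(round((1.0 - spec.fill_fraction) * len(terminals)))
    if terminals and n_unperf:
        idx = rng.choice(len(terminals), size=n_unperf, replace=False)
        for i in idx:
            terminals[i].perfused = False

    vessel = np.zeros(spec.shape, dtype=bool)
    centre_vox: list[np.ndarray] = []
    centre_rad: list[np.ndarray] = []
    for seg in segments:
        pieces = _segment_pieces(seg, rng, spec.lateral_jitter)
        if not seg.perfused:
            continue
        for p0, p1 in pieces:
            rasterise_cylinder(vessel, p0, p1, seg.radius)
            L = np.linalg.norm(p1 - p0)
            n_pts = max(2, int(np.ceil(L / 0.5)) + 1)
            ts = np.linspace(0.0, 1.0, n_pts)
            pts = np.rint(p0 + ts[:, None] * (p1 - p0)).astype(int)
            centre_vox.append(pts)
            centre_rad.append(np.full(len(pts), seg.radius))
    vessel &= tissue

    if centre_vox:
        coords = np.concatenate(centre_vox)
        rads = np.concatenate(centre_rad)
        coords, keep = np.unique(coords, axis=0, return_index=True)
        rads = rads[keep]
        inside = (
            (coords[:, 0] >= 0) & (coords[:, 0] < nz)
            & (coords[:, 1] >= 0) & (coords[:, 1] < ny)
            & (coords[:, 2] >= 0) & (coords[:, 2] < nx)
        )
        coords, rads = coords[inside], rads[inside]
        on = tissue[coords[:, 0], coords[:, 1], coords[:, 2]]
        coords, rads = coords[on], rads[on]
    else:
        coords = np.zeros((0, 3), dtype=int)
        rads = np.zeros(0)

    # grey-level rendering
    air, tis, con = spec.grey_levels
    vol = np.full(spec.shape, air, dtype=np.float64)
    vol[tissue] = tis
    vol[vessel] = con
    sd = spec.effective_noise_sd
    if sd > 0:
        vol += rng.normal(0.0, sd, size=spec.shape)
    vol = np.clip(np.rint(vol), 0, np.iinfo(np.uint16).max).astype(np.uint16)

    # exact per-bin density from analytic cord geometry
    nd = analytic_normalised_distance((ny, nx), cord, (cy, cx), spec.disc_radius_vox)
    bins2d = np.full((ny, nx), -1, dtype=int)
    valid = np.isfinite(nd)
    bins2d[valid] = np.minimum(nd[valid].astype(int), 99)
    bins3d = np.broadcast_to(bins2d, spec.shape)
    t_counts = np.bincount(bins3d[tissue] , minlength=100)[:100].astype(np.int64)
    v_counts = np.bincount(bins3d[vessel], minlength=100)[:100].astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(t_counts > 0, v_counts / np.maximum(t_counts, 1), np.nan)

    truth = GroundTruth3D(
        tissue_mask=tissue,
        vessel_mask=vessel,
        centreline_voxels=coords,
        radius_vox=rads,
        radius_um=rads * spec.voxel_size_um,
        true_density_by_bin=density,
        bin_tissue_voxels=t_counts,
        cord_point=tuple(cord),
        disc_centre=(cy, cx),
        disc_radius_vox=spec.disc_radius_vox,
        z_range=(z0, z1),
        segments=segments,
    )
    return VolumeImage(vol, spec.voxel_size_um), truth


def tree_volume_vox(spec: PhantomSpec3D) -> float:
    """Analytic (overlap-free) voxel volume of one tree under ``spec``."""
    shrink = 0.75
    total = sum(shrink**g for g in range(spec.branch_generations + 1))
    trunk_len = (
        spec.trunk_length_vox
        if spec.trunk_length_vox is not None
        else 0.95 * spec.disc_thickness_vox / total
    )
    v = 0.0
    for g in range(spec.branch_generations + 1):
        r = spec.root_radius_vox * spec.taper**g
        v += (2**g) * np.pi * r * r * trunk_len * shrink**g
    return v


def trees_for_target_density(spec: PhantomSpec3D, target_fraction: float) -> int:
    """Number of trees expected to give ``target_fraction`` vessel volume.

    Analytic estimate ignoring inter-tree overlap; accounts for root sowing
    in the dilated disc (a fraction of each edge tree falls outside the
    tissue and is clipped).
    """
    t_vol = np.pi * spec.disc_radius_vox**2 * spec.disc_thickness_vox
    margin = spec.lateral_jitter * spec.disc_thickness_vox
    dilution = ((spec.disc_radius_vox + margin) / spec.disc_radius_vox) ** 2
    n = target_fraction * t_vol * dilution / tree_volume_vox(spec)
    return max(1, int(round(n)))


# ---------------------------------------------------------------------------
# 2D micrograph phantom
# ---------------------------------------------------------------------------

#: canonical rendering colours; the perfused-lumen class shares the white of
#: the slide background (contrast agent plus shrinkage white space and
#: background form a single class downstream, as they do on real sections)
CLASS_COLOURS: dict[str, tuple[int, int, int]] = {
    "perfused": (255, 255, 255),
    "unperfused": (190, 40, 55),
    "villous": (230, 140, 160),
}
MICROFIL_COLOUR: tuple[int, int, int] = (238, 220, 130)
CLASS_NAMES: tuple[str, str, str] = ("perfused", "unperfused", "villous")


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned-by-default ellipse: centre (cy, cx), semi-axes (a, b)
    in pixels, rotation in degrees."""

    cy: float
    cx: float
    a: float
    b: float
    rotation_deg: float = 0.0

    def area_um2(self, um_per_px: float) -> float:
        return float(np.pi * self.a * self.b * um_per_px**2)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        rr, cc = _draw_ellipse(
            self.cy, self.cx, self.a, self.b,
            shape=shape, rotation=np.deg2rad(self.rotation_deg),
        )
        m[rr, cc] = True
        return m


@dataclass
class PhantomSpec2D:
    """Parameters of a 2D micrograph phantom.

    Vessel lumens normally lie inside villous tissue, as they do on real
    sections: a lumen ellipse overlapping a villous region carves its lumen
    out of the villus, so the three classes stay disjoint by construction.
    A lumen that straddles a villous boundary, or perfused and unperfused
    lumens that overlap each other, is rejected.
    """

    shape: tuple[int, int] = (768, 768)
    um_per_px: float = 1.0
    perfused: Sequence[Ellipse] = field(default_factory=list)
    unperfused: Sequence[Ellipse] = field(default_factory=list)
    villous: Sequence[Ellipse] = field(default_factory=list)
    rim_fraction: float = 0.35  # contrast-shrinkage white rim of perfused lumens
    noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.shape
        for name in CLASS_NAMES:
            for e in getattr(self, name):
                ext = max(e.a, e.b)
                if not (0 <= e.cy - ext and e.cy + ext < h
                        and 0 <= e.cx - ext and e.cx + ext < w):
                    raise DataError(f"{name} ellipse {e} does not lie within the image")


def generate_micrograph_phantom(
    spec: PhantomSpec2D,
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, list[float]]]:
    """Render a micrograph phantom.

    Returns the 8-bit RGB image, disjoint per-class boolean ground-truth
    masks (villous tissue net of the lumens carved out of it), and
    per-ellipse analytic areas (pi*a*b, um^2) per class.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape

    villous_union = np.zeros((h, w), dtype=bool)
    for e in spec.villous:
        villous_union |= e.mask((h, w))
    lumen_masks = {}
    for name in ("perfused", "unperfused"):
        m = np.zeros((h, w), dtype=bool)
        for e in getattr(spec, name):
            em = e.mask((h, w))
            inside = int((em & villous_union).sum())
            if inside not in (0, int(em.sum())):
                raise DataError(
                    f"{name} ellipse {e} straddles a villous boundary "
                    "(overlapping ellipses of different classes)"
                )
            m |= em
        lumen_masks[name] = m
    if np.any(lumen_masks["perfused"] & lumen_masks["unperfused"]):
        raise DataError(
            "overlapping ellipses of different classes: perfused/unperfused"
        )
    masks = {
        "perfused": lumen_masks["perfused"],
        "unperfused": lumen_masks["unperfused"],
        "villous": villous_union
        & ~lumen_masks["perfused"]
        & ~lumen_masks["unperfused"],
    }

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = CLASS_COLOURS["perfused"]  # background = white
    img[masks["villous"]] = CLASS_COLOURS["villous"]
    img[masks["unperfused"]] = CLASS_COLOURS["unperfused"]
    img[masks["perfused"]] = CLASS_COLOURS["perfused"]  # shrinkage white space
    for e in spec.perfused:  # contrast core inside the white rim
        core = Ellipse(
            e.cy, e.cx,
            e.a * (1.0 - spec.rim_fraction),
            e.b * (1.0 - spec.rim_fraction),
            e.rotation_deg,
        )
        img[core.mask((h, w))] = MICROFIL_COLOUR
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    areas = {
        name: [e.area_um2(spec.um_per_px) for e in getattr(spec, name)]
        for name in CLASS_NAMES
    }
    return img, masks, areas


def random_micrograph_spec(
    seed: int = 0,
    shape: tuple[int, int] = (640, 640),
    um_per_px: float = 1.0,
    n_villi: int = 6,
    lumens_per_villus: tuple[int, int] = (2, 4),
    perfused_probability: float = 0.85,
    lumen_radius_px: tuple[float, float] = (8.0, 30.0),
) -> PhantomSpec2D:
    """A realistic random micrograph scene: villous profiles on a jittered
    grid, each containing a few lumens, perfused with given probability.

    ``perfused_probability`` controls the expected vascular fill; the exact
    analytic fill follows from the generated ellipse areas.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    cells = int(np.ceil(np.sqrt(n_villi)))
    step_y, step_x = h / cells, w / cells
    villous, perfused, unperfused = [], [], []
    order = rng.permutation(cells * cells)[:n_villi]
    for cell in order:
        gy, gx = divmod(int(cell), cells)
        a = rng.uniform(0.28, 0.40) * min(step_y, step_x)
        b = a * rng.uniform(0.65, 1.0)
        cy = (gy + 0.5) * step_y + rng.uniform(-0.05, 0.05) * step_y
        cx = (gx + 0.5) * step_x + rng.uniform(-0.05, 0.05) * step_x
        rot = rng.uniform(0, 180)
        villus = Ellipse(cy, cx, a, b, rot)
        villous.append(villus)
        n_lumen = rng.integers(lumens_per_villus[0], lumens_per_villus[1] + 1)
        placed: list[Ellipse] = []
        for _ in range(int(n_lumen)):
            for _attempt in range(30):
                la = rng.uniform(*lumen_radius_px)
                lb = la * rng.uniform(0.6, 1.0)
                ext = la + 2
                # place well inside the villus (conservative inscribed box)
                ry = (min(a, b) / np.sqrt(2.0)) - ext
                if ry <= 0:
                    break
                ly = cy + rng.uniform(-ry, ry)
                lx = cx + rng.uniform(-ry, ry)
                cand = Ellipse(ly, lx, la, lb, rng.uniform(0, 180))
                if all(
                    np.hypot(p.cy - ly, p.cx - lx) > (max(p.a, p.b) + la + 2)
                    for p in placed
                ):
                    placed.append(cand)
                    break
        for lum in placed:
            if rng.random() < perfused_probability:
                perfused.append(lum)
            else:
                unperfused.append(lum)
    return PhantomSpec2D(
        shape=shape,
        um_per_px=um_per_px,
        perfused=perfused,
        unperfused=unperfused,
        villous=villous,
        seed=seed,
    )
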