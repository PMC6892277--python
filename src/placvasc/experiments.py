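"""Reference experiments over the synthetic phantoms.

These routines define the study conditions exercised by the analysis
scripts, the test suite and the acceptance script: density recovery on
phantoms of known vessel-volume fraction, the null spatial pattern
(homogeneous phantoms yield flat profiles and non-significant
density-location correlations), and the calibration of the statistical
layer.  Problem sizes are kept at desk scale (volumes of about 128^3 and
below) so a full pass runs in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import block_density, global_density_pct, radial_profile
from .geometry import compute_distance_map, placenta_mask
from .phantom import (
    PhantomSpec3D,
    generate_volume_phantom,
    trees_for_target_density,
)
from .segmentation import find_thresholds, segment
from .stats import spearman

#: ground-truth vessel-volume fractions exercised in density recovery
RECOVERY_TARGET_FRACTIONS = (0.02, 0.05, 0.10)


def recovery_spec(target_fraction: float, seed: int) -> PhantomSpec3D:
    """Phantom used for density recovery: 128^2 x 40 disc, thin villous-
    calibre vessels, cord at the disc centre."""
    spec = PhantomSpec3D(seed=seed)
    spec.n_trees = trees_for_target_density(spec, target_fraction)
    return spec


@dataclass
class RecoveryResult:
    target_fraction: float
    seed: int
    true_density_pct: float
    estimated_density_pct: float
    vessel_dice: float
    per_bin_max_abs_err_pp: float  # shared spatial binning
    profile_global_rel_err: float

    @property
    def global_rel_err(self) -> float:
        return abs(self.estimated_density_pct - self.true_density_pct) / (
            self.true_density_pct
        )


def run_density_recovery(
    target_fraction: float, seed: int
) -> RecoveryResult:
    """Generate a phantom, run the whole-placenta measurement chain, and
    compare estimated densities with the rendered ground truth."""
    spec = recovery_spec(target_fraction, seed)
    volume, truth = generate_volume_phantom(spec)
    thresholds = find_thresholds(volume)
    tissue, vessel = segment(volume, thresholds)
    dice = (
        2.0 * np.sum(vessel & truth.vessel_mask)
        / (vessel.sum() + truth.vessel_mask.sum())
    )
    geometry = compute_distance_map(placenta_mask(tissue), truth.cord_point)
    est_prof = radial_profile(vessel, tissue, geometry)
    true_prof = radial_profile(truth.vessel_mask, truth.tissue_mask, geometry)
    ok = (est_prof.n_voxels > 0) & (true_prof.n_voxels > 0)
    per_bin = float(
        np.nanmax(
            np.abs(est_prof.mean_density_pct[ok] - true_prof.mean_density_pct[ok])
        )
    )
    est = global_density_pct(vessel, tissue)
    true = 100.0 * truth.global_density
    return RecoveryResult(
        target_fraction=target_fraction,
        seed=seed,
        true_density_pct=true,
        estimated_density_pct=est,
        vessel_dice=float(dice),
        per_bin_max_abs_err_pp=per_bin,
        profile_global_rel_err=abs(est_prof.global_density_pct - true) / true,
    )


# ---------------------------------------------------------------------------
# null spatial pattern
# ---------------------------------------------------------------------------


def null_spec(seed: int) -> PhantomSpec3D:
    """Homogeneous (no radial gradient) phantom used for the null-pattern
    runs: a wide thin disc so the 100 radial bins are well resolved."""
    spec = PhantomSpec3D(
        shape=(24, 256, 256),
        disc_radius_vox=112.0,
        disc_thickness_vox=16,
        seed=seed,
        density_gradient=0.0,
    )
    spec.n_trees = trees_for_target_density(spec, 0.04)
    return spec


@dataclass
class NullRunResult:
    seed: int
    r_s: float
    p: float
    n_blocks: int
    profile_pct: np.ndarray  # (100,)
    profile_n_voxels: np.ndarray  # (100,)
    profile_trend_r: float  # Spearman bin vs density over interior bins

    @property
    def non_significant(self) -> bool:
        return abs(self.r_s) < 0.3 and self.p > 0.05


def _sample_block_centres(rng, truth, half: int, n_blocks: int):
    """Non-overlapping planar block centres, uniform by area, blocks fully
    inside the disc (independent spatial samples, as physical blocks are)."""
    r_max = truth.disc_radius_vox - half - 1.0
    min_sep = 2.0 * half + 1.0
    out: list[tuple[int, int]] = []
    attempts = 0
    while len(out) < n_blocks and attempts < 50_000:
        attempts += 1
        r = r_max * np.sqrt(rng.random())
        phi = rng.uniform(0, 2 * np.pi)
        cy = int(round(truth.disc_centre[0] + r * np.sin(phi)))
        cx = int(round(truth.disc_centre[1] + r * np.cos(phi)))
        if all(max(abs(cy - y), abs(cx - x)) >= min_sep for y, x in out):
            out.append((cy, cx))
    if len(out) < n_blocks:
        raise RuntimeError("could not place the requested number of blocks")
    return out


def run_null_pattern(seed: int, n_blocks: int = 60, block_half: int = 8) -> NullRunResult:
    """One homogeneous-phantom run: measured radial profile plus the
    block-density versus block-location rank correlation."""
    spec = null_spec(seed)
    volume, truth = generate_volume_phantom(spec)
    thresholds = find_thresholds(volume)
    tissue, vessel = segment(volume, thresholds)
    geometry = compute_distance_map(placenta_mask(tissue), truth.cord_point)
    profile = radial_profile(vessel, tissue, geometry)

    interior = np.arange(5, 96)
    ok = interior[profile.n_voxels[interior] > 0]
    trend = spearman(ok, profile.mean_density_pct[ok])

    rng = np.random.default_rng(seed + 1_000_003)
    centres = _sample_block_centres(rng, truth, block_half, n_blocks)
    dens, locs = [], []
    from .stackio import VolumeImage

    for cy, cx in centres:
        sub = volume.voxels[:, cy - block_half : cy + block_half,
                            cx - block_half : cx + block_half]
        bd = block_density(
            VolumeImage(sub.copy(), volume.voxel_size_um), thresholds
        )
        dens.append(bd.density_pct)
        locs.append(float(geometry.distance_map[cy, cx]))
    corr = spearman(locs, dens)
    return NullRunResult(
        seed=seed,
        r_s=corr.r_s,
        p=corr.p,
        n_blocks=n_blocks,
        profile_pct=profile.mean_density_pct,
        profile_n_voxels=profile.n_voxels,
        profile_trend_r=trend.r_s,
    )


def profile_flatness(
    profiles: list[np.ndarray],
    n_voxels: list[np.ndarray] | None = None,
    bins=slice(5, 96),
    min_count_fraction: float = 1.0 / 3.0,
) -> dict:
    """Replicate-spread flatness check over interior, adequately sampled bins.

    A profile is called flat when the range (max - min) of the across-run
    mean profile does not exceed twice the median per-bin Monte-Carlo SD.
    Bins whose tissue voxel count falls below ``min_count_fraction`` of the
    median bin count are under-sampled (the innermost annuli are smaller
    than a voxel footprint) and are excluded, as empty bins are.
    """
    arr = np.stack(profiles)[:, bins]
    keep = np.ones(arr.shape[1], dtype=bool)
    if n_voxels is not None:
        counts = np.stack(n_voxels)[:, bins].astype(float).mean(axis=0)
        keep = counts >= min_count_fraction * np.median(counts)
    mean = np.nanmean(arr[:, keep], axis=0)
    sd = np.nanstd(arr[:, keep], axis=0, ddof=1)
    return {
        "mean_range_pp": float(np.nanmax(mean) - np.nanmin(mean)),
        "mc_sd_pp": float(np.nanmedian(sd)),
        "n_bins": int(keep.sum()),
    }


# ---------------------------------------------------------------------------
# histology inclusion bookkeeping
# ---------------------------------------------------------------------------

#: designed >200 um^2 vascular fills for the phantom-histology manifest,
#: spread on both sides of the 75% inclusion rule and away from the boundary
DESIGNED_FILLS_PCT = (100.0, 95.0, 88.0, 82.0, 68.0, 60.0, 45.0, 100.0, 90.0, 55.0)


def _fill_scene_spec(fill_pct: float, seed: int):
    """A one-villus micrograph whose analytic vascular fill is designed.

    Perfused and unperfused lumen areas are chosen so that
    100 x perfused / total equals ``fill_pct``; every lumen is larger than
    the 200 um^2 cutoff at 1 um/px.
    """
    from .phantom import Ellipse, PhantomSpec2D

    rng = np.random.default_rng(seed)
    cy = cx = 192.0
    villus = Ellipse(cy, cx, 150.0, 150.0)
    unperfused = []
    if fill_pct < 100.0:
        # size from the unperfused lumen up so both lumens clear the
        # 200 um^2 cutoff at every designed fill
        f = fill_pct / 100.0
        ru = rng.uniform(9.5, 12.0)
        rp = ru * np.sqrt(f / (1.0 - f))
        unperfused.append(Ellipse(cy + 70, cx + 70, ru, ru))
    else:
        rp = rng.uniform(22.0, 30.0)
    perfused = [Ellipse(cy - 60, cx - 60, rp, rp)]
    return PhantomSpec2D(
        shape=(384, 384), um_per_px=1.0,
        perfused=perfused, unperfused=unperfused, villous=[villus],
        seed=seed,
    )


def run_inclusion_bookkeeping(seed: int = 0, fills=DESIGNED_FILLS_PCT):
    """Build a phantom-histology block table with designed fills, apply the
    75% inclusion rule, and return (block table, designed excluded count)."""
    import pandas as pd

    from .histology import analyse_micrograph, apply_inclusion_rule, summarise_block
    from .phantom import generate_micrograph_phantom

    rows = []
    for i, fill in enumerate(fills):
        spec = _fill_scene_spec(fill, seed + 17 * i)
        img, _, _ = generate_micrograph_phantom(spec)
        parts, villous = analyse_micrograph(img, spec.um_per_px)
        bh = summarise_block("P1", f"b{i}", [parts], [villous])
        rows.append(
            {
                "placenta_id": bh.placenta_id,
                "block_id": bh.block_id,
                "designed_fill_pct": fill,
                "fill_200_pct": bh.fill_200_pct,
                "density_pct": bh.density_pct,
                "included": bh.included,
            }
        )
    blocks = pd.DataFrame(rows)
    included = apply_inclusion_rule(blocks)
    designed_excluded = int(sum(f < 75.0 for f in fills))
    return blocks, len(blocks) - len(included), designed_excluded


# ---------------------------------------------------------------------------
# statistical calibration
# ---------------------------------------------------------------------------


def kruskal_type1_rate(
    n_sims: int = 1000, n_per_group: int = 20, seed: int = 0, alpha: float = 0.05
) -> float:
    """Type-I error of the Kruskal-Wallis test under a two-group null."""
    from scipy.stats import kruskal

    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        a = rng.normal(size=n_per_group)
        b = rng.normal(size=n_per_group)
        _, p = kruskal(a, b)
        rejections += p < alpha
    return rejections / n_sims


def spearman_p_uniformity(n_sims: int = 1000, n: int = 50, seed: int = 0) -> float:
    """KS p-value of Spearman p-values against uniform, under independence."""
    from scipy.stats import kstest

    rng = np.random.default_rng(seed)
    ps = np.empty(n_sims)
    for i in range(n_sims):
        ps[i] = spearman(rng.random(n), rng.random(n)).p
    return float(kstest(ps, "uniform").pvalue)
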