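import numpy as np
import pytest

from placvasc.density import (
    BlockDensity,
    basal_third_roi,
    block_density,
    chunk_grid_labels,
    density_map,
    density_map_chunked,
    global_density_pct,
    radial_bins,
    radial_profile,
)
from placvasc.errors import DataError
from placvasc.geometry import compute_distance_map, placenta_mask
from placvasc.phantom import analytic_normalised_distance
from placvasc.segmentation import ThresholdPair
from placvasc.stackio import ChunkGrid, VolumeImage
from placvasc.stats import spearman

AIR, TISSUE, CONTRAST = 30, 120, 240
THR = ThresholdPair(75.0, 180.0)


class TestDensityMap:
    def test_region_full_of_vessel_is_100(self):
        tissue = np.ones((4, 8, 8), bool)
        vessel = np.zeros_like(tissue)
        labels = np.zeros((4, 8, 8), int)
        labels[:, :, 4:] = 1
        vessel[:, :, 4:] = True
        dens, _ = density_map(vessel, tissue, labels)
        assert dens[0] == 0.0 and dens[1] == 100.0

    def test_empty_vessel_mask_is_zero_where_tissue(self):
        tissue = np.ones((4, 8, 8), bool)
        dens, counts = density_map(np.zeros_like(tissue), tissue,
                                   np.zeros((4, 8, 8), int))
        assert dens[0] == 0.0 and counts[0] == tissue.sum()

    def test_region_without_tissue_flagged_nan(self):
        tissue = np.zeros((2, 4, 4), bool)
        tissue[:, :2] = True
        labels = np.zeros((2, 4, 4), int)
        labels[:, 2:] = 1
        dens, _ = density_map(np.zeros_like(tissue), tissue, labels)
        assert dens[0] == 0.0 and np.isnan(dens[1])

    def test_phantom_density_map_matches_truth_bins(self, default_phantom):
        """Per-region density against ground truth on common region labels."""
        truth = default_phantom["truth"]
        nd = analytic_normalised_distance(
            truth.tissue_mask.shape[1:], truth.cord_point,
            truth.disc_centre, truth.disc_radius_vox,
        )
        labels2d = np.full(nd.shape, -1, int)
        ok = np.isfinite(nd)
        labels2d[ok] = np.minimum(nd[ok].astype(int), 99)
        est, _ = density_map(
            default_phantom["vessel"], default_phantom["tissue"], labels2d, 100
        )
        true = 100.0 * truth.true_density_by_bin
        both = np.isfinite(est) & np.isfinite(true)
        assert np.abs(est[both] - true[both]).max() <= 0.5

    def test_chunked_density_map_equals_whole_volume(self, rng):
        tissue = rng.random((12, 60, 60)) < 0.8
        vessel = tissue & (rng.random((12, 60, 60)) < 0.1)
        labels = chunk_grid_labels((60, 60), ChunkGrid(5, 5))
        d1, c1 = density_map(vessel, tissue, labels, 25)
        d2, c2 = density_map_chunked(vessel, tissue, labels, 25, ChunkGrid(4, 7))
        assert np.array_equal(c1, c2)
        assert np.allclose(d1, d2, equal_nan=True)


class TestRadialProfile:
    def _profile(self, vessel, tissue, cord):
        geo = compute_distance_map(placenta_mask(tissue), cord)
        return radial_profile(vessel, tissue, geo)

    def test_all_vessel_disc_is_100_everywhere(self):
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        disc2d = np.hypot(yy - 32, xx - 32) <= 28
        tissue = np.broadcast_to(disc2d, (8, 64, 64)).copy()
        prof = self._profile(tissue.copy(), tissue, (32.0, 32.0))
        vals = prof.mean_density_pct[prof.n_voxels > 0]
        assert np.allclose(vals, 100.0)

    def test_vessel_voxel_conservation_across_bins(self, default_phantom):
        tissue, vessel = default_phantom["tissue"], default_phantom["vessel"]
        truth = default_phantom["truth"]
        geo = compute_distance_map(placenta_mask(tissue), truth.cord_point)
        prof = radial_profile(vessel, tissue, geo)
        binned_vessels = np.nansum(prof.mean_density_pct * prof.n_voxels) / 100.0
        bins = radial_bins(geo)
        in_map = np.broadcast_to(bins >= 0, tissue.shape)
        assert binned_vessels == pytest.approx((vessel & tissue & in_map).sum())

    def test_voxel_weighted_mean_equals_global_density(self, default_phantom):
        tissue, vessel = default_phantom["tissue"], default_phantom["vessel"]
        truth = default_phantom["truth"]
        geo = compute_distance_map(placenta_mask(tissue), truth.cord_point)
        prof = radial_profile(vessel, tissue, geo)
        bins = radial_bins(geo)
        in_map = np.broadcast_to(bins >= 0, tissue.shape)
        ref = global_density_pct(vessel & in_map, tissue & in_map)
        assert prof.global_density_pct == pytest.approx(ref, rel=1e-6)

    def test_homogeneous_phantom_profile_is_flat(self, null_runs):
        from placvasc.experiments import profile_flatness

        flat = profile_flatness(
            [r.profile_pct for r in null_runs],
            [r.profile_n_voxels for r in null_runs],
        )
        assert flat["mean_range_pp"] <= 2.0 * flat["mc_sd_pp"]

    def test_gradient_phantom_profile_decreases(self):
        from placvasc.experiments import null_spec
        from placvasc.phantom import generate_volume_phantom, trees_for_target_density
        from placvasc.segmentation import find_thresholds, segment

        spec = null_spec(seed=2)
        spec.density_gradient = 1.0
        spec.n_trees = trees_for_target_density(spec, 0.10)
        vol, truth = generate_volume_phantom(spec)
        tissue, vessel = segment(vol, find_thresholds(vol))
        prof = self._profile(vessel, tissue, truth.cord_point)
        b = np.arange(5, 96)
        ok = b[prof.n_voxels[b] > 0]
        assert spearman(ok, prof.mean_density_pct[ok]).r_s < -0.9


class TestBlockDensity:
    def _block(self, vessel_fraction_roi, rng, shape=(30, 24, 24)):
        """Grey block: tissue everywhere in z 3..27, vessels only in the
        basal third, at an exact voxel fraction."""
        vox = np.full(shape, AIR, dtype=np.uint16)
        vox[3:27] = TISSUE
        roi = slice(19, 27)  # basal third of tissue extent 3..27
        n_roi = 8 * shape[1] * shape[2]
        n_ves = int(round(vessel_fraction_roi * n_roi))
        flat = rng.choice(n_roi, size=n_ves, replace=False)
        view = vox[roi].reshape(-1)
        view[flat] = CONTRAST
        return VolumeImage(vox, 13.5)

    def test_roi_is_basal_third_of_tissue_extent(self):
        tissue = np.zeros((30, 4, 4), bool)
        tissue[3:27] = True
        assert basal_third_roi(tissue) == slice(19, 27)

    def test_known_fill_recovered(self, rng):
        vol = self._block(0.10, rng)
        bd = block_density(vol, THR, "P1", "b1", 40.0)
        assert bd.density_pct == pytest.approx(10.0, abs=1.0)
        assert isinstance(bd, BlockDensity)
        assert bd.tissue_plus_vessel_volume >= bd.vessel_volume

    def test_no_vessels_zero_density(self, rng):
        vol = self._block(0.0, rng)
        assert block_density(vol, THR).density_pct == 0.0

    def test_uniform_fraction_matches_whole_block(self):
        vox = np.full((30, 24, 24), AIR, dtype=np.uint16)
        vox[3:27] = TISSUE
        vox[3:27, ::2, ::2] = CONTRAST  # exact 25% everywhere
        vol = VolumeImage(vox, 13.5)
        bd = block_density(vol, THR)
        tissue, vessel = (vox >= 75), (vox >= 180)
        whole = 100.0 * vessel.sum() / tissue.sum()
        assert abs(bd.density_pct - whole) <= 0.5

    def test_too_few_tissue_slices_rejected(self):
        vox = np.full((5, 8, 8), AIR, dtype=np.uint16)
        vox[2] = TISSUE
        with pytest.raises(DataError, match="3 slices"):
            block_density(VolumeImage(vox, 13.5), THR)
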