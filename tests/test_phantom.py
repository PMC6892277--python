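import numpy as np
import pytest

from placvasc.errors import DataError
from placvasc.phantom import (
    Ellipse,
    PhantomSpec2D,
    PhantomSpec3D,
    analytic_normalised_distance,
    generate_micrograph_phantom,
    generate_volume_phantom,
    random_micrograph_spec,
    rasterise_cylinder,
    trees_for_target_density,
)
from placvasc.stats import spearman


class TestVolumePhantom:
    def test_no_trees_means_no_vessels(self):
        spec = PhantomSpec3D(n_trees=0, seed=0)
        _, truth = generate_volume_phantom(spec)
        assert not truth.vessel_mask.any()
        dens = truth.true_density_by_bin
        assert np.all(dens[np.isfinite(dens)] == 0.0)

    def test_single_straight_trunk_volume_matches_cylinder(self):
        spec = PhantomSpec3D(
            shape=(60, 40, 40),
            disc_radius_vox=16.0,
            disc_thickness_vox=56,
            n_trees=1,
            branch_generations=0,
            root_radius_vox=3.0,
            trunk_length_vox=50.0,
            lateral_jitter=0.0,
            noise_sd=0.0,
            root_points=[(20.0, 20.0)],
            seed=0,
        )
        _, truth = generate_volume_phantom(spec)
        analytic = np.pi * 3.0**2 * 50.0
        assert abs(truth.vessel_mask.sum() - analytic) <= 0.10 * analytic

    def test_same_seed_is_bit_identical(self):
        spec = dict(shape=(24, 64, 64), disc_radius_vox=28.0,
                    disc_thickness_vox=16, n_trees=20, seed=42)
        v1, t1 = generate_volume_phantom(PhantomSpec3D(**spec))
        v2, t2 = generate_volume_phantom(PhantomSpec3D(**spec))
        assert np.array_equal(v1.voxels, v2.voxels)
        assert np.array_equal(t1.vessel_mask, t2.vessel_mask)
        assert np.array_equal(t1.centreline_voxels, t2.centreline_voxels)

    def test_vessels_confined_to_tissue(self, default_phantom):
        truth = default_phantom["truth"]
        assert not np.any(truth.vessel_mask & ~truth.tissue_mask)
        dens = truth.true_density_by_bin
        assert np.all((dens[np.isfinite(dens)] >= 0) & (dens[np.isfinite(dens)] <= 1))

    def test_oversized_root_rejected(self):
        spec = PhantomSpec3D(root_radius_vox=30.0, disc_thickness_vox=28)
        with pytest.raises(DataError, match="cannot fit"):
            generate_volume_phantom(spec)

    def test_grey_level_ordering_enforced(self):
        with pytest.raises(DataError, match="air < tissue < contrast"):
            generate_volume_phantom(PhantomSpec3D(grey_levels=(100, 50, 200)))

    def test_ground_truth_bins_match_brute_force_recount(self):
        spec = PhantomSpec3D(shape=(20, 64, 64), disc_radius_vox=28.0,
                             disc_thickness_vox=14, n_trees=25, seed=3)
        _, truth = generate_volume_phantom(spec)
        nd = analytic_normalised_distance(
            truth.tissue_mask.shape[1:], truth.cord_point,
            truth.disc_centre, truth.disc_radius_vox,
        )
        bins2d = np.full(nd.shape, -1, int)
        fin = np.isfinite(nd)
        bins2d[fin] = np.minimum(nd[fin].astype(int), 99)
        for b in (0, 10, 50, 99):
            sel2d = bins2d == b
            sel = np.broadcast_to(sel2d, truth.tissue_mask.shape)
            t = int((sel & truth.tissue_mask).sum())
            v = int((sel & truth.vessel_mask).sum())
            assert t == truth.bin_tissue_voxels[b]
            if t:
                assert truth.true_density_by_bin[b] == pytest.approx(v / t)

    def test_fill_fraction_controls_perfused_terminals(self):
        full = PhantomSpec3D(shape=(24, 64, 64), disc_radius_vox=28.0,
                             disc_thickness_vox=16, n_trees=30,
                             fill_fraction=1.0, seed=9)
        half = PhantomSpec3D(shape=(24, 64, 64), disc_radius_vox=28.0,
                             disc_thickness_vox=16, n_trees=30,
                             fill_fraction=0.3, seed=9)
        _, t_full = generate_volume_phantom(full)
        _, t_half = generate_volume_phantom(half)
        assert t_half.vessel_mask.sum() < t_full.vessel_mask.sum()

    def test_homogeneous_truth_profile_has_no_monotone_trend(self):
        """density_gradient=0: Spearman |r| < 0.3 over populated bins."""
        from placvasc.experiments import null_spec

        for seed in range(5):
            spec = null_spec(seed)
            _, truth = generate_volume_phantom(spec)
            bins = np.arange(2, 98)
            ok = bins[truth.bin_tissue_voxels[bins] > 0]
            r = spearman(ok, truth.true_density_by_bin[ok]).r_s
            assert abs(r) < 0.3, f"seed {seed}: trend r={r}"


class TestRasteriseCylinder:
    def test_finite_cylinder_voxel_count(self):
        m = np.zeros((60, 20, 20), bool)
        rasterise_cylinder(m, (5, 10, 10), (55, 10, 10), 3.0)
        # 29 in-disc pixels per slice x 51 slices
        assert m.sum() == 29 * 51

    def test_zero_length_segment_is_ball(self):
        m = np.zeros((11, 11, 11), bool)
        rasterise_cylinder(m, (5, 5, 5), (5, 5, 5), 2.0)
        assert m[5, 5, 5] and 25 <= m.sum() <= 40  # digital ball r=2 has 33


class TestMicrographPhantom:
    def test_zero_ellipses_is_blank_background(self):
        img, masks, areas = generate_micrograph_phantom(
            PhantomSpec2D(shape=(64, 64), noise_sd=0.0)
        )
        assert all(not m.any() for m in masks.values())
        assert all(len(a) == 0 for a in areas.values())
        assert (img == 255).all()

    def test_circle_area_matches_pi_r_squared(self):
        spec = PhantomSpec2D(
            shape=(128, 128), um_per_px=1.0,
            perfused=[Ellipse(64, 64, 50, 50)], noise_sd=0.0,
        )
        _, masks, areas = generate_micrograph_phantom(spec)
        assert areas["perfused"][0] == pytest.approx(np.pi * 2500)
        pixel_area = masks["perfused"].sum() * 1.0**2
        assert abs(areas["perfused"][0] - pixel_area) <= 0.05 * pixel_area

    def test_fixed_seed_reproducible(self):
        spec = random_micrograph_spec(seed=5)
        i1, m1, _ = generate_micrograph_phantom(spec)
        i2, m2, _ = generate_micrograph_phantom(random_micrograph_spec(seed=5))
        assert np.array_equal(i1, i2)
        assert all(np.array_equal(m1[k], m2[k]) for k in m1)

    def test_overlapping_lumen_classes_rejected(self):
        spec = PhantomSpec2D(
            shape=(128, 128),
            perfused=[Ellipse(64, 64, 20, 20)],
            unperfused=[Ellipse(70, 70, 20, 20)],
        )
        with pytest.raises(DataError, match="overlapping"):
            generate_micrograph_phantom(spec)

    def test_lumen_straddling_villous_boundary_rejected(self):
        spec = PhantomSpec2D(
            shape=(128, 128),
            villous=[Ellipse(64, 64, 25, 25)],
            perfused=[Ellipse(85, 64, 10, 10)],  # half in, half out
        )
        with pytest.raises(DataError, match="straddles"):
            generate_micrograph_phantom(spec)

    def test_classes_are_disjoint(self):
        _, masks, _ = generate_micrograph_phantom(random_micrograph_spec(seed=2))
        names = list(masks)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert not np.any(masks[a] & masks[b])

    def test_ellipse_outside_image_rejected(self):
        spec = PhantomSpec2D(shape=(64, 64), villous=[Ellipse(5, 5, 20, 20)])
        with pytest.raises(DataError, match="within the image"):
            generate_micrograph_phantom(spec)


class TestTargetDensityHelper:
    def test_analytic_tree_count_lands_near_target(self):
        spec = PhantomSpec3D(seed=0)
        spec.n_trees = trees_for_target_density(spec, 0.05)
        _, truth = generate_volume_phantom(spec)
        # overlap and clipping keep the realised fraction within ~2x
        assert 0.02 < truth.global_density < 0.08
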