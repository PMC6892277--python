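import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk

from placvasc.errors import DataError
from placvasc.histology import (
    analyse_micrograph,
    analyse_particles,
    apply_inclusion_rule,
    classify_pixels,
    render_class_image,
    summarise_block,
    vascular_density_histology,
    vascular_fill,
)
from placvasc.phantom import (
    Ellipse,
    PhantomSpec2D,
    generate_micrograph_phantom,
    random_micrograph_spec,
)


def _particles(rows):
    return pd.DataFrame(rows, columns=["particle_class", "area_um2"])


class TestClassifyPixels:
    def test_phantom_scene_per_class_dice(self):
        for seed in (0, 1, 2):
            spec = random_micrograph_spec(seed=seed, perfused_probability=0.7)
            img, masks, _ = generate_micrograph_phantom(spec)
            labels = classify_pixels(img)
            background = ~(masks["perfused"] | masks["unperfused"] | masks["villous"])
            truth = {
                0: masks["perfused"] | background,
                1: masks["unperfused"],
                2: masks["villous"],
            }
            for cls, gt in truth.items():
                if not gt.any():
                    continue
                pred = labels == cls
                dice = 2 * np.sum(gt & pred) / (gt.sum() + pred.sum())
                assert dice >= 0.95, (seed, cls, dice)

    def test_all_villous_scene_has_no_vessel_particles(self):
        spec = PhantomSpec2D(
            shape=(256, 256),
            villous=[Ellipse(128, 128, 90, 70, 30)],
            seed=1,
        )
        img, _, _ = generate_micrograph_phantom(spec)
        parts, villous_area = analyse_micrograph(img, 1.0)
        assert len(parts) == 0
        assert villous_area > 0

    def test_idempotent_on_its_own_label_rendering(self):
        spec = random_micrograph_spec(seed=4)
        img, _, _ = generate_micrograph_phantom(spec)
        labels = classify_pixels(img)
        assert np.array_equal(classify_pixels(render_class_image(labels)), labels)

    def test_greyscale_input_rejected(self):
        with pytest.raises(DataError, match="RGB"):
            classify_pixels(np.zeros((10, 10), np.uint8))


class TestAnalyseParticles:
    def test_circle_retained_with_pixel_exact_area(self):
        mask = np.zeros((200, 200), bool)
        rr, cc = disk((100, 100), 50.4)
        mask[rr, cc] = True
        table = analyse_particles(mask, 1.0, "perfused")
        assert len(table) == 1
        assert table.area_um2[0] == pytest.approx(float(mask.sum()))
        assert table.area_um2[0] == pytest.approx(np.pi * 50**2, rel=0.05)
        assert 0.85 <= table.circularity[0] <= 1.0

    def test_small_sliver_discarded_by_area(self):
        mask = np.zeros((50, 50), bool)
        mask[10, 10:15] = True  # 5 um^2 at 1 um/px
        assert len(analyse_particles(mask, 1.0)) == 0

    def test_long_thin_rectangle_discarded_by_circularity(self):
        mask = np.zeros((500, 50), bool)
        mask[50:450, 20:24] = True  # 400 x 4 um
        assert len(analyse_particles(mask, 1.0)) == 0
        unfiltered = analyse_particles(mask, 1.0, circ_range=(0.0, 1.0))
        assert len(unfiltered) == 1
        # 4*pi*A/P^2 = 4*pi*1600/808^2 for the ideal rectangle
        assert unfiltered.circularity[0] == pytest.approx(0.031, abs=0.015)

    def test_widening_limits_never_drops_particles(self, rng):
        mask = rng.random((200, 200)) < 0.4
        narrow = analyse_particles(mask, 1.0, area_range_um2=(60, 5000),
                                   circ_range=(0.3, 1.0))
        wide = analyse_particles(mask, 1.0, area_range_um2=(1, 1e6),
                                 circ_range=(0.0, 1.0))
        assert len(wide) >= len(narrow)

    def test_filter_is_idempotent_on_retained_table(self):
        spec = random_micrograph_spec(seed=6)
        img, _, _ = generate_micrograph_phantom(spec)
        parts, _ = analyse_micrograph(img, 1.0)
        refiltered = parts[
            parts.area_um2.between(60, 1e6) & parts.circularity.between(0.2, 1.0)
        ]
        assert len(refiltered) == len(parts)

    def test_invalid_scale_rejected(self):
        with pytest.raises(DataError, match="scale"):
            analyse_particles(np.zeros((5, 5), bool), 0.0)


class TestVascularFill:
    def test_only_perfused_is_100(self):
        t = _particles([("perfused", 5000.0), ("perfused", 300.0)])
        assert vascular_fill(t, 200.0) == 100.0

    def test_equal_areas_is_50(self):
        t = _particles([("perfused", 1000.0), ("unperfused", 1000.0)])
        assert vascular_fill(t, 200.0) == pytest.approx(50.0)

    def test_hand_computed_cutoff_case(self):
        t = _particles(
            [("perfused", 12_000.0), ("perfused", 9_000.0), ("unperfused", 15_000.0)]
        )
        assert vascular_fill(t, 10_000.0) == pytest.approx(100 * 12000 / 27000)

    def test_no_qualifying_vessels_is_undefined(self):
        t = _particles([("perfused", 150.0)])
        assert np.isnan(vascular_fill(t, 200.0))


class TestVascularDensity:
    def test_no_vessels_zero(self):
        assert vascular_density_histology(_particles([]), 5000.0) == 0.0

    def test_vessel_equal_to_villous_is_50(self):
        t = _particles([("perfused", 5000.0)])
        assert vascular_density_histology(t, 5000.0) == pytest.approx(50.0)

    def test_phantom_density_matches_mask_ratio(self):
        spec = random_micrograph_spec(seed=7, perfused_probability=0.9)
        img, masks, _ = generate_micrograph_phantom(spec)
        parts, villous_area = analyse_micrograph(img, 1.0)
        measured = vascular_density_histology(parts, villous_area)
        lumen = masks["perfused"].sum() + masks["unperfused"].sum()
        expected = 100.0 * lumen / (lumen + masks["villous"].sum())
        assert measured == pytest.approx(expected, abs=0.5)

    def test_scale_invariance_of_fill_and_density(self):
        spec1 = random_micrograph_spec(seed=8, um_per_px=1.0)
        img, _, _ = generate_micrograph_phantom(spec1)
        p1, v1 = analyse_micrograph(img, 1.0)
        p2, v2 = analyse_micrograph(img, 2.0)
        assert vascular_density_histology(p1, v1) == pytest.approx(
            vascular_density_histology(p2, v2), abs=1e-6
        )
        # cutoff chosen below the smallest lumen at both scales
        assert vascular_fill(p1, 150.0) == pytest.approx(
            vascular_fill(p2, 150.0 * 4), abs=1e-6
        )


class TestInclusionRule:
    def _blocks(self, fills):
        return pd.DataFrame(
            {
                "placenta_id": "P1",
                "block_id": [f"b{i}" for i in range(len(fills))],
                "fill_200_pct": fills,
            }
        )

    def test_boundary_is_non_strict(self):
        kept = apply_inclusion_rule(self._blocks([100.0, 74.9, 75.0]))
        assert list(kept.block_id) == ["b0", "b2"]

    def test_empty_input_passes_through(self):
        assert apply_inclusion_rule(self._blocks([])).empty

    def test_counts(self):
        fills = [80, 90, 74, 60, 100, 75, 30, 76, 50, 95]
        kept = apply_inclusion_rule(self._blocks(fills))
        assert len(kept) == 6

    def test_undefined_fill_excluded(self):
        kept = apply_inclusion_rule(self._blocks([np.nan, 80.0]))
        assert list(kept.block_id) == ["b1"]


class TestSummariseBlock:
    def test_basal_restriction_for_small_vessel_fill(self):
        basal_parts = _particles([("perfused", 300.0), ("unperfused", 300.0)])
        chorionic_parts = _particles([("perfused", 20_000.0)])
        bh = summarise_block(
            "P1", "b1",
            [chorionic_parts, basal_parts],
            [50_000.0, 50_000.0],
            basal=[False, True],
        )
        assert bh.fill_200_pct == pytest.approx(50.0)  # basal micrographs only
        assert bh.fill_10000_pct == pytest.approx(100.0)  # all micrographs
        assert not bh.included
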