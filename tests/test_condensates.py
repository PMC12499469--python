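"""Condensate segmentation and morphometric statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrcquant.condensates import (circularity, classify_condensate_vs_punctum,
                                  morphology_summary, segment_condensates)
from mrcquant.simulate import SimulationConfig, generate_condensate_image


class TestCircularityFormula:
    def test_analytic_circle_is_exactly_one(self):
        for r in (0.5, 1.0, 3.7, 20.0):
            assert circularity(math.pi * r**2, 2 * math.pi * r) == 1.0

    @settings(derandomize=True, max_examples=200)
    @given(area=st.floats(1e-6, 1e6), perimeter=st.floats(1e-6, 1e6))
    def test_always_in_unit_interval_and_circle_is_extremal(self, area,
                                                            perimeter):
        c = circularity(area, perimeter)
        assert 0.0 <= c <= 1.0
        # for the given area, no perimeter beats the circle's
        circle_perimeter = 2 * math.sqrt(math.pi * area)
        assert circularity(area, max(perimeter, circle_perimeter)) <= 1.0
        assert circularity(area, circle_perimeter) == pytest.approx(1.0)

    def test_square_is_pi_over_four(self):
        a = 5.0
        assert circularity(a**2, 4 * a) == pytest.approx(math.pi / 4)

    def test_clamped_to_unit_interval(self):
        assert circularity(1e6, 1.0) == 1.0

    def test_invalid_geometry_raises(self):
        with pytest.raises(ValueError):
            circularity(0.0, 1.0)


class TestSegmentation:
    def test_noise_free_disk_is_one_round_component(self):
        cfg = SimulationConfig(n_cells=1, image_shape=(128, 128),
                               condensate_radius=20, noise_model="none",
                               seed=2)
        stack, mask, _ = generate_condensate_image(cfg)
        objs = segment_condensates(stack.channel(0), mask,
                                   pixel_size_um=cfg.pixel_size)
        assert len(objs) == 1
        assert objs[0].circularity >= 0.95

    def test_elongated_condensate_less_circular_than_disk(self):
        kwargs = dict(n_cells=1, image_shape=(160, 160), condensate_radius=12,
                      noise_model="none", seed=5)
        disk_cfg = SimulationConfig(**kwargs)
        ell_cfg = SimulationConfig(condensate_axis_ratio=4.0, **kwargs)
        disk = segment_condensates(
            generate_condensate_image(disk_cfg)[0].channel(0),
            generate_condensate_image(disk_cfg)[1],
            pixel_size_um=disk_cfg.pixel_size)
        ell = segment_condensates(
            generate_condensate_image(ell_cfg)[0].channel(0),
            generate_condensate_image(ell_cfg)[1],
            pixel_size_um=ell_cfg.pixel_size)
        assert ell[0].circularity < disk[0].circularity

    def test_count_matches_ground_truth_on_clean_images(self):
        cfg = SimulationConfig(n_cells=4, image_shape=(256, 256),
                               condensate_radius=8, condensates_per_cell=2,
                               noise_model="none", seed=6)
        stack, mask, truth = generate_condensate_image(cfg)
        objs = segment_condensates(stack.channel(0), mask,
                                   pixel_size_um=cfg.pixel_size)
        assert len(objs) == sum(len(v) for v in truth.condensates.values())

    def test_total_area_invariant_under_intensity_offset(self):
        cfg = SimulationConfig(n_cells=1, image_shape=(128, 128),
                               condensate_radius=15, seed=7)
        stack, mask, _ = generate_condensate_image(cfg)
        img = stack.channel(0)
        a0 = sum(o.area_px for o in segment_condensates(img, mask))
        a1 = sum(o.area_px for o in segment_condensates(img + 123.0, mask))
        assert a0 == a1

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="mask is empty"):
            segment_condensates(np.ones((32, 32)), np.zeros((32, 32), dtype=int))

    def test_disk_maximizes_circularity_among_equal_area_shapes(self):
        # isoperimetric ordering on rasterized disk / ellipse / square
        from skimage import measure
        side = 40
        area = side * side
        r = math.sqrt(area / math.pi)
        yy, xx = np.mgrid[0:200, 0:200]
        shapes = {
            "disk": (yy - 60) ** 2 + (xx - 60) ** 2 <= r**2,
            "ellipse": ((yy - 60) / (r / 2)) ** 2 + ((xx - 150) / (2 * r)) ** 2 <= 1,
            "square": (abs(yy - 150) <= side // 2) & (abs(xx - 60) <= side // 2),
        }
        circ = {}
        for name, m in shapes.items():
            rp = measure.regionprops(m.astype(int))[0]
            circ[name] = circularity(rp.area, rp.perimeter_crofton)
        assert circ["disk"] > circ["ellipse"]
        assert circ["disk"] > circ["square"]


class TestSummariesAndClassification:
    def test_no_condensates_gives_zero_percent(self):
        summary = morphology_summary([], n_cells=10)
        assert summary.percent_cells_with_condensates == 0.0
        assert summary.log10_areas.size == 0

    def test_log10_of_unit_normalized_areas(self):
        from mrcquant.condensates import Condensate
        objs = [
            Condensate(cell_id=1, label=i, area_um2=a, area_px=1,
                       perimeter_um=1.0, circularity=1.0, mean_intensity=1.0,
                       peak_intensity=1.0, centroid_um=(0, 0))
            for i, a in enumerate((1.0, 10.0, 100.0))
        ]
        summary = morphology_summary(objs, n_cells=3)
        np.testing.assert_allclose(summary.log10_areas, [0.0, 1.0, 2.0])

    def test_doubling_radius_shifts_log_area_by_log10_4(self):
        out = {}
        for tag, radius in (("small", 8), ("large", 16)):
            cfg = SimulationConfig(n_cells=4, image_shape=(256, 256),
                                   condensate_radius=radius, seed=9,
                                   noise_model="none")
            stack, mask, _ = generate_condensate_image(cfg)
            objs = segment_condensates(stack.channel(0), mask,
                                       pixel_size_um=cfg.pixel_size)
            out[tag] = morphology_summary(objs, n_cells=4).log10_areas.mean()
        assert out["large"] - out["small"] == pytest.approx(math.log10(4),
                                                            abs=0.08)

    def test_invalid_normalization_raises(self):
        with pytest.raises(ValueError):
            morphology_summary([], n_cells=1, area_normalization_um2=0.0)

    def test_classification_by_size_and_roundness(self):
        from mrcquant.condensates import Condensate

        def obj(area, circ):
            return Condensate(cell_id=1, label=0, area_um2=area, area_px=1,
                              perimeter_um=1.0, circularity=circ,
                              mean_intensity=1.0, peak_intensity=1.0,
                              centroid_um=(0, 0))

        objs = [obj(0.1, 0.95), obj(2.0, 0.95), obj(2.0, 0.5)]
        labels = classify_condensate_vs_punctum(objs)
        assert labels == ["punctum", "condensate", "punctum"]

    def test_classification_boundary_tracks_area_threshold(self):
        # sweep rendered radii across the configured area threshold
        thr = 0.5  # µm²
        for radius_px in (6, 8, 10, 12, 14):
            cfg = SimulationConfig(n_cells=1, image_shape=(128, 128),
                                   condensate_radius=radius_px,
                                   noise_model="none", seed=3)
            stack, mask, _ = generate_condensate_image(cfg)
            objs = segment_condensates(stack.channel(0), mask,
                                       pixel_size_um=cfg.pixel_size)
            assert len(objs) == 1
            label = classify_condensate_vs_punctum(objs, area_threshold_um2=thr)[0]
            # allow a 1-px ring of slack around the geometric boundary
            r_um = radius_px * cfg.pixel_size
            lo = math.pi * (r_um - cfg.pixel_size) ** 2
            hi = math.pi * (r_um + cfg.pixel_size) ** 2
            if hi < thr:
                assert label == "punctum"
            elif lo > thr:
                assert label == "condensate"
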