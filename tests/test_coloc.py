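"""SNR statistic, cross-channel matching and colocalization estimates."""

import itertools
import math

import numpy as np
import pytest

from mrcquant.coloc import match_spots, pixel_correlation, snr_ratio_stat, spot_snr
from mrcquant.core import Spot
from mrcquant.simulate import SimulationConfig, generate_cell_image
from mrcquant.spots import detect_spots


def _spot(x_um, y_um, peak, cell_id=1, channel=0, px=1.0):
    return Spot(cell_id=cell_id, channel=channel, centroid_um=(x_um, y_um),
                peak_intensity=peak, area_um2=1.0,
                centroid_px=(y_um / px, x_um / px))


def _oracle_background(img, spot_rc, all_spots_rc, bg_radius_px, excl_radius_px):
    """Independent per-pixel loop implementing the documented background
    definition: disk around the spot minus disks around every labelled spot."""
    vals = []
    sy, sx = spot_rc
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            if (r - sy) ** 2 + (c - sx) ** 2 > bg_radius_px**2:
                continue
            if any((r - oy) ** 2 + (c - ox) ** 2 <= excl_radius_px**2
                   for oy, ox in all_spots_rc):
                continue
            vals.append(img[r, c])
    return np.array(vals)


class TestSpotSNR:
    def _checkerboard_image(self):
        # background alternating 5/15 (mean ~10, SD ~5) with one bright peak
        yy, xx = np.mgrid[0:61, 0:61]
        img = np.where((yy + xx) % 2 == 0, 5.0, 15.0)
        img[30, 30] = 100.0
        return img

    def test_matches_hand_computed_background_statistics(self):
        img = self._checkerboard_image()
        psf_sigma = 1.6
        spot = _spot(30.0, 30.0, 100.0)
        m = spot_snr(img, spot, bg_diameter_um=40.0, pixel_size_um=1.0,
                     psf_sigma=psf_sigma)
        bg = _oracle_background(img, (30, 30), [(30, 30)],
                                bg_radius_px=20.0, excl_radius_px=2 * psf_sigma)
        assert m.background_mean == pytest.approx(bg.mean(), abs=1e-12)
        assert m.background_sd == pytest.approx(bg.std(), abs=1e-12)
        assert m.snr == pytest.approx((100.0 - bg.mean()) / bg.std(), abs=1e-12)
        # checkerboard statistics put the value near (100-10)/5 = 18
        assert m.snr == pytest.approx(18.0, rel=0.02)

    @pytest.mark.parametrize("offset,scale", [(7.0, 1.0), (0.0, 3.0), (11.0, 2.5)])
    def test_invariant_under_positive_affine_transform(self, offset, scale):
        img = self._checkerboard_image()
        spot = _spot(30.0, 30.0, 100.0)
        base = spot_snr(img, spot, bg_diameter_um=40.0, pixel_size_um=1.0)
        spot2 = _spot(30.0, 30.0, 100.0 * scale + offset)
        other = spot_snr(img * scale + offset, spot2, bg_diameter_um=40.0,
                         pixel_size_um=1.0)
        assert other.snr == pytest.approx(base.snr, rel=1e-12)

    def test_degenerate_background_raises(self):
        img = np.full((61, 61), 10.0)
        img[30, 30] = 100.0
        with pytest.raises(ValueError, match="degenerate background"):
            spot_snr(img, _spot(30.0, 30.0, 100.0), bg_diameter_um=40.0,
                     pixel_size_um=1.0)

    def test_too_few_background_pixels_raises_with_count(self):
        img = self._checkerboard_image()
        with pytest.raises(ValueError, match="pixels"):
            spot_snr(img, _spot(30.0, 30.0, 100.0), bg_diameter_um=3.0,
                     pixel_size_um=1.0)


class TestMatching:
    def test_identical_centroids_give_full_colocalization(self):
        bait = [_spot(1.0, 1.0, 10), _spot(3.0, 3.0, 10)]
        prey = [_spot(1.0, 1.0, 8, channel=1), _spot(3.0, 3.0, 8, channel=1)]
        res = match_spots(bait, prey, max_dist_um=0.3)
        assert res.coloc_percent == 100.0
        assert all(d == 0.0 for _, _, d in res.pairs)

    def test_no_prey_spots_give_zero_percent(self):
        res = match_spots([_spot(1.0, 1.0, 10)], [], max_dist_um=0.3)
        assert res.coloc_percent == 0.0
        assert res.pairs == []

    def test_coloc_percent_monotone_in_distance_threshold(self, rng):
        bait = [_spot(x, y, 10) for x, y in rng.uniform(0, 10, (6, 2))]
        prey = [_spot(x, y, 8, channel=1) for x, y in rng.uniform(0, 10, (6, 2))]
        pcts = [match_spots(bait, prey, max_dist_um=d).coloc_percent
                for d in (0.1, 0.5, 1.0, 3.0, 10.0)]
        assert all(a <= b for a, b in zip(pcts, pcts[1:]))

    def test_greedy_equals_optimal_assignment_on_small_instances(self, rng):
        # brute force over all one-to-one assignments, maximizing matches
        # within the threshold; loci are separated well beyond the match
        # radius, as genomic recruitment sites are, so greedy closest-first
        # cannot lock out a better pairing
        max_d = 0.4
        for trial in range(30):
            nb = int(rng.integers(1, 4))
            centers = np.array([[1.0, 1.0], [4.0, 1.0], [2.5, 4.0]])[:nb]
            bait = [_spot(x, y, 10)
                    for x, y in centers + rng.normal(0, 0.05, (nb, 2))]
            keep = rng.uniform(size=nb) < 0.7
            prey_pts = centers[keep] + rng.normal(0, 0.1, (int(keep.sum()), 2))
            np_ = len(prey_pts)
            prey = [_spot(x, y, 8, channel=1) for x, y in prey_pts]
            if np_ == 0:
                assert match_spots(bait, prey, max_dist_um=max_d).pairs == []
                continue
            best = 0
            for k in range(min(nb, np_), 0, -1):
                for bs in itertools.permutations(range(nb), k):
                    for ps in itertools.permutations(range(np_), k):
                        n_ok = sum(
                            math.dist(bait[i].centroid_um, prey[j].centroid_um)
                            <= max_d
                            for i, j in zip(bs, ps)
                        )
                        best = max(best, n_ok)
            res = match_spots(bait, prey, max_dist_um=max_d)
            assert len(res.pairs) == best

    def test_estimator_recovers_generation_fraction(self):
        # 3 replicates x 15 cells at p = 0.6, as a typical experiment design
        p = 0.6
        cell_pcts = []
        n_bait_total = 0
        for rep in range(3):
            cfg = SimulationConfig(
                n_cells=15, image_shape=(256, 256), spots_per_cell=2,
                coloc_fraction=p, seed=100 + rep,
            )
            stack, mask, _ = generate_cell_image(cfg)
            bait = detect_spots(stack, mask, channel=0)
            prey = detect_spots(stack, mask, channel=1)
            for cid in range(1, 16):
                b = [s for s in bait if s.cell_id == cid]
                pr = [s for s in prey if s.cell_id == cid]
                if not b:
                    continue
                n_bait_total += len(b)
                cell_pcts.append(match_spots(b, pr).coloc_percent)
        est = np.mean(cell_pcts) / 100.0
        # binomial CI half-width on ~90 bait spots
        half = 3 * math.sqrt(p * (1 - p) / n_bait_total)
        assert abs(est - p) <= half + 0.02


class TestSNRRatio:
    def test_identical_channels_give_unit_ratio_zero_sd(self):
        m = [_spot(1, 1, 50)]
        from mrcquant.coloc import SNRMeasurement
        pairs = [(SNRMeasurement(m[0], 10, 5, 8.0, 100),
                  SNRMeasurement(m[0], 10, 5, 8.0, 100))] * 5
        stat = snr_ratio_stat(pairs)
        assert stat.mean == 1.0
        assert stat.sd == 0.0
        assert stat.n == 5

    def test_prey_at_two_thirds_peak_gives_ratio_1_5(self):
        # noise-free generation: prey peak = bait peak / 1.5 over the same
        # background, so the bait/prey SNR ratio is exactly 1.5
        from mrcquant.coloc import SNRMeasurement
        bait_m = SNRMeasurement(_spot(1, 1, 100), 10.0, 5.0,
                                (100 - 10) / 5.0, 100)
        prey_m = SNRMeasurement(_spot(1, 1, 70), 10.0, 5.0,
                                (70 - 10) / 5.0, 100)
        stat = snr_ratio_stat([(bait_m, prey_m)])
        assert stat.mean == pytest.approx(1.5)

    def test_nonpositive_prey_snr_dropped_with_warning(self):
        from mrcquant.coloc import SNRMeasurement
        good = (SNRMeasurement(_spot(1, 1, 100), 10, 5, 18.0, 100),
                SNRMeasurement(_spot(1, 1, 70), 10, 5, 12.0, 100))
        bad = (SNRMeasurement(_spot(2, 2, 100), 10, 5, 18.0, 100),
               SNRMeasurement(_spot(2, 2, 5), 10, 5, -1.0, 100))
        with pytest.warns(UserWarning, match="non-positive prey SNR"):
            stat = snr_ratio_stat([good, bad])
        assert stat.n == 1


class TestPixelCorrelation:
    def test_self_correlation_is_one(self, rng):
        img = rng.uniform(0, 100, (40, 40))
        mask = np.ones_like(img, dtype=int)
        out = pixel_correlation(img, img, mask)
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_anticorrelation_is_minus_one(self, rng):
        img = rng.uniform(10, 90, (40, 40))
        out = pixel_correlation(img, 100.0 - img, np.ones_like(img, dtype=int))
        assert out["pearson_r"] == pytest.approx(-1.0)

    def test_independent_noise_is_near_zero(self, rng):
        a = rng.uniform(0, 100, (100, 100))
        b = rng.uniform(0, 100, (100, 100))
        out = pixel_correlation(a, b, np.ones_like(a, dtype=int))
        assert abs(out["pearson_r"]) < 0.05

    def test_zero_variance_raises(self):
        a = np.full((20, 20), 5.0)
        b = np.arange(400, dtype=float).reshape(20, 20)
        with pytest.raises(ValueError, match="zero variance"):
            pixel_correlation(a, b, np.ones_like(a, dtype=int))
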