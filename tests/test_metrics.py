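import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prlquant.metrics import (
    confusion_counts,
    scores_from_counts,
    evaluate_masks,
    pr_curve,
    etdrs_regions,
    region_mean_thickness,
    sample_bscans,
)


def brute_counts(pred, truth):
    tp = fp = fn = tn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


class TestConfusionCounts:
    def test_identity(self):
        m = (np.random.default_rng(0).random((10, 12)) > 0.5)
        tp, fp, fn, tn = confusion_counts(m, m)
        assert fp == fn == 0
        assert tp == m.sum()
        assert tp + tn == m.size

    def test_fixture_50_10_30(self):
        truth = np.zeros(140, dtype=bool)
        pred = np.zeros(140, dtype=bool)
        truth[:80] = True  # tp + fn
        pred[:50] = True  # 50 tp
        pred[80:90] = True  # 10 fp
        s = scores_from_counts(*confusion_counts(pred.reshape(10, 14),
                                                 truth.reshape(10, 14)))
        assert (s.tp, s.fp, s.fn) == (50, 10, 30)
        assert round(s.precision, 4) == 0.8333
        assert round(s.recall, 4) == 0.625
        assert round(s.dice, 4) == 0.7143

    def test_empty_empty_degenerate_nan(self):
        s = scores_from_counts(*confusion_counts(np.zeros((4, 4), dtype=bool),
                                                 np.zeros((4, 4), dtype=bool)))
        assert s.degenerate
        assert np.isnan(s.dice) and np.isnan(s.precision) and np.isnan(s.recall)

    def test_counts_sum_to_region_size(self):
        rng = np.random.default_rng(1)
        pred = rng.random((3, 8, 10)) > 0.5
        truth = rng.random((3, 8, 10)) > 0.7
        region = rng.random((3, 10)) > 0.4  # en-face column selection
        tp, fp, fn, tn = confusion_counts(pred, truth, region)
        assert tp + fp + fn + tn == region.sum() * 8

    def test_region_selects_whole_columns(self):
        pred = np.zeros((2, 4, 3), dtype=bool)
        truth = np.zeros((2, 4, 3), dtype=bool)
        truth[0, :, 0] = True  # full column in excluded region
        region = np.zeros((2, 3), dtype=bool)
        region[0, 1] = True
        tp, fp, fn, tn = confusion_counts(pred, truth, region)
        assert (tp, fp, fn, tn) == (0, 0, 0, 4)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((2, 2)), np.zeros((2, 3)))

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_dice_identity_random(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.random((6, 7)) > rng.random()
        truth = rng.random((6, 7)) > rng.random()
        tp, fp, fn, tn = confusion_counts(pred, truth)
        assert (tp, fp, fn, tn) == brute_counts(pred, truth)
        s = scores_from_counts(tp, fp, fn, tn)
        if not s.degenerate and s.precision + s.recall > 0:
            via_pr = 2 * s.precision * s.recall / (s.precision + s.recall)
            assert abs(s.dice - via_pr) < 1e-12
            assert abs(s.dice - 2 * tp / (2 * tp + fp + fn)) < 1e-12


class TestPRCurve:
    def test_perfect_scorer_auc_one(self):
        truth = np.zeros((20, 20), dtype=bool)
        truth[5:9] = True
        points, auc = pr_curve(truth.astype(float), truth)
        assert np.isclose(auc, 1.0)

    def test_constant_scorer_auc_equals_prevalence(self):
        rng = np.random.default_rng(0)
        truth = rng.random((50, 50)) < 0.2
        prevalence = truth.mean()
        scores = np.full(truth.shape, 0.5)
        points, auc = pr_curve(scores, truth)
        recalls = {round(r, 6) for r, _ in points}
        assert recalls == {1.0}
        assert np.isclose(auc, prevalence, atol=1e-12)

    def test_random_scorer_auc_near_prevalence(self):
        rng = np.random.default_rng(1)
        truth = rng.random(10_000) < 0.3
        scores = rng.random(10_000)
        _, auc = pr_curve(scores.reshape(100, 100), truth.reshape(100, 100))
        assert abs(auc - truth.mean()) < 0.03

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        truth = rng.random((40, 40)) < 0.1
        scores = np.clip(rng.random((40, 40)) * 0.5 + truth * 0.4, 0, 1)
        _, auc1 = pr_curve(scores, truth)
        _, auc2 = pr_curve(scores ** 2, truth)
        assert abs(auc1 - auc2) < 0.02  # equal up to threshold-grid discretization

    def test_no_positive_pixels_raises(self):
        with pytest.raises(ValueError, match="no positive"):
            pr_curve(np.random.default_rng(0).random((4, 4)),
                     np.zeros((4, 4), dtype=bool))

    def test_region_restriction(self):
        rng = np.random.default_rng(3)
        truth = rng.random((3, 8, 10)) < 0.2
        scores = np.clip(truth * 0.8 + rng.random((3, 8, 10)) * 0.2, 0, 1)
        region = np.zeros((3, 10), dtype=bool)
        region[:, :5] = True
        _, auc_region = pr_curve(scores, truth, region)
        assert 0 <= auc_region <= 1


class TestETDRSRegions:
    GEOM = dict(n_bscans=49, n_ascans=512, dx_mm=6.0 / 512, dy_mm=6.0 / 49)

    def test_brute_force_membership(self):
        reg = etdrs_regions(**self.GEOM)
        fb, fx = reg.fovea_center
        count = 0
        for b in range(49):
            for x in range(0, 512, 1):
                d = np.hypot((b - fb) * self.GEOM["dy_mm"],
                             (x - fx) * self.GEOM["dx_mm"])
                if d <= 0.5:
                    count += 1
        assert reg.csf.sum() == count
        # area check: ~ pi * 0.25 mm^2 worth of cells
        expected = np.pi * 0.25 / (self.GEOM["dx_mm"] * self.GEOM["dy_mm"])
        assert abs(reg.csf.sum() - expected) / expected < 0.05

    def test_corner_fovea_quarter_disk(self):
        centered = etdrs_regions(**self.GEOM)
        corner = etdrs_regions(**self.GEOM, fovea_center=(0.0, 0.0))
        ratio = corner.csf.sum() / centered.csf.sum()
        assert abs(ratio - 0.25) < 0.05

    def test_disjoint_and_partition(self):
        reg = etdrs_regions(**self.GEOM)
        assert not np.any(reg.csf & reg.ring31)
        assert np.array_equal(reg.csf | reg.ring31, reg.cmm3)
        assert np.all(reg.csf[reg.csf] <= reg.cmm3[reg.csf])  # csf subset cmm3
        assert reg.full.all()

    def test_bad_spacing(self):
        with pytest.raises(ValueError):
            etdrs_regions(10, 10, dx_mm=0.0, dy_mm=0.1)


class TestRegionMeanThickness:
    GEOM = dict(n_bscans=25, n_ascans=64, dx_mm=6.0 / 64, dy_mm=6.0 / 25)

    def test_uniform_map(self):
        reg = etdrs_regions(**self.GEOM)
        means = region_mean_thickness(np.full((25, 64), 10.0), reg)
        for v in means.values():
            assert np.isclose(v, 10.0)

    def test_csf_only_counting_oracle(self):
        reg = etdrs_regions(**self.GEOM)
        grid = np.where(reg.csf, 10.0, 0.0)
        means = region_mean_thickness(grid, reg)
        assert np.isclose(means["csf"], 10.0)
        assert np.isclose(means["full"], 10.0 * reg.csf.sum() / reg.full.sum())
        assert np.isclose(means["ring31"], 0.0)


class TestSampleBscans:
    # 49 B-scans spanning 12 mm: a fovea-centred 6-mm raster holds no scan
    # beyond 3 mm along the slow axis, so the 3-6 mm band needs a wider span
    GEOM = dict(n_bscans=49, dy_mm=0.25)

    def test_band_eligibility_brute_force(self):
        samples = sample_bscans(**self.GEOM, fovea_b=24, seed=5)
        dy = self.GEOM["dy_mm"]
        bounds = [(0.0, 1.0), (1.0, 3.0), (3.0, 6.0)]
        for (lo, hi), pair in zip(bounds, samples):
            assert len(pair) == 2 and pair[0] != pair[1]
            for b in pair:
                d = abs(b - 24) * dy
                assert (d >= lo if lo == 0 else d > lo)
                assert d <= hi

    def test_determinism(self):
        s1 = sample_bscans(**self.GEOM, seed=42)
        s2 = sample_bscans(**self.GEOM, seed=42)
        assert s1 == s2

    def test_insufficient_band_raises(self):
        # 5 scans over 0.5 mm: nothing beyond 1 mm from the fovea
        with pytest.raises(ValueError, match="band"):
            sample_bscans(n_bscans=5, dy_mm=0.1, seed=0)

    def test_six_mm_raster_cannot_fill_outer_band(self):
        # the emulated 49 x 6 mm protocol leaves the 3-6 mm band empty
        with pytest.raises(ValueError, match="3.0-6.0"):
            sample_bscans(n_bscans=49, dy_mm=6.0 / 49, seed=0)

    def test_six_mm_raster_with_offset_fovea(self):
        # with the fovea at the first B-scan the full 0-5.88 mm range exists
        dy = 6.0 / 49
        samples = sample_bscans(n_bscans=49, dy_mm=dy, fovea_b=0.0, seed=1)
        for (lo, hi), pair in zip([(0, 1), (1, 3), (3, 6)], samples):
            for b in pair:
                d = b * dy
                assert (d >= lo if lo == 0 else d > lo) and d <= hi
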