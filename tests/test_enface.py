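import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prlquant.enface import (
    EnFaceMap,
    extract_interfaces,
    thickness_profile,
    enface_thickness,
    enface_std,
    normalize_for_display,
)
from prlquant.ensemble import EnsembleResult
from prlquant.phantom import PhantomSpec, Ellipse, generate_volume
from tests.conftest import make_toy_spec


def band_mask(n_rows=200, n_cols=512, top=100, bottom=110):
    m = np.zeros((n_rows, n_cols), dtype=np.uint8)
    m[top:bottom + 1, :] = 1
    return m


class TestExtractInterfaces:
    def test_constant_band(self):
        ifs = extract_interfaces(band_mask())
        assert np.all(ifs.upper == 100)
        assert np.all(ifs.lower == 110)
        assert np.allclose(ifs.upper_fit, 100, atol=1e-6)
        assert np.allclose(ifs.lower_fit, 110, atol=1e-6)
        assert np.allclose(ifs.medial, 105, atol=1e-6)
        assert not ifs.disrupted.any()
        assert not ifs.empty

    def test_disruption_bridged_by_spline(self):
        m = band_mask()
        m[:, 200:211] = 0
        ifs = extract_interfaces(m)
        expected = np.zeros(512, dtype=bool)
        expected[200:211] = True
        assert np.array_equal(ifs.disrupted, expected)
        assert np.isnan(ifs.upper[200])
        # fits are continuous across the gap and stay within the band
        assert np.all(np.isfinite(ifs.upper_fit))
        assert np.all(ifs.upper_fit[200:211] >= 100 - 1e-6)
        assert np.all(ifs.lower_fit[200:211] <= 110 + 1e-6)

    def test_single_pixel_band(self):
        m = np.zeros((100, 64), dtype=np.uint8)
        m[50, :] = 1
        ifs = extract_interfaces(m)
        assert np.all(ifs.upper == 50)
        assert np.all(ifs.lower == 50)
        assert np.allclose(ifs.medial, 50, atol=1e-6)

    def test_empty_mask_signalled(self):
        ifs = extract_interfaces(np.zeros((20, 30), dtype=np.uint8))
        assert ifs.empty
        assert ifs.disrupted.all()
        assert np.all(np.isnan(ifs.upper_fit))

    def test_multi_blob_column_spans_all(self):
        m = np.zeros((50, 10), dtype=np.uint8)
        m[10:13, :] = 1
        m[20:22, 4] = 1  # second blob in column 4
        ifs = extract_interfaces(m)
        assert ifs.upper[4] == 10
        assert ifs.lower[4] == 21

    def test_disruption_from_raw_mask_not_spline(self):
        m = band_mask(n_cols=64)
        m[:, 30] = 0
        ifs = extract_interfaces(m)
        assert ifs.disrupted[30]
        assert np.isfinite(ifs.upper_fit[30])  # spline still bridges

    def test_rejects_3d(self):
        with pytest.raises(ValueError):
            extract_interfaces(np.zeros((2, 3, 4)))


class TestThicknessProfile:
    def test_constant_band_inclusive_extent(self):
        t = thickness_profile(extract_interfaces(band_mask()))
        assert np.allclose(t, 11, atol=1e-6)

    def test_disruption_zeroed(self):
        m = band_mask()
        m[:, 200:211] = 0
        t = thickness_profile(extract_interfaces(m))
        assert np.all(t[200:211] == 0)
        assert np.all(t[:200] > 0)

    def test_single_pixel_thickness_one(self):
        m = np.zeros((100, 32), dtype=np.uint8)
        m[50, :] = 1
        t = thickness_profile(extract_interfaces(m))
        assert np.allclose(t, 1, atol=1e-6)

    def test_empty_mask_zero(self):
        t = thickness_profile(extract_interfaces(np.zeros((10, 12), dtype=np.uint8)))
        assert np.all(t == 0)

    def test_phantom_truth_recovery_within_1px(self):
        spec = make_toy_spec(11, n_bscans=3, n_depth=96, n_ascans=128,
                             thickness=10, speckle=0.0, disruption=True)
        _, truth = generate_volume(spec)
        for b in range(3):
            t = thickness_profile(extract_interfaces(truth.mask.mask[b]))
            ok = ~truth.disrupted[b]
            assert np.max(np.abs(t[ok] - truth.thickness_true[b, ok])) <= 1.0
            assert np.all(t[~ok] == 0)

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 500))
    def test_run_length_oracle_random_phantoms(self, seed):
        _, truth = generate_volume(
            make_toy_spec(seed, n_bscans=2, n_depth=64, n_ascans=64, thickness=7)
        )
        for b in range(2):
            mask = truth.mask.mask[b]
            t = thickness_profile(extract_interfaces(mask))
            run_length = mask.sum(axis=0)
            ok = run_length > 0
            assert np.max(np.abs(t[ok] - run_length[ok])) <= 1.0
            assert np.all(t[~ok] == 0)


class TestEnfaceThickness:
    def test_flat_band_uniform_map(self):
        masks = [band_mask(n_rows=64, n_cols=32, top=20, bottom=29)] * 5
        emap = enface_thickness(masks, dx_mm=0.01, dy_mm=0.1, dz_um=1.0)
        assert emap.grid.shape == (5, 32)
        assert np.allclose(emap.grid, 10, atol=1e-6)
        assert emap.units == "px"

    def test_dz_scaling_to_microns(self):
        masks = [band_mask(n_rows=64, n_cols=32, top=20, bottom=29)] * 2
        emap = enface_thickness(masks, dx_mm=0.01, dy_mm=0.1, dz_um=3.5)
        assert np.allclose(emap.grid, 35, atol=1e-5)
        assert emap.units == "um"

    def test_disruption_footprint_zeroed(self):
        spec = make_toy_spec(4, n_bscans=6, n_depth=64, n_ascans=96, speckle=0.0)
        spec.disruptions = [Ellipse(center_b=3, center_x=48, radius_b=1.2,
                                    radius_x=10.2)]
        _, truth = generate_volume(spec)
        emap = enface_thickness(list(truth.mask.mask), 0.01, 0.1)
        assert np.all(emap.grid[truth.disrupted] == 0)
        assert np.all(emap.grid[~truth.disrupted] > 0)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        masks = []
        for i in range(4):
            masks.append(band_mask(n_rows=64, n_cols=16, top=10 + i, bottom=20 + 2 * i))
        emap = enface_thickness(masks, 0.01, 0.1)
        perm = [2, 0, 3, 1]
        emap_perm = enface_thickness([masks[i] for i in perm], 0.01, 0.1)
        assert np.allclose(emap_perm.grid, emap.grid[perm])

    def test_thickness_never_negative(self):
        rng = np.random.default_rng(1)
        masks = [(rng.random((32, 24)) > 0.8).astype(np.uint8) for _ in range(3)]
        emap = enface_thickness(masks, 0.01, 0.1)
        assert np.all(emap.grid >= 0)


def _result(binary, std_map):
    return EnsembleResult(mean_score=np.zeros_like(std_map), std_map=std_map,
                          binary=binary, threshold=0.5)


class TestEnfaceStd:
    def test_zero_std_maps(self):
        binary = band_mask(n_rows=32, n_cols=16, top=10, bottom=20)
        results = [_result(binary, np.zeros((32, 16))) for _ in range(3)]
        emap, coverage = enface_std(results, 0.01, 0.1)
        assert np.all(emap.grid == 0)
        assert coverage.all()

    def test_hot_pixel_on_medial_axis(self):
        n_b, n_rows, n_cols = 5, 40, 16
        binary = band_mask(n_rows=n_rows, n_cols=n_cols, top=10, bottom=20)
        results = []
        for b in range(n_b):
            std = np.zeros((n_rows, n_cols))
            if b == 3:
                std[15, 7] = 0.4  # medial row of the 10..20 band
            results.append(_result(binary, std))
        emap, _ = enface_std(results, 0.01, 0.1)
        assert emap.grid[3, 7] == 0.4
        emap.grid[3, 7] = 0.0
        assert np.all(emap.grid == 0)

    def test_empty_bscan_zero_with_coverage_flag(self):
        binary = band_mask(n_rows=32, n_cols=8, top=10, bottom=20)
        empty = np.zeros((32, 8), dtype=np.uint8)
        results = [_result(binary, np.full((32, 8), 0.3)),
                   _result(empty, np.full((32, 8), 0.3))]
        emap, coverage = enface_std(results, 0.01, 0.1)
        assert np.all(emap.grid[0] == 0.3)
        assert np.all(emap.grid[1] == 0)
        assert coverage[0].all()
        assert not coverage[1].any()

    def test_values_bounded_by_half(self, toy_volume):
        vol, truth = toy_volume
        rng = np.random.default_rng(0)
        results = [
            _result(truth.mask.mask[b], rng.random(truth.mask.mask[b].shape) * 0.5)
            for b in range(vol.n_bscans)
        ]
        emap, _ = enface_std(results, vol.dx_mm, vol.dy_mm)
        assert emap.grid.max() <= 0.5


class TestNormalizeForDisplay:
    def test_hand_computed(self):
        out, flag = normalize_for_display(np.array([[1.0, 3.0], [5.0, 9.0]]))
        assert not flag
        assert np.allclose(out, [[0, 0.25], [0.5, 1.0]])

    def test_idempotent_on_unit_range(self):
        grid = np.array([[0.0, 0.4], [0.7, 1.0]])
        out, flag = normalize_for_display(grid)
        assert not flag
        assert np.allclose(out, grid)

    def test_constant_flagged(self):
        out, flag = normalize_for_display(np.full((3, 3), 2.0))
        assert flag
        assert np.all(out == 0)

    def test_endpoints_attained(self):
        rng = np.random.default_rng(0)
        grid = rng.normal(size=(10, 10))
        out, _ = normalize_for_display(grid)
        assert out.min() == 0.0
        assert out.max() == 1.0

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            normalize_for_display(np.array([[np.nan, 1.0]]))
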