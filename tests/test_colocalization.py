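"""Colocalization measures: oracles, endpoints, shift recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coloc_stress import (
    ChannelStack, SceneParams, make_coloc_stack,
    PixelPairField, estimate_background, pearson_r, icq, van_steensel, analyze_pair,
)
from conftest import SMALL_GRID, pearson_brute, icq_brute

VOX = (60.0, 60.0, 120.0)


def _stack(arr):
    return ChannelStack(np.asarray(arr, dtype=float), VOX)


class TestBackground:
    def test_all_zero(self):
        assert estimate_background(_stack(np.zeros((2, 8, 8)))) == 0.0

    def test_constant_stack_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            assert estimate_background(_stack(np.full((2, 8, 8), 7.0))) == 7.0

    def test_scene_plus_offset_bounds_offset(self, clean_params):
        a, _, _ = make_coloc_stack(clean_params)
        shifted = _stack(a.data + 50.0)
        assert estimate_background(shifted) >= 50.0

    def test_percentile_matches_sorted_oracle(self):
        rng = np.random.default_rng(3)
        data = rng.exponential(10.0, size=(4, 16, 16))
        est = estimate_background(_stack(data), percentile=1.0)
        # brute-force oracle: sorted-array percentile by linear interpolation
        flat = np.sort(data.ravel())
        pos = 0.01 * (flat.size - 1)
        lo = int(np.floor(pos))
        oracle = flat[lo] + (pos - lo) * (flat[lo + 1] - flat[lo])
        assert est == pytest.approx(oracle, rel=1e-12)


class TestPearson:
    def test_identity_and_inversion(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(PixelPairField.from_arrays(a, a)) == pytest.approx(1.0)
        assert pearson_r(PixelPairField.from_arrays(a, 5.0 - a)) == pytest.approx(-1.0)

    def test_hand_enumerated_example(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [1.0, 3.0, 2.0, 4.0]
        expected = pearson_brute(a, b)  # 10-line loop oracle
        assert pearson_r(PixelPairField.from_arrays(a, b)) == pytest.approx(
            expected, abs=1e-14)

    def test_constant_channel_is_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            r = pearson_r(PixelPairField.from_arrays([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))
        assert np.isnan(r)

    @settings(deadline=None, max_examples=25)
    @given(gain=st.floats(0.1, 50.0), offset=st.floats(-100.0, 100.0))
    def test_affine_invariance(self, gain, offset):
        rng = np.random.default_rng(7)
        a = rng.normal(size=64)
        b = rng.normal(size=64) + 0.5 * a
        r0 = pearson_r(PixelPairField.from_arrays(a, b))
        r1 = pearson_r(PixelPairField.from_arrays(gain * a + offset, b))
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestICQ:
    def test_identity_endpoint(self):
        a = np.tile([1.0, 2.0, 4.0, 8.0], 8)  # no pixel at the mean
        res = icq(PixelPairField.from_arrays(a, a))
        assert res.icq == 0.5
        assert res.n_zero == 0

    def test_inversion_endpoint(self):
        a = np.tile([1.0, 2.0, 4.0, 8.0], 8)
        b = (a.max() + a.min()) - a
        assert icq(PixelPairField.from_arrays(a, b)).icq == -0.5

    def test_hand_enumerated_sign_pattern(self):
        # covariance signs: means are 2.5 each; products of deviations:
        # (-1.5)(1.5)<0, (-0.5)(-1.5)>0, (0.5)(0.5)>0, (1.5)(-0.5)<0 -> 2 of 4
        a = [1.0, 2.0, 3.0, 4.0]
        b = [4.0, 1.0, 3.0, 2.0]
        res = icq(PixelPairField.from_arrays(a, b))
        assert res.n_positive == 2 and res.n_total == 4
        assert res.icq == 0.0

    def test_zero_covariance_in_denominator_only(self):
        # one pixel of each channel sits exactly at its mean
        a = np.array([0.0, 2.0, 4.0, 2.0])
        res = icq(PixelPairField.from_arrays(a, a))
        assert res.n_zero == 2
        assert res.icq == pytest.approx(2 / 4 - 0.5)

    def test_bounds_hold(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b = rng.normal(size=(2, 50))
            v = icq(PixelPairField.from_arrays(a, b)).icq
            assert -0.5 <= v <= 0.5


class TestOracleEquivalence:
    """R and ICQ against independent brute-force loops on tiny stacks."""

    @pytest.mark.parametrize("seed", range(5))
    def test_small_stack_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 100, size=(2, 8, 8)).astype(float)
        b = rng.integers(0, 100, size=(2, 8, 8)).astype(float)
        fld = PixelPairField.from_arrays(a, b)
        assert pearson_r(fld) == pytest.approx(pearson_brute(a, b), abs=1e-12)
        assert icq(fld).icq == pytest.approx(icq_brute(a, b), abs=1e-12)


class TestVanSteensel:
    def test_autocorrelation_symmetric_apex_zero(self, clean_pair):
        a, _, _ = clean_pair
        prof = van_steensel(a, a, max_shift_px=8)
        assert prof.vs_shift_nm == pytest.approx(0.0, abs=15.0)
        mid = prof.r_values[prof.shifts_nm == 0]
        assert mid == pytest.approx(prof.r_values.max())
        # symmetry of the measured profile
        np.testing.assert_allclose(prof.r_values, prof.r_values[::-1], atol=1e-9)

    def test_known_two_pixel_shift(self):
        params = SceneParams(grid_shape=SMALL_GRID, n_puncta=40,
                             displacement=(120.0, 0.0, 0.0), poisson_noise=False,
                             read_noise_sd=0.0, background=0.0, seed=4)
        a, b, _ = make_coloc_stack(params)
        prof = van_steensel(a, b, max_shift_px=10)
        assert prof.fit_ok
        assert prof.vs_shift_nm == pytest.approx(120.0, abs=30.0)

    def test_independent_noise_flags_poor_fit(self):
        flagged = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = _stack(rng.poisson(50, size=(4, 48, 48)).astype(float))
            b = _stack(rng.poisson(50, size=(4, 48, 48)).astype(float))
            prof = van_steensel(a, b, max_shift_px=8)
            flagged += (not prof.fit_ok)
        assert flagged >= 19  # >= 95% of seeds

    def test_min_shift_rejected(self, clean_pair):
        a, b, _ = clean_pair
        with pytest.raises(ValueError, match="max_shift"):
            van_steensel(a, b, max_shift_px=2)


class TestAnalyzePair:
    def test_colocalized_limit(self, noisy_params):
        a, b, _ = make_coloc_stack(noisy_params)
        summ = analyze_pair(a, b, max_shift_px=10)
        assert summ.r > 0.9
        assert summ.icq > 0.3
        assert summ.vs_shift_nm < 60.0

    def test_dispersal_reduces_r_and_icq(self):
        base = dict(grid_shape=SMALL_GRID, n_puncta=40)
        lo, hi = [], []
        for seed in range(5):  # paired seeds
            a, b, _ = make_coloc_stack(SceneParams(**base, seed=seed))
            s0 = analyze_pair(a, b, max_shift_px=6)
            a, b, _ = make_coloc_stack(SceneParams(**base, dispersal_sd=500.0, seed=seed))
            s1 = analyze_pair(a, b, max_shift_px=6)
            lo.append((s1.r, s1.icq))
            hi.append((s0.r, s0.icq))
        assert all(l[0] < h[0] and l[1] < h[1] for l, h in zip(lo, hi))

    def test_record_matches_table_schema(self, clean_pair):
        a, b, _ = clean_pair
        rec = analyze_pair(a, b, max_shift_px=6).to_record()
        for col in ("subject_id", "cell_id", "R", "ICQ", "VS_shift_nm",
                    "FWHM_um", "fit_ok", "flags"):
            assert col in rec

    def test_degenerate_cell_flagged_not_raised(self):
        a = _stack(np.full((2, 8, 8), 5.0))
        b = _stack(np.full((2, 8, 8), 9.0))
        summ = analyze_pair(a, b, max_shift_px=3)
        assert summ.flags  # flagged, batch would continue
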