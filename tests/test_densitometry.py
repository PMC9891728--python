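"""Band mass, lane normalization, and dual-band decomposition."""

import numpy as np
import pytest

from coloc_stress import LaneProfile, band_mass, lane_normalization, dual_band_fit, make_blot

SIGMA = 8.0
PEAK = 10000.0 / (np.sqrt(2 * np.pi) * SIGMA)  # peak of a 10000-area band


def _profile(bands, baseline=(40.0, 0.1), noise_sd=0.0, seed=0):
    img, _ = make_blot(bands, baseline=baseline, noise_sd=noise_sd, seed=seed)
    return LaneProfile.from_image(img)


class TestLaneProfile:
    def test_rect_reduction_is_mean(self):
        img = np.arange(20.0)[:, None] * np.ones((1, 10))
        prof = LaneProfile.from_image(img, rect=(2, 5, 8, 15))
        np.testing.assert_allclose(prof.intensities, np.arange(5.0, 15.0))
        np.testing.assert_allclose(prof.positions, np.arange(5.0, 15.0))

    def test_width_insensitivity(self):
        img, _ = make_blot([(200.0, SIGMA, 5000.0)], noise_sd=0.0)
        narrow = LaneProfile.from_image(img, rect=(10, 0, 20, 400))
        wide = LaneProfile.from_image(img, rect=(0, 0, 60, 400))
        m1 = band_mass(narrow, (160, 240)).signal_mass
        m2 = band_mass(wide, (160, 240)).signal_mass
        assert m1 == pytest.approx(m2, rel=1e-9)


class TestBandMass:
    def test_flat_profile_zero_mass(self):
        prof = _profile([], baseline=(40.0, 0.15))
        assert band_mass(prof, (100, 200)).signal_mass == pytest.approx(0.0, abs=1e-9)

    def test_recovers_area_on_sloped_baseline(self):
        prof = _profile([(200.0, SIGMA, 5000.0)], baseline=(40.0, 0.2))
        q = band_mass(prof, (160, 240))
        assert q.signal_mass == pytest.approx(5000.0, rel=0.02)

    def test_gain_linearity(self):
        img, _ = make_blot([(200.0, SIGMA, 5000.0)], baseline=(0.0, 0.0), noise_sd=0.0)
        m1 = band_mass(LaneProfile.from_image(img), (160, 240)).signal_mass
        m2 = band_mass(LaneProfile.from_image(2.0 * img), (160, 240)).signal_mass
        assert m2 / m1 == pytest.approx(2.0, rel=1e-9)

    def test_window_at_edge_errors(self):
        prof = _profile([])
        with pytest.raises(ValueError, match="edge"):
            band_mass(prof, (0, 100))


class TestLaneNormalization:
    def test_loading_ratio(self):
        lane1 = _profile([(200.0, 30.0, 20000.0)], baseline=(10.0, 0.0),
                         noise_sd=1.0, seed=1)
        lane2 = _profile([(200.0, 30.0, 40000.0)], baseline=(10.0, 0.0),
                         noise_sd=1.0, seed=2)
        f1 = lane_normalization(lane1, background=10.0)
        f2 = lane_normalization(lane2, background=10.0)
        assert f2 / f1 == pytest.approx(2.0, rel=0.05)

    def test_normalized_signal_gain_invariant(self):
        img, _ = make_blot([(200.0, SIGMA, 5000.0)], baseline=(10.0, 0.0), noise_sd=0.0)
        gel, _ = make_blot([(200.0, 40.0, 30000.0)], baseline=(5.0, 0.0), noise_sd=0.0)
        def norm_sig(gain):
            mass = band_mass(LaneProfile.from_image(gain * img), (160, 240)).signal_mass
            fac = lane_normalization(LaneProfile.from_image(gain * gel),
                                     background=gain * 5.0)
            return mass / fac
        assert norm_sig(3.0) == pytest.approx(norm_sig(1.0), rel=1e-9)

    def test_blank_lane_errors(self):
        prof = _profile([], baseline=(20.0, 0.0))
        with pytest.raises(ValueError, match="empty lane"):
            lane_normalization(prof, background=20.0)

    def test_short_region_errors(self):
        prof = LaneProfile(np.arange(30.0), np.ones(30))
        with pytest.raises(ValueError, match="50 px"):
            lane_normalization(prof)


class TestDualBandFit:
    def test_equal_bands_three_sigma_ratio_one(self):
        prof = _profile([(180.0, SIGMA, 5000.0), (204.0, SIGMA, 5000.0)])
        q = dual_band_fit(prof, (140, 250))
        assert q.success
        assert q.dual_ratio == pytest.approx(1.0, rel=0.01)

    def test_noiseless_one_to_two_ratio(self):
        prof = _profile([(190.0, SIGMA, 5000.0), (202.0, SIGMA, 10000.0)])
        q = dual_band_fit(prof, (150, 250))
        assert q.success
        assert q.dual_ratio == pytest.approx(2.0, rel=0.01)

    def test_noisy_ratio_recovery_snr20(self):
        """Separation 1.5 sigma, pixel SNR 20: shared-width decomposition
        (the generator's bands share a width) recovers the 2:1 mass
        ratio; the mean over seeds lands within 5%."""
        ratios = []
        for seed in range(10):
            prof = _profile([(190.0, SIGMA, 5000.0), (202.0, SIGMA, 10000.0)],
                            noise_sd=PEAK / 20.0, seed=seed)
            q = dual_band_fit(prof, (150, 250), shared_width=True)
            assert q.success
            ratios.append(q.dual_ratio)
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.05)

    def test_single_band_profile_flagged(self):
        flagged = 0
        for seed in range(10):
            prof = _profile([(200.0, SIGMA, 5000.0)], baseline=(40.0, 0.0),
                            noise_sd=0.5 * PEAK / 20.0, seed=seed)
            q = dual_band_fit(prof, (150, 250))
            flagged += (not q.success)
        assert flagged >= 9  # >= 90% of seeds

    def test_well_separated_agrees_with_band_mass(self):
        img, _ = make_blot([(150.0, 6.0, 4000.0), (250.0, 6.0, 8000.0)],
                           baseline=(30.0, 0.05), noise_sd=0.0)
        prof = LaneProfile.from_image(img)
        q = dual_band_fit(prof, (110, 290))
        m1 = band_mass(prof, (120, 180)).signal_mass
        m2 = band_mass(prof, (220, 280)).signal_mass
        assert q.masses[0] == pytest.approx(m1, rel=0.02)
        assert q.masses[1] == pytest.approx(m2, rel=0.02)

    def test_mass_conservation_in_window(self):
        prof = _profile([(190.0, SIGMA, 5000.0), (202.0, SIGMA, 10000.0)])
        q = dual_band_fit(prof, (150, 250))
        total = band_mass(prof, (150, 250)).signal_mass
        assert sum(q.masses) == pytest.approx(total, rel=0.03)

    def test_narrow_window_errors(self):
        prof = _profile([(200.0, SIGMA, 5000.0)])
        with pytest.raises(ValueError, match="narrow"):
            dual_band_fit(prof, (200, 202))
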