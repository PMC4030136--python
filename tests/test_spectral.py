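import warnings

import numpy as np
import pytest
from scipy import stats as sps
from scipy.signal import windows

from prestim.containers import EpochSet
from prestim.preprocess import ReferenceScheme, rereference
from prestim.spectral import (
    alpha_power_contrast,
    circular_difference_deg,
    circular_mean,
    phase_lag_analysis,
    spectral_estimate,
    watson_williams,
)


def _epochs(montage, data, fs=1000.0, onset=200):
    n_trials = data.shape[0]
    conds = np.array((["CA", "CU"] * n_trials)[:n_trials])
    return EpochSet(data=data, fs=fs, onset_index=onset, conditions=conds, montage=montage)


class TestSpectralEstimate:
    def test_bin_spacing_5hz(self, montage16, rng):
        data = rng.normal(size=(2, 16, 200))
        est = spectral_estimate(_epochs(montage16, data), window_ms=200.0)
        assert est.freqs[1] - est.freqs[0] == pytest.approx(5.0)
        assert est.freqs[2] == pytest.approx(10.0)

    def test_off_bin_frequency_rejected(self, montage16, rng):
        est = spectral_estimate(_epochs(montage16, rng.normal(size=(1, 16, 200))))
        with pytest.raises(ValueError):
            est.at_freq(12.5)

    def test_onbin_cosine_phase(self, montage16):
        """Phase of an on-bin 10 Hz cosine against the closed-form windowed
        DFT (the Blackman window leaks a conjugate term at bin 4)."""
        N, fs = 200, 1000.0
        n = np.arange(N)
        w = windows.blackman(N, sym=True)
        W = lambda m: np.sum(w * np.exp(-2j * np.pi * m * n / N))
        for phi in (-2.0, -0.5, 0.0, 0.9, 2.7):
            x = np.cos(2 * np.pi * 10 * n / fs + phi)
            data = np.tile(x, (1, 16, 1))
            est = spectral_estimate(_epochs(montage16, data), window_ms=200.0)
            _, phase = est.at_freq(10.0)
            expected = np.angle(0.5 * (np.exp(1j * phi) * W(0) + np.exp(-1j * phi) * W(4)))
            assert phase[0, 0] == pytest.approx(expected, abs=1e-9)
            assert abs(np.angle(np.exp(1j * (phase[0, 0] - phi)))) < 0.01

    def test_zero_signal_phase_undefined(self, montage16):
        data = np.zeros((1, 16, 250))
        est = spectral_estimate(_epochs(montage16, data, onset=250))
        power, phase = est.at_freq(10.0)
        assert power.max() == 0.0
        assert np.isnan(phase).all()

    def test_power_invariant_to_constant_offset_outside_mainlobe(self, montage16):
        """A DC offset leaks only into the Blackman mainlobe (bins 0-2);
        power at bins beyond it, e.g. 25 Hz, is essentially unchanged."""
        t = np.arange(200) / 1000.0
        x = np.cos(2 * np.pi * 25 * t)
        data = np.tile(x, (1, 16, 1))
        p0, _ = spectral_estimate(_epochs(montage16, data)).at_freq(25.0)
        p1, _ = spectral_estimate(_epochs(montage16, data + 11.0)).at_freq(25.0)
        assert p1 == pytest.approx(p0, rel=1e-2)


class TestCircularMean:
    def test_single_angle(self):
        mean, rbar = circular_mean(np.array([1.2]))
        assert mean == pytest.approx(1.2) and rbar == pytest.approx(1.0)

    def test_antipodal_undefined(self):
        mean, rbar = circular_mean(np.array([0.0, np.pi]))
        assert np.isnan(mean) and rbar < 1e-12

    def test_hand_value_45deg(self):
        mean, rbar = circular_mean(np.radians([0.0, 90.0]))
        assert np.degrees(mean) == pytest.approx(45.0)
        assert rbar == pytest.approx(np.sqrt(2) / 2)

    def test_matches_scipy_circmean(self, rng):
        angles = rng.vonmises(0.7, 2.0, 50)
        mean, _ = circular_mean(angles)
        ref = sps.circmean(angles, high=np.pi, low=-np.pi)
        assert np.angle(np.exp(1j * (mean - ref))) == pytest.approx(0.0, abs=1e-9)

    def test_invariant_to_2pi_relabeling(self, rng):
        angles = rng.vonmises(0.3, 3.0, 20)
        m0, r0 = circular_mean(angles)
        m1, r1 = circular_mean(angles + 2 * np.pi)
        assert np.angle(np.exp(1j * (m1 - m0))) == pytest.approx(0.0, abs=1e-12)
        assert r1 == pytest.approx(r0)


class TestWatsonWilliams:
    def test_same_sample_no_difference(self, rng):
        a = rng.vonmises(0.5, 3.0, 25)
        res = watson_williams(a, a.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        """A = {-10, 0, 10} deg, B = {80, 90, 100} deg: resultants are known
        in closed form (R1 = R2 = 1 + 2 cos 10deg), giving F ~ 115."""
        a = np.radians([-10.0, 0.0, 10.0])
        b = np.radians([80.0, 90.0, 100.0])
        res = watson_williams(a, b)
        r1 = 1 + 2 * np.cos(np.radians(10.0))
        R = np.sqrt(2) * r1
        rbar = 2 * r1 / 6
        kappa = 1 / (rbar**3 - 4 * rbar**2 + 3 * rbar)
        K = 1 + 3 / (8 * kappa)
        f_expected = K * 4 * (2 * r1 - R) / (6 - 2 * r1)
        assert res.statistic == pytest.approx(f_expected, rel=1e-12)
        assert res.statistic == pytest.approx(115.0, rel=0.01)
        assert res.p < 0.001
        assert res.df == (1, 4)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            watson_williams(np.array([0.2, 0.2, 0.2]), np.array([0.2, 0.2, 0.2]))

    def test_low_concentration_warns(self, rng):
        a = rng.uniform(-np.pi, np.pi, 30)
        b = rng.uniform(-np.pi, np.pi, 30)
        with pytest.warns(UserWarning):
            watson_williams(a, b)


class TestCircularDifference:
    def test_wraps_into_half_open_interval(self):
        assert circular_difference_deg(np.pi, 0.0) == pytest.approx(180.0)
        assert circular_difference_deg(0.0, np.pi) == pytest.approx(180.0)
        assert circular_difference_deg(0.2, 0.1) == pytest.approx(np.degrees(0.1))


def _alpha_cohort(montage, rng, n_subjects=6, n_trials=24, offset=np.pi,
                  channel_weights=None, power_boost_cu=1.0):
    """Subjects with a 10 Hz component whose onset phase differs by
    ``offset`` between conditions, projected through ``channel_weights``."""
    n_ch = montage.n_channels
    if channel_weights is None:
        channel_weights = np.ones(n_ch)
    out = []
    t = (np.arange(300) - 250) / 1000.0
    for s in range(n_subjects):
        data = rng.normal(0, 0.3, size=(n_trials, n_ch, 300))
        conds = np.array((["CA", "CU"] * n_trials)[:n_trials])
        for tr in range(n_trials):
            mu = 0.0 if conds[tr] == "CA" else offset
            theta = rng.vonmises(mu, 8.0)
            amp = power_boost_cu if conds[tr] == "CU" else 1.0
            data[tr] += amp * np.outer(channel_weights, np.cos(2 * np.pi * 10 * t + theta))
        out.append(EpochSet(data=data, fs=1000.0, onset_index=250,
                            conditions=conds, montage=montage,
                            subject_id=f"S{s:02d}"))
    return out


class TestPhaseLagAnalysis:
    def test_reference_electrode_lag_undefined(self, montage16, rng):
        cohort = _alpha_cohort(montage16, rng)
        res = phase_lag_analysis(
            cohort, [ReferenceScheme("electrode", electrode_name="Cz")], freq=10.0
        )
        tab = res["Cz"]
        row = tab[tab["channel"] == "Cz"].iloc[0]
        assert np.isnan(row["lag_deg"]) and not row["flagged"]

    def test_planted_inversion_flagged_under_average_reference(self, montage16, rng):
        """Channels carrying an opposite-phase alpha component are flagged as
        near-inversions (|lag| close to 180 deg)."""
        weights = np.zeros(16)
        weights[:8] = 1.0   # half the montage carries the oscillation
        cohort = _alpha_cohort(montage16, rng, channel_weights=weights)
        res = phase_lag_analysis(cohort, [ReferenceScheme("average")], freq=10.0)
        tab = res["average"]
        carrying = tab.iloc[:8]
        assert carrying["flagged"].sum() >= 6
        assert np.abs(carrying["lag_deg"]).min() > 150.0


class TestAlphaPowerContrast:
    def test_identical_conditions_null(self, montage16, rng):
        cohort = _alpha_cohort(montage16, rng, offset=0.0)
        for ep in cohort:
            # make CU trials literal copies of CA trials
            ca = np.flatnonzero(ep.conditions == "CA")
            cu = np.flatnonzero(ep.conditions == "CU")
            ep.data[cu] = ep.data[ca]
        table = alpha_power_contrast(cohort, freq=10.0)
        assert np.abs(table["t"]).max() == 0.0
        assert not table["significant"].any()

    def test_planted_power_boost_detected(self, montage16, rng):
        weights = np.zeros(16)
        weights[4:10] = 1.0
        cohort = _alpha_cohort(
            montage16, rng, n_subjects=8, offset=0.0,
            channel_weights=weights, power_boost_cu=1.6,
        )
        table = alpha_power_contrast(cohort, freq=10.0)
        boosted = table.iloc[4:10]
        assert boosted["significant"].any()
        assert (boosted["t"] < 0).all()   # CU power higher -> negative t
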