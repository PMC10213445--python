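"""First-harmonic extraction, cosinor fitting and circular statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from circaeeg.rhythm import (
    amplitude_peaktime,
    circular_difference,
    circular_mean,
    cosinor_fit,
    fourier_component,
    mww_test,
    normalize_power,
)
from circaeeg.spectra import HourlyStageSpectra, N_FREQ


def _hss_from_series(series):
    """Wrap a single hourly series into a full tensor (NREM, all freqs)."""
    n = len(series)
    power = np.ones((n, 3, N_FREQ))
    power[:, 1, :] = np.asarray(series)[:, None]
    power[:, :, 0] = 0.0  # DC
    counts = np.full((n, 3), 10)
    return HourlyStageSpectra(power=power, n_epochs=counts)


class TestNormalizePower:
    def test_constant_series_gives_zeros(self):
        nps = normalize_power(_hss_from_series(np.full(72, 5.0)))
        assert np.allclose(nps.norm[:, 1, 1:], 0.0)

    def test_two_value_example(self):
        # mean of {1, 3} is 2 -> normalized {-0.5, +0.5}
        series = np.concatenate([np.full(36, 1.0), np.full(36, 3.0)])
        nps = normalize_power(_hss_from_series(series))
        assert np.allclose(nps.norm[:36, 1, 1], -0.5)
        assert np.allclose(nps.norm[36:, 1, 1], 0.5)

    def test_output_mean_is_zero(self):
        rng = np.random.default_rng(0)
        nps = normalize_power(_hss_from_series(rng.uniform(1, 3, 72)))
        assert np.nanmean(nps.norm[:, 1, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_dc_bin_invalid(self):
        nps = normalize_power(_hss_from_series(np.full(72, 5.0)))
        assert not nps.valid[1, 0]
        assert np.all(np.isnan(nps.norm[:, 1, 0]))

    def test_too_few_hours_invalid(self):
        hss = _hss_from_series(np.full(12, 5.0))
        assert not normalize_power(hss).valid.any()


class TestFourierComponent:
    def test_recovers_pure_cosine_exactly(self):
        """Discrete orthogonality over 3 full cycles of 24 hourly samples."""
        i = np.arange(1, 73)
        series = 0.3 * np.cos(2 * np.pi * (i - 18) / 24.0)
        c, s = fourier_component(series)
        a, tp = amplitude_peaktime(c, s)
        assert a == pytest.approx(0.3, abs=1e-9)
        assert tp == pytest.approx(18.0, abs=1e-6)

    def test_zero_series(self):
        assert fourier_component(np.zeros(72)) == (0.0, 0.0)

    def test_orthogonal_12h_harmonic(self):
        i = np.arange(1, 73)
        series = np.cos(2 * np.pi * i / 12.0)
        c, s = fourier_component(series)
        assert abs(c) < 1e-12 and abs(s) < 1e-12

    def test_missing_hours_unbiased(self):
        i = np.arange(1, 73, dtype=float)
        series = 0.3 * np.cos(2 * np.pi * (i - 18) / 24.0)
        series[::6] = np.nan  # drop every 6th hour: still balanced sampling
        c, s = fourier_component(series)
        a, tp = amplitude_peaktime(c, s)
        assert a == pytest.approx(0.3, abs=1e-9)
        assert tp == pytest.approx(18.0, abs=1e-6)

    @given(shift=st.integers(0, 23))
    def test_rotation_covariance(self, shift):
        """Circularly shifting the series shifts t_p and preserves A."""
        rng = np.random.default_rng(99)
        series = rng.normal(size=72)
        a0, tp0 = amplitude_peaktime(*fourier_component(series))
        rolled = np.roll(series, shift)
        a1, tp1 = amplitude_peaktime(*fourier_component(rolled))
        assert a1 == pytest.approx(a0, abs=1e-9)
        assert abs(circular_difference(tp1, (tp0 + shift) % 24)) < 1e-6


class TestAmplitudePeaktime:
    @pytest.mark.parametrize(
        "cos,sin,a,tp",
        [(1.0, 0.0, 1.0, 0.0), (0.0, 1.0, 1.0, 6.0), (0.0, -1.0, 1.0, 18.0)],
    )
    def test_quadrants(self, cos, sin, a, tp):
        a_hat, tp_hat = amplitude_peaktime(cos, sin)
        assert a_hat == pytest.approx(a, abs=1e-12)
        assert tp_hat == pytest.approx(tp, abs=1e-12)

    def test_zero_amplitude_has_no_peak(self):
        a, tp = amplitude_peaktime(0.0, 0.0)
        assert a == 0.0 and np.isnan(tp)


class TestCosinor:
    def test_noiseless_exact(self):
        t = np.arange(72.0)
        y = 5.0 + 2.0 * np.cos(2 * np.pi * (t - 20.0) / 24.0)
        fit = cosinor_fit(t, y)
        assert fit.mesor == pytest.approx(5.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-6)
        assert fit.acrophase == pytest.approx(20.0, abs=1e-6)
        assert fit.period == pytest.approx(24.0, abs=1e-6)
        assert fit.rss < 1e-10

    def test_constant_series_flagged(self):
        fit = cosinor_fit(np.arange(24.0), np.full(24, 3.0))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)
        assert not fit.period_identifiable

    def test_agrees_with_harmonic_estimator(self):
        t = np.arange(72.0)
        y = 1.0 + 0.4 * np.cos(2 * np.pi * (t - 7.0) / 24.0)
        fit = cosinor_fit(t, y)
        # the fixed-24 h harmonic estimator uses 1-based hour times
        c, s = fourier_component(y[np.argsort(t)] - y.mean())
        _, tp = amplitude_peaktime(c, s)
        assert abs(circular_difference(fit.acrophase, tp - 1.0)) < 1e-5

    def test_noisy_recovery(self):
        """A=2, sd=0.2 noise: amplitude and phase recovered in >=95% of runs."""
        t = np.arange(72.0)
        truth = 5.0 + 2.0 * np.cos(2 * np.pi * (t - 20.0) / 24.0)
        rng = np.random.default_rng(7)
        ok = 0
        n_rep = 100
        for _ in range(n_rep):
            fit = cosinor_fit(t, truth + rng.normal(0, 0.2, size=72))
            if abs(fit.amplitude - 2.0) < 0.15 and abs(
                circular_difference(fit.acrophase, 20.0)
            ) < 0.5:
                ok += 1
        assert ok >= 95


class TestMWW:
    def test_identical_groups(self):
        g = np.array([1.0, 3.0, 6.0, 9.0, 14.0, 20.0, 22.0, 11.0])
        res = mww_test(g, g, n_permutations=999, seed=0)
        assert res["p_permutation"] > 0.5

    def test_separated_groups(self):
        rng = np.random.default_rng(0)
        g1 = np.mod(6.0 + rng.normal(0, 0.5, 10), 24)
        g2 = np.mod(18.0 + rng.normal(0, 0.5, 10), 24)
        res = mww_test(g1, g2, n_permutations=9999, seed=0)
        assert res["p_permutation"] < 0.01

    def test_rotation_invariance(self):
        rng = np.random.default_rng(1)
        g1 = rng.uniform(0, 24, 8)
        g2 = rng.uniform(0, 24, 8)
        w0 = mww_test(g1, g2, n_permutations=9)["W"]
        # rotate by an amount that does not reorder across the 0/24 seam
        shift = 0.01
        w1 = mww_test(np.mod(g1 + shift, 24), np.mod(g2 + shift, 24), n_permutations=9)["W"]
        assert w1 == pytest.approx(w0, abs=1e-9)

    def test_chisq_matches_permutation_at_n20(self):
        rng = np.random.default_rng(5)
        g1 = np.mod(8.0 + rng.normal(0, 3.0, 20), 24)
        g2 = np.mod(10.0 + rng.normal(0, 3.0, 20), 24)
        res = mww_test(g1, g2, n_permutations=9999, seed=0)
        assert abs(res["p_chisq"] - res["p_permutation"]) < 0.02

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            mww_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0, 7.0])


class TestCircularMean:
    def test_plain(self):
        assert circular_mean([6.0, 6.0, 6.0]) == pytest.approx(6.0, abs=1e-9)

    def test_wraparound(self):
        assert circular_mean([23.0, 1.0]) == pytest.approx(0.0, abs=1e-9)

    def test_antipodal_is_undefined(self):
        assert np.isnan(circular_mean([0.0, 12.0]))

    @given(t=st.floats(0, 24, exclude_max=True))
    def test_difference_is_signed_and_bounded(self, t):
        d = circular_difference(t, (t + 5.0) % 24)
        assert d == pytest.approx(-5.0, abs=1e-9)
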