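import numpy as np
import pytest

from astrofilter.response import (LogisticFit, ResponseCurve, StimWindows,
                                  classify_stimulated, exact_onset_frequency,
                                  fit_logistic, normalize_trace, onset_frequency,
                                  response_delay, responsiveness)


def logistic(f, A, B, C, tau):
    return A + (B - A) / (1 + np.exp(-(f - C) / tau))


class TestNormalize:
    def test_values(self):
        assert np.all(normalize_trace(np.full(5, 2.0), 2.0) == 0)
        assert normalize_trace(np.array([4.0]), 2.0)[0] == 1.0
        a = normalize_trace(np.array([3.0]), 2.0)
        b = normalize_trace(np.array([4.0]), 2.0)
        assert b[0] == pytest.approx(2 * a[0])

    def test_nonpositive_rest_rejected(self):
        with pytest.raises(ValueError):
            normalize_trace(np.ones(3), 0.0)


class TestResponsiveness:
    time = np.arange(0.0, 90.0, 0.1)
    windows = StimWindows(stim=((30.0, 60.0),), spont=(0.0, 29.9))

    def test_constant_series_zero(self):
        assert responsiveness(np.full_like(self.time, 3.3), self.time,
                              self.windows) == pytest.approx(0.0)

    def test_indicator_series_one(self):
        series = ((self.time >= 30) & (self.time <= 60)).astype(float)
        assert responsiveness(series, self.time, self.windows) == pytest.approx(1.0)

    def test_ramp_matches_direct_window_sums(self):
        """Oracle: compute both window means by direct summation."""
        series = 0.05 * self.time + np.sin(0.2 * self.time)
        stim_mask = (self.time >= 30) & (self.time <= 60)
        spont_mask = (self.time >= 0) & (self.time <= 29.9)
        expected = series[stim_mask].sum() / stim_mask.sum() \
            - series[spont_mask].sum() / spont_mask.sum()
        assert responsiveness(series, self.time, self.windows) == pytest.approx(expected)

    def test_offset_invariance_and_linearity(self, rng):
        series = rng.normal(size=self.time.size)
        r = responsiveness(series, self.time, self.windows)
        assert responsiveness(series + 5.0, self.time,
                              self.windows) == pytest.approx(r, abs=1e-12)
        assert responsiveness(3.0 * series, self.time,
                              self.windows) == pytest.approx(3 * r, abs=1e-12)

    def test_population_mean_equals_mean_of_cells(self, rng):
        cells = rng.normal(size=(7, self.time.size))
        singles = [responsiveness(c, self.time, self.windows) for c in cells]
        pop = responsiveness(cells.mean(axis=0), self.time, self.windows)
        assert pop == pytest.approx(np.mean(singles))

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            StimWindows(stim=((10.0, 40.0),), spont=(30.0, 50.0))


class TestLogisticFit:
    freqs = np.array([0.5, 1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 15, 20.0])

    def test_exact_recovery_on_noiseless_data(self):
        r = logistic(self.freqs, 0.0, 1.0, 5.0, 1.0)
        fit = fit_logistic(ResponseCurve(self.freqs, r))
        assert fit.mode == "sigmoid" and fit.ok
        assert fit.A == pytest.approx(0.0, abs=1e-6)
        assert fit.B == pytest.approx(1.0, abs=1e-6)
        assert fit.C == pytest.approx(5.0, abs=1e-6)
        assert fit.tau == pytest.approx(1.0, abs=1e-6)

    def test_constant_data_flagged_degenerate(self):
        fit = fit_logistic(ResponseCurve(self.freqs, np.full(self.freqs.size, 2.0)))
        assert not fit.ok
        assert onset_frequency(fit).ok is False

    def test_no_plateau_falls_back_to_exponential_rise(self):
        r = 0.1 * np.exp(self.freqs / 8.0)
        fit = fit_logistic(ResponseCurve(self.freqs, r))
        assert fit.mode == "exponential"
        est = onset_frequency(fit)
        assert est.ok and np.isfinite(est.frequency_hz)

    def test_noisy_confidence_interval_coverage(self):
        """Monte-Carlo: with 5% noise the true midpoint C lies inside its
        95% CI (from the fit covariance) in at least ~90% of replicates."""
        rng = np.random.default_rng(7)
        A, B, C, tau = 0.0, 1.0, 5.0, 1.0
        hits = trials = 0
        for _ in range(200):
            r = logistic(self.freqs, A, B, C, tau) + rng.normal(0, 0.05 * B,
                                                                self.freqs.size)
            fit = fit_logistic(ResponseCurve(self.freqs, r))
            if not (fit.ok and fit.mode == "sigmoid" and fit.covariance is not None):
                continue
            var_c = fit.covariance[2, 2]
            if not np.isfinite(var_c) or var_c <= 0:
                continue
            trials += 1
            half = 1.96 * np.sqrt(var_c)
            hits += (fit.C - half) <= C <= (fit.C + half)
        assert trials > 150
        assert hits / trials >= 0.90


class TestOnset:
    def fit(self, A=0.0, B=1.0, C=5.0, tau=1.0):
        return LogisticFit(A, B, C, tau, None, 0.0)

    def test_closed_form_ten_percent_point(self):
        est = onset_frequency(self.fit())
        assert est.frequency_hz == pytest.approx(5.0 - np.log(9))

    def test_shift_equivariance(self):
        a = onset_frequency(self.fit(C=5.0)).frequency_hz
        b = onset_frequency(self.fit(C=7.5)).frequency_hz
        assert b - a == pytest.approx(2.5)

    def test_steep_limit_approaches_midpoint(self):
        est = onset_frequency(self.fit(tau=1e-6))
        assert est.frequency_hz == pytest.approx(5.0, abs=1e-4)

    def test_onset_below_midpoint(self):
        for tau in (0.3, 1.0, 2.5):
            assert onset_frequency(self.fit(tau=tau)).frequency_hz < 5.0


class TestExactOnset:
    def test_inflection_of_sampled_sigmoid(self):
        f = np.linspace(0.5, 10, 40)
        r = logistic(f, 0, 1, 5, 0.8)
        est = exact_onset_frequency(ResponseCurve(f, r))
        step = f[1] - f[0]
        assert abs(est.frequency_hz - 5.0) <= step

    def test_linear_curve_flagged_flat(self):
        f = np.linspace(1, 10, 10)
        est = exact_onset_frequency(ResponseCurve(f, 0.3 * f))
        assert not est.ok


class TestResponseDelay:
    time = np.arange(0.0, 60.0, 0.1)

    def test_step_response(self):
        series = (self.time >= 30.5).astype(float)
        d = response_delay(series, self.time, 30.0)
        assert d == pytest.approx(0.5, abs=0.11)
        assert classify_stimulated(d)

    def test_flat_series_unstimulated(self):
        d = response_delay(np.zeros_like(self.time), self.time, 30.0)
        assert d is None and not classify_stimulated(d)

    def test_linear_ramp_crosses_at_sixty_percent(self):
        T = 20.0
        series = np.clip((self.time - 30.0) / T, 0.0, 1.0)
        d = response_delay(series, self.time, 30.0)
        assert d == pytest.approx(0.6 * T, abs=0.11)

    def test_slow_responder_not_classified_stimulated(self):
        series = (self.time >= 33.0).astype(float)
        assert not classify_stimulated(response_delay(series, self.time, 30.0))
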