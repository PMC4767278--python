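"""Spectral statistics: normalization, response measures, bootstrap, OLS."""

import numpy as np
import pytest

from wcresonance import (
    BootstrapConfig,
    PowerSpectrum,
    ResonanceCurve,
    bootstrap_peak_frequency,
    bootstrap_response_power,
    bootstrap_spectrum_peak,
    bootstrap_statistic,
    linear_fit,
    peak_driving_frequency,
    power_spectrum,
    response_power_at,
    ssep_response_power,
)


def _sinusoid(freq, n=2000, dt=0.001, phase=0.3):
    t = np.arange(n) * dt
    return np.sin(2 * np.pi * freq * t + phase)


class TestPowerSpectrum:
    def test_sinusoid_concentrates_in_one_bin(self):
        spec = power_spectrum(_sinusoid(12.5), 0.001)
        assert spec.power.max() == pytest.approx(1.0, abs=1e-6)
        # Delta f = 0.5 Hz, DC dropped: 12.5 Hz lands at index 24
        assert np.argmax(spec.power) == 24
        assert spec.freqs[np.argmax(spec.power)] == pytest.approx(12.5)

    def test_normalization(self, rng):
        spec = power_spectrum(rng.standard_normal(1500), 0.001)
        assert spec.power.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(spec.power >= 0)
        assert np.all(np.diff(spec.freqs) > 0)
        assert spec.freqs[0] > 0  # DC excluded

    def test_offset_invariance(self, rng):
        x = rng.standard_normal(1000)
        a = power_spectrum(x, 0.001)
        b = power_spectrum(x + 100.0, 0.001)
        assert np.allclose(a.power, b.power, atol=1e-9)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            power_spectrum(np.ones(100), 0.001)


class TestResponsePower:
    def test_concentrated_spectrum_gives_one(self):
        spec = power_spectrum(_sinusoid(10.0), 0.001)
        assert response_power_at(spec, 10.0) == pytest.approx(1.0, abs=1e-6)

    def test_flat_spectrum_gives_reciprocal_bins(self):
        n = 200
        freqs = np.arange(1, n + 1) * 0.5
        spec = PowerSpectrum(freqs, np.full(n, 1.0 / n))
        assert response_power_at(spec, 30.0) == pytest.approx(1.0 / n)

    def test_off_grid_frequency_maps_to_nearest_bin(self):
        spec = power_spectrum(_sinusoid(12.5), 0.001)  # Delta f = 0.5
        assert response_power_at(spec, 12.6) == response_power_at(spec, 12.5)

    def test_ssep_three_bin_capture(self):
        # power concentrated one bin away from the nominal frequency
        spec = power_spectrum(_sinusoid(12.5), 0.001)
        assert ssep_response_power(spec, 13.0) == pytest.approx(1.0, abs=1e-6)

    def test_ssep_equals_point_response_when_bin_dominates(self):
        spec = power_spectrum(_sinusoid(12.5), 0.001)
        assert ssep_response_power(spec, 12.5) == response_power_at(spec, 12.5)

    def test_ordering_invariant(self, rng):
        spec = power_spectrum(rng.standard_normal(1000), 0.001)
        for f in (5.0, 20.0, 100.0):
            assert (
                response_power_at(spec, f)
                <= ssep_response_power(spec, f)
                <= 1.0
            )


class TestBootstrap:
    def _spectra(self, rng, n=20):
        return [power_spectrum(rng.standard_normal(1000), 0.001) for _ in range(n)]

    def test_identical_inputs_give_zero_sd(self):
        spec = power_spectrum(_sinusoid(10.0), 0.001)
        mean, sd = bootstrap_response_power([spec] * 10, 10.0, BootstrapConfig(200))
        assert sd == 0.0
        assert mean == pytest.approx(1.0, abs=1e-6)

    def test_seeded_reproducibility(self, rng):
        spectra = self._spectra(rng)
        cfg = BootstrapConfig(n_boot=50, seed=5)
        assert bootstrap_response_power(
            spectra, 20.0, cfg
        ) == bootstrap_response_power(spectra, 20.0, cfg)

    def test_mean_close_to_plug_in_statistic(self, rng):
        spectra = self._spectra(rng, n=40)
        mean, sd = bootstrap_response_power(
            spectra, 25.0, BootstrapConfig(n_boot=2000, seed=1)
        )
        plug_in = np.mean([response_power_at(s, 25.0) for s in spectra])
        assert mean == pytest.approx(plug_in, abs=4 * sd / np.sqrt(2000) + 1e-4)

    def test_averaged_spectra_stay_normalized(self, rng):
        spectra = self._spectra(rng)
        P = np.stack([s.power for s in spectra])
        idx = np.random.default_rng(0).integers(0, len(spectra), size=(50, 20))
        sums = P[idx].mean(axis=1).sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_peak_frequency_identifies_driven_condition(self, rng):
        # condition at 10 Hz has all its power at 10 Hz; others are noise
        conds = []
        for f in (8.0, 10.0, 12.0):
            if f == 10.0:
                spectra = [power_spectrum(_sinusoid(10.0), 0.001)] * 5
            else:
                spectra = self._spectra(rng, n=5)
            conds.append((f, spectra))
        mean, sd = bootstrap_peak_frequency(conds, BootstrapConfig(100, seed=2))
        assert mean == pytest.approx(10.0)
        assert sd == 0.0

    def test_dispatcher_routes_both_statistics(self, rng):
        spectra = self._spectra(rng, n=6)
        cfg = BootstrapConfig(50, seed=3)
        assert bootstrap_statistic(
            spectra, 20.0, cfg, "response_at_drive"
        ) == bootstrap_response_power(spectra, 20.0, cfg)
        conds = [(10.0, spectra), (11.0, spectra)]
        assert bootstrap_statistic(
            conds, None, cfg, "peak_drive_freq"
        ) == bootstrap_peak_frequency(conds, cfg)

    def test_spectrum_peak_on_pure_tone(self):
        spec = power_spectrum(_sinusoid(9.0, n=5000), 0.001)
        mean, sd, power = bootstrap_spectrum_peak([spec] * 8, BootstrapConfig(100))
        assert mean == pytest.approx(9.0)
        assert sd == 0.0
        assert power == pytest.approx(1.0, abs=1e-6)


class TestPeakDrivingFrequency:
    def test_single_point(self):
        c = ResonanceCurve(np.array([12.0]), np.array([0.3]), np.array([0.0]))
        assert peak_driving_frequency(c) == 12.0

    def test_unimodal_mode(self):
        f = np.arange(10.0, 15.5, 0.5)
        resp = -((f - 13.0) ** 2)
        c = ResonanceCurve(f, resp, np.zeros_like(f))
        assert peak_driving_frequency(c) == 13.0

    def test_tie_breaks_toward_lower_frequency(self):
        c = ResonanceCurve(
            np.array([12.5, 13.0]), np.array([0.4, 0.4]), np.zeros(2)
        )
        assert peak_driving_frequency(c) == 12.5


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = linear_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.p_value < 1e-10

    def test_hand_computed_five_points(self):
        # worked by hand: slope 6/10, intercept 2.2, R^2 = 1 - 2.4/6
        fit = linear_fit([1, 2, 3, 4, 5], [2, 4, 5, 4, 5])
        assert fit.slope == pytest.approx(0.6)
        assert fit.intercept == pytest.approx(2.2)
        assert fit.r_squared == pytest.approx(0.6)

    def test_independent_y_gives_small_r_squared(self, rng):
        x = np.arange(50.0)
        y = rng.permutation(x)
        assert linear_fit(x, y).r_squared < 0.2

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            linear_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
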