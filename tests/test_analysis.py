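"""Signal analysis: spike density, wavelet features, PPC, coherence,
phase differences, period metrics and circular statistics."""

import numpy as np
import pytest
from scipy.signal import chirp

from pingnet.analysis import (DensityTrace, circular_linear_correlation,
                              instantaneous_features, morlet_transform,
                              multitaper_coherence, pairwise_phase_consistency,
                              period_metrics, phase_difference, spike_density,
                              spike_phases)
from pingnet.network import SpikeRaster


def _raster(times, ids, n=400, duration=1000.0, label="c0E"):
    return SpikeRaster(np.asarray(times, float), np.asarray(ids, np.int32),
                       {label: slice(0, n)}, duration, 0.05)


class TestSpikeDensity:
    def test_no_spikes_all_zero(self):
        d = spike_density(_raster([], []), "c0E")
        assert np.all(d.values == 0.0)

    def test_single_spike_bin_value(self):
        """One spike among N = 400 in a 0.5 ms bin -> 1000/(0.5*400) = 5."""
        d = spike_density(_raster([100.2], [7]), "c0E")
        k = int(100.2 / 0.5)
        assert d.values[k] == pytest.approx(5.0)
        assert d.values.sum() == pytest.approx(5.0)

    def test_poisson_population_recovers_rate(self):
        rng = np.random.default_rng(0)
        rate, n, T = 20.0, 400, 30000.0
        counts = rng.poisson(rate * T / 1000.0, size=n)
        times = np.concatenate([rng.uniform(0, T, c) for c in counts])
        ids = np.concatenate([np.full(c, i) for i, c in enumerate(counts)])
        d = spike_density(_raster(times, ids, duration=T), "c0E", t1=T)
        assert d.values.mean() == pytest.approx(rate, rel=0.02)

    def test_counts_are_integer_consistent(self):
        d = spike_density(_raster([10.1, 10.2, 50.0], [1, 2, 3]), "c0E")
        assert d.counts().sum() == 3

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            spike_density(_raster([1.0], [0]), "c0E", dt=0.0)


class TestMorlet:
    dt = 0.5
    t = np.arange(0, 3000, dt)

    def test_pure_cosine_ridge_and_phase(self):
        x = np.cos(2 * np.pi * 40 * self.t / 1000.0)
        f = instantaneous_features(morlet_transform(x, dt=self.dt))
        assert abs(f.mean_frequency - 40.0) < 0.05
        maxima = np.arange(300, 2700, 25.0)
        ph = f.phase_at(maxima)
        ph = np.mod(ph + np.pi, 2 * np.pi) - np.pi
        assert np.abs(ph).max() < 0.05

    def test_constant_signal_has_no_power(self):
        m = morlet_transform(np.full(2000, 3.7), dt=self.dt)
        assert m.power.max() < 1e-12

    def test_amplitude_doubling_quadruples_power(self):
        x = np.cos(2 * np.pi * 40 * self.t / 1000.0)
        f1 = instantaneous_features(morlet_transform(x, dt=self.dt))
        f2 = instantaneous_features(morlet_transform(2 * x, dt=self.dt))
        v = f1.valid
        assert np.allclose(f2.power[v], 4 * f1.power[v], rtol=1e-6)
        assert np.allclose(f2.phase[v], f1.phase[v], atol=1e-6)

    def test_chirp_frequency_monotone(self):
        x = chirp(self.t / 1000.0, 30, 3.0, 50)
        f = instantaneous_features(morlet_transform(x, dt=self.dt))
        fr = f.frequency[f.valid]
        sm = np.convolve(fr, np.ones(201) / 201, mode="valid")
        assert np.all(np.diff(sm[::100]) > 0)

    def test_grid_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            morlet_transform(np.zeros(100), frequencies=np.array([1100.0]),
                             dt=self.dt)

    def test_low_synchrony_flags_frequency_undefined(self):
        x = np.cos(2 * np.pi * 40 * self.t / 1000.0)
        f = instantaneous_features(morlet_transform(x, dt=self.dt), ppc=0.01)
        assert not f.defined and f.frequency is None


class TestPPC:
    def test_identical_phases_give_one(self):
        assert pairwise_phase_consistency(np.full(17, 0.8)) == pytest.approx(1.0)

    def test_uniform_phases_unbiased_near_zero(self):
        rng = np.random.default_rng(1)
        vals = [pairwise_phase_consistency(rng.uniform(0, 2 * np.pi, 1000))
                for _ in range(100)]
        assert abs(np.mean(vals)) < 0.01

    def test_closed_form_equals_pair_loop(self):
        """Closed form vs explicit O(n^2) average over all unordered pairs."""
        rng = np.random.default_rng(2)
        ph = rng.uniform(0, 2 * np.pi, 200)
        brute = np.mean([np.cos(a - b) for i, a in enumerate(ph)
                         for b in ph[i + 1:]])
        assert pairwise_phase_consistency(ph) == pytest.approx(brute, abs=1e-12)

    def test_too_few_spikes_flagged(self):
        with pytest.raises(ValueError):
            pairwise_phase_consistency(np.array([1.0]))


class TestCoherence:
    dt = 0.5
    t = np.arange(0, 3000, dt)

    def test_self_coherence_is_one(self):
        x = np.cos(2 * np.pi * 40 * self.t / 1000.0)
        c = multitaper_coherence(x, x)
        band = (c.frequencies > 5) & (c.frequencies < 900)
        assert np.allclose(c.coherence[band], 1.0, atol=1e-9)

    def test_lagged_common_sinusoid_high_coherence(self):
        rng = np.random.default_rng(3)
        x = np.cos(2 * np.pi * 40 * self.t / 1000.0) + 0.05 * rng.standard_normal(self.t.size)
        y = np.cos(2 * np.pi * 40 * (self.t - 4.0) / 1000.0) + 0.05 * rng.standard_normal(self.t.size)
        assert multitaper_coherence(x, y).at(40.0) > 0.99

    def test_independent_noise_within_null(self):
        """Coherence of independent white noise stays below the Monte-Carlo
        95th percentile of the K-taper null."""
        rng = np.random.default_rng(4)
        null = []
        for _ in range(40):
            c = multitaper_coherence(rng.standard_normal(2000),
                                     rng.standard_normal(2000))
            null.append(c.at(40.0))
        q95 = np.quantile(null, 0.95)
        fresh = multitaper_coherence(rng.standard_normal(2000),
                                     rng.standard_normal(2000)).at(40.0)
        assert fresh < max(q95, 0.2)
        assert np.median(null) < 0.1

    def test_symmetry_and_length_check(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal(1000), rng.standard_normal(1000)
        a = multitaper_coherence(x, y).coherence
        b = multitaper_coherence(y, x).coherence
        assert np.allclose(a, b, atol=1e-12)
        with pytest.raises(ValueError):
            multitaper_coherence(x, y[:-1])


class TestPhaseDifference:
    dt = 0.5
    t = np.arange(0, 3000, dt)

    def _feats(self, x):
        return instantaneous_features(morlet_transform(x, dt=self.dt))

    def test_identical_traces_zero(self):
        x = np.cos(2 * np.pi * 40 * self.t / 1000.0)
        pd = phase_difference(self._feats(x), self._feats(x), 0.99)
        assert pd.defined
        assert min(pd.value, 2 * np.pi - pd.value) < 1e-6

    def test_quarter_period_delay_gives_half_pi(self):
        x = np.cos(2 * np.pi * 40 * self.t / 1000.0)
        y = np.cos(2 * np.pi * 40 * (self.t - 6.25) / 1000.0)
        pd = phase_difference(self._feats(x), self._feats(y), 0.99)
        assert pd.value == pytest.approx(np.pi / 2, abs=0.05)
        assert pd.periods == pytest.approx(0.25, abs=0.01)

    def test_low_coherence_flagged_undefined(self):
        x = np.cos(2 * np.pi * 40 * self.t / 1000.0)
        pd = phase_difference(self._feats(x), self._feats(x), 0.5)
        assert not pd.defined and pd.value is None and np.isnan(pd.periods)


def _synthetic_density(peak_times, dt=0.5, T=1000.0, width=2.0, n=400):
    t = np.arange(0, T, dt)
    v = np.zeros_like(t)
    for p in peak_times:
        v += 200.0 * np.exp(-0.5 * ((t - p) / width) ** 2)
    return DensityTrace(v, dt, 0.0, n)


class TestPeriodMetrics:
    def test_reference_equal_to_test_gives_zero_deltas(self):
        d = _synthetic_density(np.arange(50, 950, 25.0))
        pm = period_metrics(d, reference=d, center_freq=40.0)
        assert np.allclose(pm.delta_peak_time, 0.0)
        assert np.allclose(pm.delta_peak_height, 0.0)
        assert np.allclose(pm.delta_rate, 0.0)

    def test_advanced_peaks_detected_as_negative_shift(self):
        base = np.arange(50, 950, 25.0)
        shifted = base.copy()
        shifted[10:] -= 2.0  # advance every peak from mid-trace on
        pm = period_metrics(_synthetic_density(shifted),
                            reference=_synthetic_density(base),
                            center_freq=40.0)
        d = np.round(pm.delta_peak_time, 1)
        assert set(d) <= {0.0, -2.0}
        assert np.count_nonzero(d == -2.0) >= 20  # the advanced peaks
        assert np.count_nonzero(d == 0.0) >= 5    # the untouched ones

    def test_flat_trace_raises(self):
        flat = DensityTrace(np.zeros(2000), 0.5, 0.0, 400)
        with pytest.raises(ValueError):
            period_metrics(flat, center_freq=40.0)


class TestCircularLinear:
    def test_cosine_dependence_gives_one(self):
        th = np.random.default_rng(6).uniform(0, 2 * np.pi, 300)
        rho, p = circular_linear_correlation(th, np.cos(th))
        assert rho == pytest.approx(1.0, abs=1e-9)
        assert p < 1e-10

    def test_phase_shift_invariance(self):
        th = np.random.default_rng(7).uniform(0, 2 * np.pi, 300)
        for phi0 in (0.7, 2.9, 5.1):
            rho, _ = circular_linear_correlation(th, np.cos(th - phi0))
            assert rho == pytest.approx(1.0, abs=1e-9)

    def test_independent_values_mostly_insignificant(self):
        rng = np.random.default_rng(8)
        ok = 0
        for _ in range(50):
            th = rng.uniform(0, 2 * np.pi, 1000)
            rho, p = circular_linear_correlation(th, rng.standard_normal(1000))
            ok += (rho < 0.1) and (p > 0.05)
        assert ok >= 45

    def test_constant_values(self):
        th = np.linspace(0, 2 * np.pi, 50)
        assert circular_linear_correlation(th, np.ones(50)) == (0.0, 1.0)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            circular_linear_correlation(np.arange(5.0), np.arange(5.0))


class TestPhaseConventionOnSimulation:
    def test_density_peaks_sit_at_phase_zero(self, ping_run):
        """Self-consistency of the phase convention: the mean wavelet phase
        at the peaks of the band-limited oscillation is 0 +- 0.1 rad on a
        PING simulation (the raw spiky volley maxima sit a fraction of a
        millisecond earlier than the narrow-band peak)."""
        from scipy.signal import find_peaks
        d = spike_density(ping_run.window(500, 1300), "c0E", t0=500, t1=1300)
        f = instantaneous_features(morlet_transform(d))
        f0 = f.mean_frequency
        x = d.values - d.values.mean()
        fr = np.fft.rfftfreq(x.size, d.dt / 1000.0)
        X = np.fft.rfft(x)
        X[(fr < f0 - 15) | (fr > f0 + 15)] = 0.0
        xb = np.fft.irfft(X, x.size)
        pk, _ = find_peaks(xb, distance=int(0.6 * 2000 / f0))
        ph = f.phase_at(d.t0 + pk[3:-3] * d.dt)
        mean = np.angle(np.exp(1j * ph).mean())
        assert abs(mean) < 0.1
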