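"""Transfer of noise-induced variability between circuits.

Each circuit's activity is summarized by three signal traces on the common
0.5 ms density grid: instantaneous oscillation frequency, power at the
oscillation frequency, and firing rate per oscillation period (held
constant within each period, then smoothed with a boxcar one mean period
wide).  These signals are not themselves oscillatory, so correlating them
between circuits quantifies how much of the receiver's noise-induced
variability is explained by the sender: the zero-lag Pearson correlation
rho per signal type (the 5 ms axonal delay is negligible against the 200 ms
input correlation time), cross-checked with a plug-in mutual information on
a 6 x 6 equal-width-bin histogram.

Controls: full time-shuffling of the receiver's traces destroys all
temporal structure; shuffling windows of one oscillation period preserves
within-period structure only.  Both should collapse rho to its null range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .analysis import (DensityTrace, InstantaneousFeatures, PeriodMetrics,
                       HIGH_COHERENCE, instantaneous_features,
                       morlet_transform, multitaper_coherence,
                       period_metrics, phase_difference, spike_density)
from .network import SpikeRaster

__all__ = [
    "CircuitSignals",
    "TransferResult",
    "extract_signals",
    "signal_correlation",
    "mutual_information",
    "shuffle_controls",
    "compute_transfer",
    "windowed_transfer",
]

SIGNAL_TYPES = ("frequency", "power", "rate")


def signal_correlation(sig1: np.ndarray, sig2: np.ndarray) -> float:
    """Zero-lag Pearson correlation of two equal-length signal traces.

    Returns NaN (flagged undefined) for zero-variance input.
    """
    x = np.asarray(sig1, dtype=np.float64)
    y = np.asarray(sig2, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("signals must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("signals must be finite")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero-variance signal: correlation undefined", stacklevel=2)
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def mutual_information(sig1: np.ndarray, sig2: np.ndarray, bins: int = 6) -> float:
    """Plug-in mutual information (bits) on an equal-width joint histogram.

    No bias correction is applied; the plug-in bias of independent signals
    is approximately ``(bins - 1)^2 / (2 n ln 2)`` bits and can be gauged
    with a shuffled baseline.  Degenerate (single-bin) signals give 0.
    """
    x = np.asarray(sig1, dtype=np.float64)
    y = np.asarray(sig2, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("signals must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log2(p[nz] / (px @ py)[nz])).sum())


def shuffle_controls(sig: np.ndarray, period_boundaries: np.ndarray,
                     seed: int | np.random.Generator = 0,
                     dt: float | None = None, t0: float = 0.0):
    """(time-shuffled, period-shuffled) copies of a signal trace.

    The time shuffle is a full sample permutation; the period shuffle
    permutes the blocks delimited by ``period_boundaries`` (sample indices,
    or times in ms when ``dt`` is given), preserving within-period structure
    only.  Requires at least 3 periods.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(sig, dtype=np.float64)
    b = np.asarray(period_boundaries, dtype=np.float64)
    if dt is not None:
        b = (b - t0) / dt
    idx = np.unique(np.clip(np.round(b).astype(int), 0, x.size))
    blocks = [x[a:c] for a, c in zip(idx[:-1], idx[1:]) if c > a]
    if len(blocks) < 3:
        raise ValueError("period shuffle requires at least 3 periods")
    time_shuffled = rng.permutation(x)
    order = rng.permutation(len(blocks))
    inner = np.concatenate([blocks[k] for k in order])
    period_shuffled = np.concatenate([x[:idx[0]], inner, x[idx[-1]:]])
    return time_shuffled, period_shuffled


@dataclass
class CircuitSignals:
    """Per-circuit signal traces on the density grid, plus their sources."""

    density: DensityTrace
    features: InstantaneousFeatures
    periods: PeriodMetrics
    frequency: np.ndarray
    power: np.ndarray
    rate: np.ndarray
    valid: np.ndarray

    @property
    def dt(self) -> float:
        return self.density.dt

    @property
    def t0(self) -> float:
        return self.density.t0

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"frequency": self.frequency, "power": self.power, "rate": self.rate}


def extract_signals(raster: SpikeRaster, label: str, t0: float,
                    t1: float | None = None) -> CircuitSignals:
    """Build the three transfer signals for one circuit.

    Frequency and power come from the wavelet ridge; the rate signal is the
    spike count per oscillation period, resampled as a step function onto
    the density grid and smoothed with a boxcar of one mean period.
    """
    t1 = raster.duration if t1 is None else t1
    dens = spike_density(raster.window(t0, t1), label, t0=t0, t1=t1)
    feats = instantaneous_features(morlet_transform(dens))
    pm = period_metrics(dens, center_freq=feats.mean_frequency)

    n = dens.values.size
    rate = np.zeros(n)
    edges = np.clip(((pm.peak_times - dens.t0) / dens.dt).astype(int), 0, n)
    if pm.spike_counts.size:
        # period-averaged spike density: spikes/s per neuron within each period
        widths = np.diff(edges) * dens.dt  # ms
        per_rate = 1000.0 * pm.spike_counts / (widths * dens.n_neurons)
        for i in range(per_rate.size):
            rate[edges[i]:edges[i + 1]] = per_rate[i]
        rate[:edges[0]] = per_rate[0]
        rate[edges[-1]:] = per_rate[-1]
    nwin = max(1, int(round(pm.mean_period / dens.dt)) | 1)
    rate = np.convolve(rate, np.ones(nwin) / nwin, mode="same")

    valid = feats.valid.copy()
    pad = int(nwin // 2)
    valid[:pad] = False
    if pad:
        valid[-pad:] = False
    freq = feats.frequency if feats.frequency is not None else np.full(n, np.nan)
    return CircuitSignals(dens, feats, pm, freq, feats.power, rate, valid)


@dataclass
class TransferResult:
    """Correlation/MI per signal type between a sender and a receiver."""

    rho: dict[str, float]
    mi: dict[str, float]
    rho_time_shuffled: dict[str, float]
    rho_period_shuffled: dict[str, float]
    coherence_at_sender: float
    sender_frequency: float
    receiver_frequency: float
    phase_diff: float | None           # rad, None below the coherence threshold
    window: tuple[float, float] = (np.nan, np.nan)

    @property
    def phase_diff_pi(self) -> float:
        return np.nan if self.phase_diff is None else self.phase_diff / np.pi


def compute_transfer(raster: SpikeRaster, sender: str = "c0E",
                     receiver: str = "c1E", t0: float = 500.0,
                     t1: float | None = None, control_seed: int = 0,
                     signals: tuple[CircuitSignals, CircuitSignals] | None = None
                     ) -> TransferResult:
    """End-to-end transfer measurement between two circuits of one run."""
    if signals is None:
        s1 = extract_signals(raster, sender, t0, t1)
        s2 = extract_signals(raster, receiver, t0, t1)
    else:
        s1, s2 = signals
    coh = multitaper_coherence(s1.density, s2.density)
    f1 = s1.features.mean_frequency
    c_at = coh.at(f1)
    pd = phase_difference(s1.features, s2.features, c_at)

    ok = s1.valid & s2.valid
    rho, mi, rho_t, rho_p = {}, {}, {}, {}
    d1, d2 = s1.as_dict(), s2.as_dict()
    for name in SIGNAL_TYPES:
        x, y = d1[name][ok], d2[name][ok]
        rho[name] = signal_correlation(x, y)
        mi[name] = mutual_information(x, y)
        tsh, psh = shuffle_controls(d2[name], s2.periods.peak_times,
                                    control_seed, s2.dt, s2.t0)
        rho_t[name] = signal_correlation(x, tsh[ok])
        rho_p[name] = signal_correlation(x, psh[ok])
    return TransferResult(rho, mi, rho_t, rho_p, c_at, f1,
                          s2.features.mean_frequency,
                          pd.value if pd.defined else None,
                          (s1.t0, s1.t0 + s1.dt * s1.density.values.size))


def windowed_transfer(raster: SpikeRaster, sender: str = "c0E",
                      receiver: str = "c1E", t0: float = 500.0,
                      t1: float | None = None, window: float = 1000.0,
                      step: float = 100.0,
                      exclusion: list[tuple[float, float]] = (),
                      control_seed: int = 0) -> list[TransferResult | None]:
    """Time-resolved transfer in overlapping windows (default 1000 ms spaced
    100 ms apart); windows overlapping an exclusion zone are masked (None).

    Raises if every window is excluded.
    """
    t1 = raster.duration if t1 is None else t1
    if t1 - t0 < window:
        raise ValueError("trace shorter than one window")
    starts = np.arange(t0, t1 - window + 1e-9, step)
    out: list[TransferResult | None] = []
    for ws in starts:
        we = ws + window
        if any(ws < ex1 and we > ex0 for ex0, ex1 in exclusion):
            out.append(None)
            continue
        out.append(compute_transfer(raster, sender, receiver, ws, we,
                                    control_seed))
    if all(r is None for r in out):
        raise ValueError("all windows excluded")
    return out
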