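"""Synthetic input generation: static drives, EPSC pulses, colored noise, sinusoids.

These inputs are the "data" of the study.  Every neuron receives a static
depolarizing current ``I_inj = I_0 + I_sigma`` where ``I_0`` is shared by all
neurons of one type in one circuit and ``I_sigma`` is per-neuron Gaussian
jitter (SD 0.1 uA/cm^2).  Information is injected either as EPSC-shaped
pulses delivered simultaneously to a fixed random 75% subset of the
pyramidal cells, or as a colored-noise current (Ornstein-Uhlenbeck process,
correlation time 200 ms, amplitude spectrum falling off approximately as 1/f
above the ~0.8 Hz corner) shared by all pyramidal cells of a circuit but
independent across circuits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "static_drive",
    "epsc_pulse",
    "colored_noise",
    "seed_screen",
    "sinusoidal_drive",
    "PulseSpec",
    "NoiseSpec",
    "SinusoidSpec",
    "Epoch",
    "StimulusSet",
    "DEFAULT_HETEROGENEITY_SD",
    "DEFAULT_NOISE_SD",
    "DEFAULT_PULSE_AMPLITUDE",
    "DEFAULT_PULSE_TAU",
]

#: SD of the per-neuron static-current jitter (uA/cm^2).
DEFAULT_HETEROGENEITY_SD = 0.1
#: SD of the shared colored-noise current (uA/cm^2); sized so that the
#: induced instantaneous-frequency excursions span a few Hz.
DEFAULT_NOISE_SD = 0.4
#: EPSC pulse peak amplitude (uA/cm^2) and decay constant (ms); AMPA-like.
DEFAULT_PULSE_AMPLITUDE = 2.0
DEFAULT_PULSE_TAU = 2.0
#: Fraction of pyramidal cells receiving pulses.
DEFAULT_PULSE_FRACTION = 0.75


def static_drive(I0: float, n: int, sd: float = DEFAULT_HETEROGENEITY_SD,
                 seed: int | np.random.Generator = 0) -> np.ndarray:
    """Per-neuron tonic currents ``I_0 + N(0, sd)``, fixed for a run."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    return I0 + sd * rng.standard_normal(n)


def epsc_pulse(t: np.ndarray, t_pulse: float, amplitude: float = DEFAULT_PULSE_AMPLITUDE,
               tau: float = DEFAULT_PULSE_TAU) -> np.ndarray:
    """AMPA-EPSC-shaped current: zero before ``t_pulse``, then instantaneous
    rise to ``amplitude`` with exponential decay of time constant ``tau`` (ms).
    """
    t = np.asarray(t, dtype=np.float64)
    out = np.zeros_like(t)
    on = t >= t_pulse
    out[on] = amplitude * np.exp(-(t[on] - t_pulse) / tau)
    return out


def colored_noise(duration: float, dt: float, tau_corr: float = 200.0,
                  sd: float = DEFAULT_NOISE_SD,
                  seed: int | np.random.Generator = 0) -> np.ndarray:
    """Shared colored-noise current trace on the ``dt`` grid.

    Stationary zero-mean Ornstein-Uhlenbeck process with exponential
    autocorrelation ``exp(-lag/tau_corr)`` and stationary SD ``sd``.  Its
    Lorentzian power spectrum gives an approximate 1/f amplitude fall-off
    above the corner frequency ``1/(2 pi tau_corr)``.
    """
    if duration < 5 * tau_corr:
        warnings.warn("duration < 5 * tau_corr: autocorrelation estimates "
                      "from this trace will be poor", stacklevel=2)
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    a = np.exp(-dt / tau_corr)
    b = sd * np.sqrt(1.0 - a * a)
    white = rng.standard_normal(n)
    x0 = sd * rng.standard_normal()  # stationary initial condition
    # x[k] = a x[k-1] + b w[k]  via an IIR filter with initial state
    zi = signal.lfiltic([b], [1.0, -a], [x0], [0.0])
    trace, _ = signal.lfilter([b], [1.0, -a], white, zi=zi)
    return trace


def seed_screen(candidate_seeds, duration: float = 3000.0, dt: float = 0.5,
                tau_corr: float = 200.0, max_corr: float = 0.05,
                n_required: int | None = None) -> list[int]:
    """Greedy screen of noise seeds for mutual decorrelation.

    Returns seeds whose pairwise colored-noise trace correlations are all
    below ``max_corr`` in magnitude (first-come greedy acceptance).  A trace
    of ``duration`` ms holds only about ``duration / (2 tau_corr)``
    independent samples, so unscreened pairs routinely correlate at the 0.3
    level and most candidates are rejected -- supply a generous pool.  With
    ``n_required`` the search stops as soon as that many seeds are accepted
    and raises (naming the best rejected pair) if the pool is exhausted
    first.
    """
    seeds = list(candidate_seeds)
    if len(seeds) < 2:
        return seeds
    accepted: list[int] = []
    traces: dict[int, np.ndarray] = {}
    best_pair, best_corr = None, np.inf
    for s in seeds:
        traces[s] = colored_noise(duration, dt, tau_corr, 1.0, s)
        ok = True
        for a in accepted:
            c = abs(np.corrcoef(traces[s], traces[a])[0, 1])
            if c >= max_corr:
                ok = False
                if c < best_corr:
                    best_corr, best_pair = c, (a, s)
                break
        if ok:
            accepted.append(s)
            if n_required is not None and len(accepted) >= n_required:
                return accepted
    need = 2 if n_required is None else n_required
    if len(accepted) < need:
        raise ValueError(
            f"only {len(accepted)} admissible seeds in a pool of "
            f"{len(seeds)}; best rejected pair {best_pair} had "
            f"|corr| = {best_corr:.3f}")
    return accepted


def sinusoidal_drive(t: np.ndarray, mean: float, amplitude: float,
                     f_d: float) -> np.ndarray:
    """Sinusoidal current ``mean + amplitude * sin(2 pi f_d t)`` (t in ms, f_d in Hz)."""
    if f_d <= 0:
        raise ValueError("drive frequency must be > 0")
    t = np.asarray(t, dtype=np.float64)
    return mean + amplitude * np.sin(2e-3 * np.pi * f_d * t)


# ---------------------------------------------------------------------------
# Stimulus specification containers
# ---------------------------------------------------------------------------

@dataclass
class PulseSpec:
    """EPSC pulses to a fixed random subset of one circuit's pyramidal cells."""
    circuit: int
    times: tuple[float, ...]
    amplitude: float = DEFAULT_PULSE_AMPLITUDE
    tau: float = DEFAULT_PULSE_TAU
    fraction: float = DEFAULT_PULSE_FRACTION


@dataclass
class NoiseSpec:
    """Shared colored-noise current to one circuit's pyramidal cells."""
    circuit: int
    seed: int
    sd: float = DEFAULT_NOISE_SD
    tau_corr: float = 200.0


@dataclass
class SinusoidSpec:
    """Sinusoidal drive added to one circuit's pyramidal cells."""
    circuit: int
    mean: float
    amplitude: float
    f_d: float


@dataclass
class Epoch:
    """Static-drive change: from ``start`` on, circuit ``circuit`` receives
    tonic drives ``I0_E`` / ``I0_I`` (uA/cm^2)."""
    start: float
    circuit: int
    I0_E: float
    I0_I: float


@dataclass
class StimulusSet:
    """All external inputs of one run; realized onto the integration grid by
    :class:`pingnet.network.Simulation`.

    Static drives per circuit live in the network spec; this container holds
    the optional time-varying components and the epoch schedule.
    """
    pulses: list[PulseSpec] = field(default_factory=list)
    noise: list[NoiseSpec] = field(default_factory=list)
    sinusoids: list[SinusoidSpec] = field(default_factory=list)
    epochs: list[Epoch] = field(default_factory=list)
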