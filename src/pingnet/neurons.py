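"""Single-compartment conductance-based neuron models and the fixed-step integrator.

Two cell types are implemented:

* fast-spiking interneurons -- the Wang-Buzsaki model (transient Na with
  instantaneous activation, delayed-rectifier K, leak; gating kinetics
  accelerated by a temperature-like factor ``phi``);
* regular-spiking pyramidal cells -- the Golomb-Amitai model (transient Na,
  persistent Na, delayed-rectifier K, a slow K adaptation current ``z`` with
  a 75 ms time constant, and leak).

Units follow the usual single-compartment convention: membrane potential in
mV, time in ms, capacitance in uF/cm^2, conductances in mS/cm^2, currents in
uA/cm^2.  All rate/steady-state constants are held in dataclasses so that
alternative parameter sets can be substituted without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Callable

import numpy as np
from numba import njit

__all__ = [
    "WangBuzsakiParams",
    "GolombAmitaiParams",
    "PopulationState",
    "interneuron_derivative",
    "pyramidal_derivative",
    "interneuron_steady_gates",
    "pyramidal_steady_gates",
    "rk4_step",
    "detect_spikes",
    "SPIKE_THRESHOLD_MV",
]

#: Spike detection thresholds (mV) per cell type.
SPIKE_THRESHOLD_MV = {"pyramidal": -20.0, "interneuron": 0.0}


@dataclass(frozen=True)
class WangBuzsakiParams:
    """Wang-Buzsaki fast-spiking interneuron parameters (canonical set)."""

    capacitance: float = 1.0      # uF/cm^2
    g_na: float = 35.0            # mS/cm^2
    e_na: float = 55.0            # mV
    g_k: float = 9.0
    e_k: float = -90.0
    g_leak: float = 0.1
    e_leak: float = -65.0
    phi: float = 5.0              # gating rate scale
    cell_type: str = "interneuron"

    def __post_init__(self) -> None:
        _check_positive_conductances(self)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.capacitance, self.g_na, self.e_na, self.g_k, self.e_k,
             self.g_leak, self.e_leak, self.phi],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class GolombAmitaiParams:
    """Golomb-Amitai regular-spiking pyramidal cell parameters (canonical set).

    Sigmoid gates use ``1 / (1 + exp(-(V - theta) / sigma))``; negative
    ``sigma`` yields inactivation-type curves.
    """

    capacitance: float = 1.0
    g_na: float = 24.0
    e_na: float = 55.0
    g_nap: float = 0.07
    g_kdr: float = 3.0
    e_k: float = -90.0
    g_z: float = 1.0              # slow K adaptation
    g_leak: float = 0.02
    e_leak: float = -70.0
    theta_m: float = -30.0
    sigma_m: float = 9.5
    theta_h: float = -53.0
    sigma_h: float = -7.0
    theta_n: float = -30.0
    sigma_n: float = 10.0
    theta_p: float = -40.0
    sigma_p: float = 5.0
    theta_z: float = -39.0
    sigma_z: float = 5.0
    tau_z: float = 75.0           # ms
    tau_h0: float = 0.37
    tau_h1: float = 2.78
    theta_th: float = -40.5
    sigma_th: float = -6.0
    tau_n0: float = 0.37
    tau_n1: float = 1.85
    theta_tn: float = -27.0
    sigma_tn: float = -15.0
    cell_type: str = "pyramidal"

    def __post_init__(self) -> None:
        _check_positive_conductances(self)

    def as_array(self) -> np.ndarray:
        vals = [getattr(self, f.name) for f in fields(self) if f.name != "cell_type"]
        return np.array(vals, dtype=np.float64)


def _check_positive_conductances(params) -> None:
    if params.capacitance <= 0:
        raise ValueError("capacitance must be > 0")
    for f in fields(params):
        if f.name.startswith("g_") and getattr(params, f.name) < 0:
            raise ValueError(f"{f.name} must be >= 0")


@dataclass
class PopulationState:
    """Dynamical variables of one neuron population at one instant.

    ``z`` (slow K gate) is only meaningful for pyramidal populations; for
    interneurons it is carried as zeros so both cell types share one layout.
    """

    V: np.ndarray
    h: np.ndarray
    n: np.ndarray
    z: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=np.float64)
        self.h = np.asarray(self.h, dtype=np.float64)
        self.n = np.asarray(self.n, dtype=np.float64)
        self.z = np.asarray(self.z, dtype=np.float64)
        sizes = {a.size for a in (self.V, self.h, self.n, self.z)}
        if len(sizes) != 1:
            raise ValueError("state vectors must have equal length")

    @property
    def size(self) -> int:
        return self.V.size

    def validate(self) -> None:
        for name in ("h", "n", "z"):
            g = getattr(self, name)
            if np.any((g < 0) | (g > 1)):
                raise ValueError(f"gating variable {name} outside [0, 1]")
        if not np.all(np.isfinite(self.V)):
            raise ValueError("non-finite membrane potential")

    def copy(self) -> "PopulationState":
        return PopulationState(self.V.copy(), self.h.copy(), self.n.copy(),
                               self.z.copy(), self.t)


# ---------------------------------------------------------------------------
# Scalar right-hand sides (numba, shared with the network kernel)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _wb_rhs(V, h, n, I, p):
    C, g_na, e_na, g_k, e_k, g_l, e_l, phi = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7])
    # Na activation: instantaneous, alpha/beta kinetics
    vm = V + 35.0
    if abs(vm) < 1e-9:
        a_m = 1.0  # limit of -0.1*vm/(exp(-0.1*vm)-1)
    else:
        a_m = -0.1 * vm / (np.exp(-0.1 * vm) - 1.0)
    b_m = 4.0 * np.exp(-(V + 60.0) / 18.0)
    m = a_m / (a_m + b_m)

    a_h = 0.07 * np.exp(-(V + 58.0) / 20.0)
    b_h = 1.0 / (np.exp(-0.1 * (V + 28.0)) + 1.0)
    vn = V + 34.0
    if abs(vn) < 1e-9:
        a_n = 0.1
    else:
        a_n = -0.01 * vn / (np.exp(-0.1 * vn) - 1.0)
    b_n = 0.125 * np.exp(-(V + 44.0) / 80.0)

    i_na = g_na * m * m * m * h * (V - e_na)
    i_k = g_k * n ** 4 * (V - e_k)
    i_l = g_l * (V - e_l)
    dV = (I - i_na - i_k - i_l) / C
    dh = phi * (a_h * (1.0 - h) - b_h * h)
    dn = phi * (a_n * (1.0 - n) - b_n * n)
    return dV, dh, dn


@njit(cache=True, inline="always")
def _sig(V, theta, sigma):
    return 1.0 / (1.0 + np.exp(-(V - theta) / sigma))


@njit(cache=True, inline="always")
def _ga_rhs(V, h, n, z, I, p):
    C = p[0]
    g_na, e_na, g_nap, g_kdr, e_k, g_z, g_l, e_l = (
        p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8])
    theta_m, sigma_m = p[9], p[10]
    theta_h, sigma_h = p[11], p[12]
    theta_n, sigma_n = p[13], p[14]
    theta_p, sigma_p = p[15], p[16]
    theta_z, sigma_z, tau_z = p[17], p[18], p[19]
    tau_h0, tau_h1, theta_th, sigma_th = p[20], p[21], p[22], p[23]
    tau_n0, tau_n1, theta_tn, sigma_tn = p[24], p[25], p[26], p[27]

    m = _sig(V, theta_m, sigma_m)
    p_gate = _sig(V, theta_p, sigma_p)
    i_na = g_na * m * m * m * h * (V - e_na)
    i_nap = g_nap * p_gate * (V - e_na)
    i_kdr = g_kdr * n ** 4 * (V - e_k)
    i_z = g_z * z * (V - e_k)
    i_l = g_l * (V - e_l)
    dV = (I - i_na - i_nap - i_kdr - i_z - i_l) / C

    tau_h = tau_h0 + tau_h1 * _sig(V, theta_th, sigma_th)
    tau_n = tau_n0 + tau_n1 * _sig(V, theta_tn, sigma_tn)
    dh = (_sig(V, theta_h, sigma_h) - h) / tau_h
    dn = (_sig(V, theta_n, sigma_n) - n) / tau_n
    dz = (_sig(V, theta_z, sigma_z) - z) / tau_z
    return dV, dh, dn, dz


@njit(cache=True)
def _wb_rhs_vec(V, h, n, I, p, dV, dh, dn):
    for i in range(V.size):
        dV[i], dh[i], dn[i] = _wb_rhs(V[i], h[i], n[i], I[i], p)


@njit(cache=True)
def _ga_rhs_vec(V, h, n, z, I, p, dV, dh, dn, dz):
    for i in range(V.size):
        dV[i], dh[i], dn[i], dz[i] = _ga_rhs(V[i], h[i], n[i], z[i], I[i], p)


# ---------------------------------------------------------------------------
# Public derivative / steady-state functions
# ---------------------------------------------------------------------------

def _validate_deriv_inputs(state: PopulationState, I_total: np.ndarray) -> np.ndarray:
    I_total = np.broadcast_to(np.asarray(I_total, dtype=np.float64),
                              state.V.shape).copy()
    if not (np.all(np.isfinite(state.V)) and np.all(np.isfinite(I_total))):
        raise FloatingPointError("non-finite state or input current")
    return I_total


def interneuron_derivative(
    state: PopulationState,
    I_total: np.ndarray | float,
    params: WangBuzsakiParams | None = None,
) -> PopulationState:
    """Time derivative of a Wang-Buzsaki interneuron population.

    Pure function of ``(state, I_total)``; returns a `PopulationState` whose
    fields hold d/dt of the corresponding variables (``z`` slot is zero).
    """
    params = params or WangBuzsakiParams()
    I_total = _validate_deriv_inputs(state, I_total)
    p = params.as_array()
    dV = np.empty_like(state.V)
    dh = np.empty_like(state.h)
    dn = np.empty_like(state.n)
    _wb_rhs_vec(state.V, state.h, state.n, I_total, p, dV, dh, dn)
    return PopulationState(dV, dh, dn, np.zeros_like(state.z), state.t)


def pyramidal_derivative(
    state: PopulationState,
    I_total: np.ndarray | float,
    params: GolombAmitaiParams | None = None,
) -> PopulationState:
    """Time derivative of a Golomb-Amitai pyramidal population."""
    params = params or GolombAmitaiParams()
    I_total = _validate_deriv_inputs(state, I_total)
    p = params.as_array()
    dV = np.empty_like(state.V)
    dh = np.empty_like(state.h)
    dn = np.empty_like(state.n)
    dz = np.empty_like(state.z)
    _ga_rhs_vec(state.V, state.h, state.n, state.z, I_total, p, dV, dh, dn, dz)
    return PopulationState(dV, dh, dn, dz, state.t)


def interneuron_steady_gates(V, params: WangBuzsakiParams | None = None):
    """Voltage-clamped steady-state values (h, n) of the interneuron gates."""
    V = np.asarray(V, dtype=np.float64)
    a_h = 0.07 * np.exp(-(V + 58.0) / 20.0)
    b_h = 1.0 / (np.exp(-0.1 * (V + 28.0)) + 1.0)
    vn = V + 34.0
    a_n = np.where(np.abs(vn) < 1e-9, 0.1,
                   -0.01 * vn / np.expm1(-0.1 * vn))
    b_n = 0.125 * np.exp(-(V + 44.0) / 80.0)
    return a_h / (a_h + b_h), a_n / (a_n + b_n)


def pyramidal_steady_gates(V, params: GolombAmitaiParams | None = None):
    """Voltage-clamped steady-state values (h, n, z) of the pyramidal gates."""
    params = params or GolombAmitaiParams()
    V = np.asarray(V, dtype=np.float64)

    def sig(theta, sigma):
        return 1.0 / (1.0 + np.exp(-(V - theta) / sigma))

    return (sig(params.theta_h, params.sigma_h),
            sig(params.theta_n, params.sigma_n),
            sig(params.theta_z, params.sigma_z))


def rk4_step(
    state: PopulationState,
    derivative_fn: Callable[[PopulationState], PopulationState],
    dt: float,
) -> PopulationState:
    """One classical 4th-order Runge-Kutta update of a population state.

    ``derivative_fn`` maps a `PopulationState` to its time derivative; applied
    currents are expected to be baked into the closure (held constant over the
    step).  Raises `FloatingPointError` naming the first offending neuron if
    the update produces a non-finite voltage.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")

    def shifted(k: PopulationState, frac: float) -> PopulationState:
        return PopulationState(
            state.V + frac * dt * k.V,
            state.h + frac * dt * k.h,
            state.n + frac * dt * k.n,
            state.z + frac * dt * k.z,
            state.t + frac * dt,
        )

    k1 = derivative_fn(state)
    k2 = derivative_fn(shifted(k1, 0.5))
    k3 = derivative_fn(shifted(k2, 0.5))
    k4 = derivative_fn(shifted(k3, 1.0))
    out = PopulationState(
        state.V + dt / 6.0 * (k1.V + 2 * k2.V + 2 * k3.V + k4.V),
        state.h + dt / 6.0 * (k1.h + 2 * k2.h + 2 * k3.h + k4.h),
        state.n + dt / 6.0 * (k1.n + 2 * k2.n + 2 * k3.n + k4.n),
        state.z + dt / 6.0 * (k1.z + 2 * k2.z + 2 * k3.z + k4.z),
        state.t + dt,
    )
    if not np.all(np.isfinite(out.V)):
        bad = int(np.flatnonzero(~np.isfinite(out.V))[0])
        raise FloatingPointError(
            f"numerical blow-up at t={out.t:.3f} ms, neuron {bad}")
    return out


def detect_spikes(
    V_trace: np.ndarray,
    dt: float,
    cell_type: str = "pyramidal",
    threshold: float | None = None,
    t0: float = 0.0,
) -> np.ndarray:
    """Spike times (ms) from upward threshold crossings of a voltage trace.

    A spike is registered at the first sample at or above threshold whose
    predecessor was below it (-20 mV for pyramidal cells, 0 mV for
    interneurons).  An empty trace yields an empty result.
    """
    V_trace = np.asarray(V_trace, dtype=np.float64)
    if V_trace.size < 2:
        return np.empty(0)
    if threshold is None:
        threshold = SPIKE_THRESHOLD_MV[cell_type]
    up = (V_trace[:-1] < threshold) & (V_trace[1:] >= threshold)
    return t0 + dt * (np.flatnonzero(up) + 1).astype(np.float64)
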