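"""Circuit and network assembly: connectivity, synapse kinetics, simulation.

A circuit is 400 pyramidal cells plus 100 fast-spiking interneurons with
random intra-circuit connectivity (Bernoulli per ordered pair, no
self-synapses) and 1 ms synaptic delays.  Circuits are coupled by purely
excitatory projections onto both cell types of the target with a 5 ms
axonal delay.  Synapses use instantaneous-rise / single-exponential-decay
conductance kinetics (AMPA tau = 2 ms, E_rev = 0 mV; GABA_A tau = 8 ms,
E_rev = -75 mV): each presynaptic spike, after its delay, increments the
summed conductance of the target by the unitary strength.

Unitary strengths are quoted in uS/cm^2 as in the connection table and
converted to mS/cm^2 internally; projections are conveniently parameterized
by the *total* conductance per target neuron (probability x source count x
unitary strength).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel
from .neurons import (GolombAmitaiParams, WangBuzsakiParams,
                      SPIKE_THRESHOLD_MV, interneuron_steady_gates,
                      pyramidal_steady_gates)
from .stimuli import StimulusSet, colored_noise, epsc_pulse, sinusoidal_drive

__all__ = [
    "CircuitSpec",
    "ProjectionSpec",
    "NetworkSpec",
    "ConnectivityGraph",
    "SynapseBank",
    "build_connectivity",
    "synaptic_current",
    "Simulation",
    "run_simulation",
    "SpikeRaster",
]

#: Default intra-circuit connection table: probability (fraction) and
#: unitary strength (uS/cm^2) per (pre, post) cell-type pair.
INTRA_TABLE = {
    ("E", "E"): (0.10, 1.2),
    ("E", "I"): (0.30, 1.0),
    ("I", "I"): (0.20, 12.0),
    ("I", "E"): (0.60, 5.0),
}

E_AMPA = 0.0     # mV
E_GABA = -75.0   # mV
TAU_AMPA = 2.0   # ms
TAU_GABA = 8.0   # ms


@dataclass
class CircuitSpec:
    """One local circuit: population sizes, drives and intra-circuit wiring."""

    I0_E: float = 1.0
    I0_I: float = 0.2
    n_pyramidal: int = 400
    n_interneuron: int = 100
    connection_table: dict = field(default_factory=lambda: dict(INTRA_TABLE))
    delay_ms: float = 1.0
    heterogeneity_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_pyramidal <= 0 or self.n_interneuron <= 0:
            raise ValueError("population sizes must be > 0")
        # accept "E->E" style keys (config files) alongside ("E", "E") tuples
        self.connection_table = {
            (tuple(k.split("->")) if isinstance(k, str) else tuple(k)): tuple(v)
            for k, v in self.connection_table.items()}
        for key, (p, g) in self.connection_table.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"connection probability {key} outside [0, 1]")
            if g < 0:
                raise ValueError(f"unitary strength {key} must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_pyramidal + self.n_interneuron


@dataclass
class ProjectionSpec:
    """Purely excitatory inter-circuit projection onto E and I cells."""

    source: int
    target: int
    g_ee: float = 11.0           # unitary, uS/cm^2 (table range 0-15)
    g_ei: float = 5.5            # unitary, uS/cm^2 (table range 0-7.5)
    p_ee: float = 0.05
    p_ei: float = 0.10
    delay_ms: float = 5.0

    def __post_init__(self) -> None:
        if self.delay_ms <= 0:
            raise ValueError("projection delay must be > 0")
        for p in (self.p_ee, self.p_ei):
            if not 0.0 <= p <= 1.0:
                raise ValueError("projection probability outside [0, 1]")

    def total_conductance(self, n_source_E: int = 400) -> tuple[float, float]:
        """(E->E, E->I) total conductance per target neuron in mS/cm^2."""
        return (self.p_ee * n_source_E * self.g_ee * 1e-3,
                self.p_ei * n_source_E * self.g_ei * 1e-3)

    @classmethod
    def from_total_conductance(cls, source: int, target: int,
                               total_ee: float, total_ei: float | None = None,
                               n_source_E: int = 400, **kw) -> "ProjectionSpec":
        """Build a projection from total conductances (mS/cm^2 per target)."""
        if total_ei is None:
            total_ei = total_ee
        spec = cls(source, target, **kw)
        return replace(spec,
                       g_ee=total_ee * 1e3 / (spec.p_ee * n_source_E),
                       g_ei=total_ei * 1e3 / (spec.p_ei * n_source_E))


@dataclass
class NetworkSpec:
    circuits: list[CircuitSpec]
    projections: list[ProjectionSpec] = field(default_factory=list)
    pyramidal_params: GolombAmitaiParams = field(default_factory=GolombAmitaiParams)
    interneuron_params: WangBuzsakiParams = field(default_factory=WangBuzsakiParams)

    def __post_init__(self) -> None:
        for proj in self.projections:
            for c in (proj.source, proj.target):
                if not 0 <= c < len(self.circuits):
                    raise ValueError(f"projection references unknown circuit {c}")

    @property
    def n_neurons(self) -> int:
        return sum(c.n_total for c in self.circuits)

    def population_slices(self) -> dict[str, slice]:
        """Flat-index slices per population, keys like ``"c0E"``, ``"c0I"``."""
        out, ofs = {}, 0
        for ci, c in enumerate(self.circuits):
            out[f"c{ci}E"] = slice(ofs, ofs + c.n_pyramidal)
            out[f"c{ci}I"] = slice(ofs + c.n_pyramidal, ofs + c.n_total)
            ofs += c.n_total
        return out


@dataclass
class ConnectivityGraph:
    """Directed synapse list over the flat neuron index space."""

    pre: np.ndarray        # int32
    post: np.ndarray       # int32
    weight: np.ndarray     # mS/cm^2 (unitary)
    delay_ms: np.ndarray
    receptor: np.ndarray   # 0 = AMPA, 1 = GABA
    n_neurons: int

    @property
    def n_synapses(self) -> int:
        return self.pre.size

    def total_conductance_per_target(self, targets: slice,
                                     receptor: int | None = None,
                                     pre_range: slice | None = None) -> np.ndarray:
        """Summed afferent unitary conductance for each neuron in ``targets``."""
        sel = (self.post >= targets.start) & (self.post < targets.stop)
        if receptor is not None:
            sel &= self.receptor == receptor
        if pre_range is not None:
            sel &= (self.pre >= pre_range.start) & (self.pre < pre_range.stop)
        out = np.zeros(targets.stop - targets.start)
        np.add.at(out, self.post[sel] - targets.start, self.weight[sel])
        return out

    def csr(self) -> tuple[np.ndarray, ...]:
        order = np.argsort(self.pre, kind="stable")
        indptr = np.zeros(self.n_neurons + 1, dtype=np.int64)
        np.add.at(indptr, self.pre + 1, 1)
        np.cumsum(indptr, out=indptr)
        return (indptr, self.post[order].astype(np.int32),
                self.weight[order].astype(np.float64),
                self.delay_ms[order], self.receptor[order].astype(np.int8))


@dataclass
class SynapseBank:
    """Summed synaptic conductance state per neuron and receptor class."""

    g: np.ndarray                      # (n_neurons, 2) mS/cm^2
    tau: tuple[float, float] = (TAU_AMPA, TAU_GABA)
    e_rev: tuple[float, float] = (E_AMPA, E_GABA)


def _bernoulli_block(rng, pre_idx, post_idx, p):
    """Index pairs of an independent-Bernoulli random block, no self-pairs."""
    if p <= 0 or pre_idx.size == 0 or post_idx.size == 0:
        return (np.empty(0, np.int32),) * 2
    mask = rng.random((pre_idx.size, post_idx.size)) < p
    shared = np.intersect1d(pre_idx, post_idx)
    if shared.size:
        ii = np.searchsorted(pre_idx, shared)
        jj = np.searchsorted(post_idx, shared)
        mask[ii, jj] = False
    rows, cols = np.nonzero(mask)
    return pre_idx[rows].astype(np.int32), post_idx[cols].astype(np.int32)


def build_connectivity(spec: NetworkSpec, seed: int | np.random.Generator) -> ConnectivityGraph:
    """Draw the random synapse list of a network (Bernoulli per ordered pair).

    Reproducible for a fixed seed; at most one synapse per ordered neuron
    pair per connection class; self-synapses excluded.
    """
    rng = np.random.default_rng(seed)
    slices = spec.population_slices()
    pres, posts, ws, ds, recs = [], [], [], [], []

    def add(pre_idx, post_idx, p, g_us, delay, pre_type):
        a, b = _bernoulli_block(rng, pre_idx, post_idx, p)
        if a.size:
            pres.append(a)
            posts.append(b)
            ws.append(np.full(a.size, g_us * 1e-3))
            ds.append(np.full(a.size, delay))
            recs.append(np.full(
                a.size, _kernel.GABA if pre_type == "I" else _kernel.AMPA,
                dtype=np.int8))

    for ci, c in enumerate(spec.circuits):
        idx = {"E": np.arange(slices[f"c{ci}E"].start, slices[f"c{ci}E"].stop),
               "I": np.arange(slices[f"c{ci}I"].start, slices[f"c{ci}I"].stop)}
        for (src, tgt), (p, g) in c.connection_table.items():
            add(idx[src], idx[tgt], p, g, c.delay_ms, src)

    for proj in spec.projections:
        src_E = np.arange(slices[f"c{proj.source}E"].start,
                          slices[f"c{proj.source}E"].stop)
        tgt_E = np.arange(slices[f"c{proj.target}E"].start,
                          slices[f"c{proj.target}E"].stop)
        tgt_I = np.arange(slices[f"c{proj.target}I"].start,
                          slices[f"c{proj.target}I"].stop)
        add(src_E, tgt_E, proj.p_ee, proj.g_ee, proj.delay_ms, "E")
        add(src_E, tgt_I, proj.p_ei, proj.g_ei, proj.delay_ms, "E")

    cat = lambda parts, dtype: (np.concatenate(parts).astype(dtype) if parts
                                else np.empty(0, dtype))
    return ConnectivityGraph(cat(pres, np.int32), cat(posts, np.int32),
                             cat(ws, np.float64), cat(ds, np.float64),
                             cat(recs, np.int8), spec.n_neurons)


def synaptic_current(bank: SynapseBank, V_post: np.ndarray) -> np.ndarray:
    """Total synaptic current per neuron, ``sum_r g_r * (E_r - V)`` (uA/cm^2)."""
    V_post = np.asarray(V_post, dtype=np.float64)
    if V_post.shape[0] != bank.g.shape[0]:
        raise ValueError("voltage vector does not match synapse bank size")
    return (bank.g[:, 0] * (bank.e_rev[0] - V_post)
            + bank.g[:, 1] * (bank.e_rev[1] - V_post))


@dataclass
class SpikeRaster:
    """Spike times per neuron for a whole network run."""

    times: np.ndarray          # ms, ascending within a run
    ids: np.ndarray            # flat neuron indices
    populations: dict[str, slice]
    duration: float            # ms
    dt: float
    seed: int | None = None

    def population(self, label: str) -> "SpikeRaster":
        sl = self.populations[label]
        sel = (self.ids >= sl.start) & (self.ids < sl.stop)
        return SpikeRaster(self.times[sel], self.ids[sel], {label: sl},
                           self.duration, self.dt, self.seed)

    def window(self, t0: float, t1: float) -> "SpikeRaster":
        sel = (self.times >= t0) & (self.times < t1)
        return SpikeRaster(self.times[sel], self.ids[sel], self.populations,
                           self.duration, self.dt, self.seed)

    def n_in_population(self, label: str) -> int:
        sl = self.populations[label]
        return sl.stop - sl.start

    def rate(self, label: str, t0: float = 0.0, t1: float | None = None) -> float:
        """Mean firing rate (spikes/s per neuron) of one population."""
        t1 = self.duration if t1 is None else t1
        pop = self.population(label).window(t0, t1)
        return 1e3 * pop.times.size / ((t1 - t0) * self.n_in_population(label))


class Simulation:
    """Stateful network simulation supporting snapshots and branching.

    All randomness (connectivity, initial conditions, static-drive jitter,
    pulse target subsets) derives from independent named streams spawned
    from ``seed``, so adding e.g. a pulse never perturbs the other draws;
    colored-noise currents use the explicit per-circuit seeds of the
    stimulus set (they are screened for decorrelation separately).
    Input traces are realized up-front for ``duration`` ms, which is why the
    total horizon is fixed at construction.
    """

    def __init__(self, spec: NetworkSpec, stimuli: StimulusSet | None = None,
                 duration: float = 1000.0, dt: float = 0.05, seed: int = 0,
                 record: tuple[int, ...] = (), max_rate_hz: float = 200.0):
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.spec = spec
        self.stimuli = stimuli or StimulusSet()
        self.duration = float(duration)
        self.dt = float(dt)
        self.seed = int(seed)
        self.n_steps_total = int(round(duration / dt))
        self.populations = spec.population_slices()
        N = spec.n_neurons

        ss = {name: np.random.SeedSequence((seed, k)) for k, name in
              enumerate(["connectivity", "init", "hetero", "pulse_targets"])}

        self.graph = build_connectivity(spec, np.random.default_rng(ss["connectivity"]))
        indptr, post, w, delay_ms, rec = self.graph.csr()
        delay_steps = np.round(delay_ms / dt).astype(np.int64)
        if np.any(np.abs(delay_steps * dt - delay_ms) > 1e-9):
            raise ValueError("synaptic delays must be multiples of dt")
        self._csr = (indptr, post, w, delay_steps, rec)
        D = int(delay_steps.max(initial=0)) + 2

        self.cell_type = np.empty(N, dtype=np.int8)
        for label, sl in self.populations.items():
            self.cell_type[sl] = 0 if label.endswith("E") else 1
        self.thresholds = np.where(self.cell_type == 0,
                                   SPIKE_THRESHOLD_MV["pyramidal"],
                                   SPIKE_THRESHOLD_MV["interneuron"])

        # static drives with per-neuron jitter
        rng_h = np.random.default_rng(ss["hetero"])
        self.I_static = np.empty(N)
        for ci, c in enumerate(spec.circuits):
            for pop, I0 in (("E", c.I0_E), ("I", c.I0_I)):
                sl = self.populations[f"c{ci}{pop}"]
                self.I_static[sl] = I0 + c.heterogeneity_sd * rng_h.standard_normal(
                    sl.stop - sl.start)

        self._build_drive_traces()
        self._build_pulse_channels(np.random.default_rng(ss["pulse_targets"]))

        # initial state: V uniform in [-70, -50] mV, gates at steady state
        rng_i = np.random.default_rng(ss["init"])
        self.V = rng_i.uniform(-70.0, -50.0, N)
        self.h = np.empty(N)
        self.n = np.empty(N)
        self.z = np.zeros(N)
        pyr = self.cell_type == 0
        hh, nn, zz = pyramidal_steady_gates(self.V[pyr])
        self.h[pyr], self.n[pyr], self.z[pyr] = hh, nn, zz
        hh, nn = interneuron_steady_gates(self.V[~pyr])
        self.h[~pyr], self.n[~pyr] = hh, nn

        self.g_syn = np.zeros((N, 2))
        self.ring = np.zeros((D, N, 2))
        self.step = 0

        cap = int(N * duration * 1e-3 * max_rate_hz) + 1024
        self._spike_steps = np.zeros(cap, dtype=np.int64)
        self._spike_ids = np.zeros(cap, dtype=np.int32)
        self.n_spikes = 0

        self.record_idx = np.asarray(record, dtype=np.int64)
        self.v_rec = np.zeros((len(record), self.n_steps_total), dtype=np.float64)

        self._pyr_p = spec.pyramidal_params.as_array()
        self._int_p = spec.interneuron_params.as_array()

    # -- input realization -------------------------------------------------

    def _grid(self) -> np.ndarray:
        return self.dt * np.arange(self.n_steps_total + 1)

    def _ensure_row(self, table: dict, arr_name: str, key) -> int:
        if key not in table:
            arr = getattr(self, arr_name)
            table[key] = arr.shape[0]
            setattr(self, arr_name,
                    np.vstack([arr, np.zeros((1, self.n_steps_total + 1))]))
        return table[key]

    def _build_drive_traces(self) -> None:
        self.drive_traces = np.zeros((0, self.n_steps_total + 1))
        self.drive_id = np.full(self.spec.n_neurons, -1, dtype=np.int32)
        rows: dict[tuple[int, str], int] = {}
        t = self._grid()

        for ns in self.stimuli.noise:
            r = self._ensure_row(rows, "drive_traces", (ns.circuit, "E"))
            self.drive_traces[r] += colored_noise(
                (self.n_steps_total + 1) * self.dt, self.dt, ns.tau_corr,
                ns.sd, ns.seed)[: self.n_steps_total + 1]
        for sn in self.stimuli.sinusoids:
            r = self._ensure_row(rows, "drive_traces", (sn.circuit, "E"))
            self.drive_traces[r] += sinusoidal_drive(t, sn.mean, sn.amplitude, sn.f_d)
        # epochs define absolute tonic levels from their start until the
        # next epoch of the same circuit (not cumulative increments)
        by_circuit: dict[int, list] = {}
        for ep in self.stimuli.epochs:
            by_circuit.setdefault(ep.circuit, []).append(ep)
        for ci, eps in by_circuit.items():
            eps = sorted(eps, key=lambda e: e.start)
            c = self.spec.circuits[ci]
            starts = [e.start for e in eps] + [np.inf]
            for k, ep in enumerate(eps):
                sel = (t >= ep.start) & (t < starts[k + 1])
                for pop, new, base in (("E", ep.I0_E, c.I0_E),
                                       ("I", ep.I0_I, c.I0_I)):
                    if new == base:
                        continue
                    r = self._ensure_row(rows, "drive_traces", (ci, pop))
                    self.drive_traces[r, sel] += new - base

        for (ci, pop), r in rows.items():
            self.drive_id[self.populations[f"c{ci}{pop}"]] = r

    def _build_pulse_channels(self, rng: np.random.Generator) -> None:
        self.pulse_traces = np.zeros((0, self.n_steps_total + 1))
        self.pulse_id = np.full(self.spec.n_neurons, -1, dtype=np.int32)
        self._pulse_rows: dict[int, int] = {}
        self._pulse_rng = rng
        for ps in self.stimuli.pulses:
            for tp in ps.times:
                self.add_pulse(ps.circuit, tp, ps.amplitude, ps.tau, ps.fraction)

    def add_pulse(self, circuit: int, t_pulse: float,
                  amplitude: float | None = None, tau: float | None = None,
                  fraction: float = 0.75) -> None:
        """Add one EPSC pulse to the fixed random subset of ``circuit``'s pyramids.

        The target subset is drawn once per circuit (first call) and reused,
        so paired pulse / no-pulse branches share identical targets.
        """
        from .stimuli import DEFAULT_PULSE_AMPLITUDE, DEFAULT_PULSE_TAU
        amplitude = DEFAULT_PULSE_AMPLITUDE if amplitude is None else amplitude
        tau = DEFAULT_PULSE_TAU if tau is None else tau
        if circuit not in self._pulse_rows:
            r = self._ensure_row(self._pulse_rows, "pulse_traces", circuit)
            sl = self.populations[f"c{circuit}E"]
            n_e = sl.stop - sl.start
            targets = self._pulse_rng.choice(n_e, size=int(round(fraction * n_e)),
                                             replace=False)
            self.pulse_id[sl.start + targets] = r
        r = self._pulse_rows[circuit]
        self.pulse_traces[r] += epsc_pulse(self._grid(), t_pulse, amplitude, tau)

    # -- execution ---------------------------------------------------------

    @property
    def t(self) -> float:
        return self.step * self.dt

    def run_until(self, t_ms: float) -> None:
        """Advance the network to time ``t_ms`` (must be within the horizon)."""
        target = int(round(t_ms / self.dt))
        if target > self.n_steps_total:
            raise ValueError("t_ms beyond the simulation horizon")
        n = target - self.step
        if n <= 0:
            return
        indptr, post, w, delay, rec = self._csr
        v_rec = (self.v_rec[:, self.step:target] if self.record_idx.size
                 else np.zeros((0, 0)))
        n_sp, status, bad_j, bad_step = _kernel.simulate(
            n, self.step, self.dt,
            self.cell_type, self._pyr_p, self._int_p,
            self.I_static, self.drive_id, self.drive_traces,
            self.pulse_id, self.pulse_traces,
            indptr, post, w, delay, rec,
            TAU_AMPA, TAU_GABA, E_AMPA, E_GABA,
            self.V, self.h, self.n, self.z, self.g_syn, self.ring,
            self.thresholds,
            self._spike_steps, self._spike_ids, self.n_spikes,
            self.record_idx, v_rec)
        self.n_spikes = n_sp
        self.step = target
        if status == 1:
            raise FloatingPointError(
                f"numerical blow-up: neuron {bad_j} at t = {bad_step * self.dt:.2f} ms")
        if status == 2:
            raise RuntimeError("spike capacity exceeded; raise max_rate_hz")

    def snapshot(self) -> dict:
        """Copy of the full dynamical state (for paired-branch protocols)."""
        return {
            "step": self.step, "n_spikes": self.n_spikes,
            "V": self.V.copy(), "h": self.h.copy(), "n": self.n.copy(),
            "z": self.z.copy(), "g_syn": self.g_syn.copy(),
            "ring": self.ring.copy(),
            "pulse_traces": self.pulse_traces.copy(),
            "pulse_id": self.pulse_id.copy(),
            "pulse_rows": dict(self._pulse_rows),
        }

    def restore(self, snap: dict) -> None:
        self.step = snap["step"]
        self.n_spikes = snap["n_spikes"]
        self.V[:] = snap["V"]
        self.h[:] = snap["h"]
        self.n[:] = snap["n"]
        self.z[:] = snap["z"]
        self.g_syn[:] = snap["g_syn"]
        self.ring[:] = snap["ring"]
        self.pulse_traces = snap["pulse_traces"].copy()
        self.pulse_id = snap["pulse_id"].copy()
        self._pulse_rows = dict(snap["pulse_rows"])

    def raster(self) -> SpikeRaster:
        sel = slice(0, self.n_spikes)
        return SpikeRaster(self._spike_steps[sel] * self.dt,
                           self._spike_ids[sel].copy(),
                           self.populations, self.t, self.dt, self.seed)


def run_simulation(spec: NetworkSpec, stimuli: StimulusSet | None = None,
                   duration: float = 1500.0, dt: float = 0.05, seed: int = 0,
                   record: tuple[int, ...] = ()) -> SpikeRaster:
    """One-shot network run returning the spike raster (deterministic per seed)."""
    sim = Simulation(spec, stimuli, duration, dt, seed, record)
    sim.run_until(duration)
    raster = sim.raster()
    if record:
        raster.v_rec = sim.v_rec
        raster.record_idx = sim.record_idx
    return raster
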