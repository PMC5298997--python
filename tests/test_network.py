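"""Network assembly and simulation: connectivity statistics, synapse
kinetics, delay contracts, determinism and PING phenomenology."""

import numpy as np
import pytest

from pingnet import _kernel
from pingnet.experiments import _ei_lag, reference_circuit, reference_pyramidal_params
from pingnet.analysis import (instantaneous_features, morlet_transform,
                              pairwise_phase_consistency, spike_density,
                              spike_phases)
from pingnet.network import (CircuitSpec, NetworkSpec, ProjectionSpec,
                             Simulation, SynapseBank, build_connectivity,
                             run_simulation, synaptic_current, TAU_AMPA)
from pingnet.stimuli import StimulusSet


def _zero_table():
    return {k: (0.0, 0.0) for k in
            [("E", "E"), ("E", "I"), ("I", "I"), ("I", "E")]}


class TestConnectivity:
    def test_intra_circuit_in_degrees_match_probabilities(self):
        spec = NetworkSpec([CircuitSpec(I0_E=1.0, I0_I=0.3)])
        g = build_connectivity(spec, seed=1)
        ee = g.total_conductance_per_target(slice(0, 400), receptor=0,
                                            pre_range=slice(0, 400))
        # E->E: p=0.10, 400 sources, unitary 1.2 uS -> mean in-degree 40
        indeg = ee / 1.2e-3
        assert abs(indeg.mean() - 40.0 * 399 / 400) < 2.0
        ie = g.total_conductance_per_target(slice(0, 400), receptor=1)
        # I->E: p=0.60, 100 interneurons, unitary 5.0 uS -> mean in-degree 60
        assert abs((ie / 5.0e-3).mean() - 60.0) < 3.0

    def test_zero_probability_yields_empty_list(self):
        spec = NetworkSpec([CircuitSpec(I0_E=1.0, I0_I=0.3,
                                        connection_table=_zero_table())])
        assert build_connectivity(spec, seed=0).n_synapses == 0

    def test_no_self_synapses_and_unique_pairs(self):
        spec = NetworkSpec([CircuitSpec(I0_E=1.0, I0_I=0.3)])
        g = build_connectivity(spec, seed=2)
        assert not np.any(g.pre == g.post)
        pairs = np.stack([g.pre, g.post, g.receptor]).T
        assert len(np.unique(pairs, axis=0)) == len(pairs)

    def test_reproducible_for_fixed_seed(self):
        spec = NetworkSpec([CircuitSpec(I0_E=1.0, I0_I=0.3)])
        a = build_connectivity(spec, seed=9)
        b = build_connectivity(spec, seed=9)
        assert np.array_equal(a.pre, b.pre) and np.array_equal(a.post, b.post)

    def test_probability_validation(self):
        with pytest.raises(ValueError):
            CircuitSpec(connection_table={("E", "E"): (1.3, 1.0)})
        with pytest.raises(ValueError):
            ProjectionSpec(0, 1, p_ee=-0.1)

    def test_projection_total_conductance_bookkeeping(self):
        """Realized mean total projection conductance per target is within
        5% of the specified 0.22 mS/cm^2."""
        proj = ProjectionSpec.from_total_conductance(0, 1, 0.22)
        spec = NetworkSpec([CircuitSpec(I0_E=1.0, I0_I=0.3)] * 2, [proj])
        g = build_connectivity(spec, seed=3)
        tot_e = g.total_conductance_per_target(slice(500, 900),
                                               pre_range=slice(0, 400))
        tot_i = g.total_conductance_per_target(slice(900, 1000),
                                               pre_range=slice(0, 400))
        assert tot_e.mean() == pytest.approx(0.22, rel=0.05)
        assert tot_i.mean() == pytest.approx(0.22, rel=0.05)
        assert proj.total_conductance() == pytest.approx((0.22, 0.22), rel=1e-9)


class TestSynapticCurrent:
    def test_zero_gates_zero_current(self):
        bank = SynapseBank(np.zeros((5, 2)))
        assert np.all(synaptic_current(bank, np.full(5, -60.0)) == 0.0)

    def test_ampa_depolarizing_sign_and_magnitude(self):
        g = np.zeros((1, 2))
        g[0, 0] = 1.2e-3  # mS/cm^2
        i = synaptic_current(SynapseBank(g), np.array([-60.0]))
        assert i[0] == pytest.approx(1.2e-3 * 60.0)
        assert i[0] > 0

    def test_gaba_at_reversal_is_zero(self):
        g = np.zeros((1, 2))
        g[0, 1] = 5e-3
        i = synaptic_current(SynapseBank(g), np.array([-75.0]))
        assert i[0] == 0.0


class TestDelaysAndGates:
    def test_gate_decay_without_spikes(self):
        """Synaptic conductances decay exponentially to zero when no spike
        ever arrives."""
        spec = NetworkSpec([CircuitSpec(I0_E=-2.0, I0_I=-2.0, n_pyramidal=4,
                                        n_interneuron=2,
                                        connection_table=_zero_table(),
                                        heterogeneity_sd=0.0)])
        sim = Simulation(spec, StimulusSet(), duration=50.0, seed=0)
        snap = sim.snapshot()
        snap["g_syn"][:, 0] = 0.5
        sim.restore(snap)
        sim.run_until(10.0)
        expected = 0.5 * np.exp(-10.0 / TAU_AMPA)
        assert np.allclose(sim.g_syn[:, 0], expected, rtol=1e-6)

    def test_spike_acts_on_target_after_exact_delay(self):
        """A presynaptic spike at t increments the postsynaptic gate at
        exactly t + delay (1 ms here)."""
        table = _zero_table()
        table[("E", "E")] = (1.0, 2.0)  # all-to-all E->E, 2 uS
        spec = NetworkSpec([CircuitSpec(I0_E=0.0, I0_I=-2.0, n_pyramidal=2,
                                        n_interneuron=1,
                                        connection_table=table,
                                        heterogeneity_sd=0.0)])
        sim = Simulation(spec, StimulusSet(), duration=100.0, seed=0)
        sim.I_static[0] = 3.0    # only neuron 0 fires
        sim.I_static[1] = -5.0
        sim.run_until(60.0)
        raster = sim.raster()
        t_spk = raster.times[raster.ids == 0][0]
        sim2 = Simulation(spec, StimulusSet(), duration=100.0, seed=0)
        sim2.I_static[0] = 3.0
        sim2.I_static[1] = -5.0
        sim2.run_until(t_spk + 1.0)
        assert sim2.g_syn[1, 0] == 0.0  # delay not yet elapsed at t + 1 ms
        sim2.run_until(t_spk + 1.0 + sim2.dt)
        # the increment acts from exactly t + 1 ms on (one decay step later)
        assert sim2.g_syn[1, 0] == pytest.approx(
            2e-3 * np.exp(-sim2.dt / TAU_AMPA), rel=1e-9)

    def test_disconnected_circuits_match_isolated_run(self):
        """With zero inter-circuit conductance, circuit 0 of a two-circuit
        network spikes identically to the same circuit run alone (same
        seed): no acausal or zero-strength interaction."""
        c = CircuitSpec(I0_E=2.0, I0_I=0.6)
        two = NetworkSpec([c, CircuitSpec(I0_E=1.0, I0_I=0.3)],
                          [ProjectionSpec.from_total_conductance(0, 1, 0.0)])
        one = NetworkSpec([c])
        r2 = run_simulation(two, duration=600.0, seed=5)
        r1 = run_simulation(one, duration=600.0, seed=5)
        sel = r2.ids < 500
        assert np.array_equal(r2.times[sel], r1.times)
        assert np.array_equal(r2.ids[sel], r1.ids)


class TestSimulation:
    def test_same_seed_identical_rasters(self):
        spec = NetworkSpec([CircuitSpec(I0_E=2.0, I0_I=0.6)])
        a = run_simulation(spec, duration=400.0, seed=12)
        b = run_simulation(spec, duration=400.0, seed=12)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.ids, b.ids)

    def test_blowup_reports_neuron_and_time(self):
        spec = NetworkSpec([CircuitSpec(I0_E=1.0, I0_I=0.3, n_pyramidal=4,
                                        n_interneuron=2,
                                        connection_table=_zero_table())])
        sim = Simulation(spec, StimulusSet(), duration=100.0, seed=0)
        sim.I_static[2] = np.inf
        with pytest.raises(FloatingPointError, match="neuron 2"):
            sim.run_until(10.0)

    def test_snapshot_restore_branches_identically(self):
        spec = NetworkSpec([CircuitSpec(I0_E=2.0, I0_I=0.6)])
        sim = Simulation(spec, StimulusSet(), duration=500.0, seed=4)
        sim.run_until(200.0)
        snap = sim.snapshot()
        sim.run_until(400.0)
        first = sim.raster().times.copy()
        sim.restore(snap)
        sim.run_until(400.0)
        assert np.array_equal(sim.raster().times, first)


class TestPingPhenomenology:
    def test_gates_stay_in_unit_interval(self, ping_run, gamma_op):
        spec = NetworkSpec([reference_circuit(gamma_op.I0_E,
                                              I0_I=gamma_op.I0_I)],
                           pyramidal_params=reference_pyramidal_params())
        sim = Simulation(spec, StimulusSet(), duration=300.0, seed=3)
        sim.run_until(300.0)
        for g in (sim.h, sim.n, sim.z):
            assert np.all(g >= 0.0) and np.all(g <= 1.0)

    def test_pyramidal_volleys_lead_interneuron_volleys(self, ping_run):
        """Cross-correlogram peak lag of the I density behind the E density
        falls in [1, 5] ms in the PING regime."""
        lag = _ei_lag(ping_run, 500.0, 1300.0)
        assert 1.0 <= lag <= 5.0

    def test_interneurons_lock_more_strongly_than_pyramids(self, ping_run):
        dens = spike_density(ping_run.window(500, 1300), "c0E", t0=500, t1=1300)
        feats = instantaneous_features(morlet_transform(dens))
        inner = ping_run.window(550, 1250)
        ppc_e = pairwise_phase_consistency(
            spike_phases(inner.population("c0E").times, feats))
        ppc_i = pairwise_phase_consistency(
            spike_phases(inner.population("c0I").times, feats))
        assert ppc_i >= ppc_e

    def test_joint_depolarization_sweeps_beta_to_gamma(self):
        """Drive pairs along the reference diagonal produce oscillation
        frequencies spanning the beta and gamma bands (20-90 Hz)."""
        freqs = []
        for I_E in (0.7, 2.5, 7.8):
            spec = NetworkSpec([reference_circuit(I_E)],
                               pyramidal_params=reference_pyramidal_params())
            r = run_simulation(spec, duration=1100.0, seed=6)
            d = spike_density(r.window(500, 1100), "c0E", t0=500, t1=1100)
            freqs.append(instantaneous_features(morlet_transform(d)).mean_frequency)
        assert freqs[0] < 25.0
        assert freqs[-1] > 80.0
        assert np.all(np.diff(freqs) > 0)
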