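"""Shared fixtures: a few expensive simulations reused across test modules."""

import numpy as np
import pytest

from pingnet.experiments import (calibrate_frequency, reference_circuit,
                                 reference_pyramidal_params)
from pingnet.network import (CircuitSpec, NetworkSpec, ProjectionSpec,
                             run_simulation)
from pingnet.stimuli import NoiseSpec, StimulusSet, seed_screen


@pytest.fixture(scope="session")
def gamma_op():
    """Reference operating point calibrated to 73 Hz."""
    return calibrate_frequency(73.0, seed=11)


@pytest.fixture(scope="session")
def ping_run(gamma_op):
    """One isolated PING circuit at the 73 Hz reference point, 1.3 s."""
    spec = NetworkSpec([reference_circuit(gamma_op.I0_E, I0_I=gamma_op.I0_I)],
                       pyramidal_params=reference_pyramidal_params())
    return run_simulation(spec, duration=1300.0, seed=3)


@pytest.fixture(scope="session")
def coupled_pair_run(gamma_op):
    """Locked feedforward pair (73 Hz sender, ~43 Hz receiver, 0.22 mS/cm^2)
    with independent colored-noise currents, 3.6 s."""
    rec = calibrate_frequency(43.0, seed=11)
    spec = NetworkSpec(
        [reference_circuit(gamma_op.I0_E, I0_I=gamma_op.I0_I),
         reference_circuit(rec.I0_E, I0_I=rec.I0_I)],
        [ProjectionSpec.from_total_conductance(0, 1, 0.22)],
        pyramidal_params=reference_pyramidal_params())
    s1, s2 = seed_screen(range(100, 180), 3600.0, dt=0.05, n_required=2)
    stim = StimulusSet(noise=[NoiseSpec(0, seed=s1), NoiseSpec(1, seed=s2)])
    return run_simulation(spec, stim, duration=3600.0, seed=7)


@pytest.fixture(scope="session")
def uncoupled_pair_run(gamma_op):
    """Same two circuits with zero inter-circuit conductance, 3.6 s."""
    rec = calibrate_frequency(43.0, seed=11)
    spec = NetworkSpec(
        [reference_circuit(gamma_op.I0_E, I0_I=gamma_op.I0_I),
         reference_circuit(rec.I0_E, I0_I=rec.I0_I)],
        [ProjectionSpec.from_total_conductance(0, 1, 0.0)],
        pyramidal_params=reference_pyramidal_params())
    s1, s2 = seed_screen(range(100, 180), 3600.0, dt=0.05, n_required=2)
    stim = StimulusSet(noise=[NoiseSpec(0, seed=s1), NoiseSpec(1, seed=s2)])
    return run_simulation(spec, stim, duration=3600.0, seed=7)
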