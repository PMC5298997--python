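"""Numba integration kernel for multi-circuit spiking networks.

One flat neuron index space covers all circuits.  Synapses are stored in CSR
form keyed by presynaptic neuron; spike arrivals are queued in a circular
buffer at time-step resolution (delays are exact multiples of dt).  Within a
time step the total current of each neuron (static drive + shared traces +
synaptic current evaluated at the step-start voltage) is held constant while
the membrane equations advance by one classical RK4 update.

Status codes returned by :func:`simulate`: 0 ok, 1 numerical blow-up
(non-finite voltage; offending neuron and step reported), 2 spike-capacity
overflow.
"""

import numpy as np
from numba import njit

from .neurons import _wb_rhs, _ga_rhs

AMPA = 0
GABA = 1


@njit(cache=True, inline="always")
def _rk4_neuron(ct, V, h, n, z, I, pyr_p, int_p, dt):
    if ct == 0:
        d1V, d1h, d1n, d1z = _ga_rhs(V, h, n, z, I, pyr_p)
        d2V, d2h, d2n, d2z = _ga_rhs(V + 0.5 * dt * d1V, h + 0.5 * dt * d1h,
                                     n + 0.5 * dt * d1n, z + 0.5 * dt * d1z, I, pyr_p)
        d3V, d3h, d3n, d3z = _ga_rhs(V + 0.5 * dt * d2V, h + 0.5 * dt * d2h,
                                     n + 0.5 * dt * d2n, z + 0.5 * dt * d2z, I, pyr_p)
        d4V, d4h, d4n, d4z = _ga_rhs(V + dt * d3V, h + dt * d3h,
                                     n + dt * d3n, z + dt * d3z, I, pyr_p)
        return (V + dt / 6.0 * (d1V + 2 * d2V + 2 * d3V + d4V),
                h + dt / 6.0 * (d1h + 2 * d2h + 2 * d3h + d4h),
                n + dt / 6.0 * (d1n + 2 * d2n + 2 * d3n + d4n),
                z + dt / 6.0 * (d1z + 2 * d2z + 2 * d3z + d4z))
    else:
        d1V, d1h, d1n = _wb_rhs(V, h, n, I, int_p)
        d2V, d2h, d2n = _wb_rhs(V + 0.5 * dt * d1V, h + 0.5 * dt * d1h,
                                n + 0.5 * dt * d1n, I, int_p)
        d3V, d3h, d3n = _wb_rhs(V + 0.5 * dt * d2V, h + 0.5 * dt * d2h,
                                n + 0.5 * dt * d2n, I, int_p)
        d4V, d4h, d4n = _wb_rhs(V + dt * d3V, h + dt * d3h,
                                n + dt * d3n, I, int_p)
        return (V + dt / 6.0 * (d1V + 2 * d2V + 2 * d3V + d4V),
                h + dt / 6.0 * (d1h + 2 * d2h + 2 * d3h + d4h),
                n + dt / 6.0 * (d1n + 2 * d2n + 2 * d3n + d4n),
                z)


@njit(cache=True)
def simulate(n_steps, step0, dt,
             cell_type, pyr_p, int_p,
             I_static, drive_id, drive_traces, pulse_id, pulse_traces,
             indptr, syn_post, syn_w, syn_delay, syn_rec,
             tau_ampa, tau_gaba, e_ampa, e_gaba,
             V, h, n, z, g_syn, ring, thresholds,
             spike_steps, spike_ids, n_spikes0,
             rec_idx, v_rec):
    N = V.size
    D = ring.shape[0]
    dec_a = np.exp(-dt / tau_ampa)
    dec_g = np.exp(-dt / tau_gaba)
    n_sp = n_spikes0
    cap = spike_steps.size
    n_rec = rec_idx.size

    for k in range(n_steps):
        g = step0 + k
        slot = g % D
        for j in range(N):
            g_syn[j, AMPA] += ring[slot, j, AMPA]
            g_syn[j, GABA] += ring[slot, j, GABA]
            ring[slot, j, AMPA] = 0.0
            ring[slot, j, GABA] = 0.0

        for j in range(N):
            I = I_static[j]
            di = drive_id[j]
            if di >= 0:
                I += drive_traces[di, g]
            pi = pulse_id[j]
            if pi >= 0:
                I += pulse_traces[pi, g]
            I += g_syn[j, AMPA] * (e_ampa - V[j]) + g_syn[j, GABA] * (e_gaba - V[j])

            v_old = V[j]
            V[j], h[j], n[j], z[j] = _rk4_neuron(
                cell_type[j], V[j], h[j], n[j], z[j], I, pyr_p, int_p, dt)
            if not np.isfinite(V[j]):
                return n_sp, 1, j, g + 1

            thr = thresholds[j]
            if v_old < thr and V[j] >= thr:
                if n_sp >= cap:
                    return n_sp, 2, j, g + 1
                spike_steps[n_sp] = g + 1
                spike_ids[n_sp] = j
                n_sp += 1
                for s in range(indptr[j], indptr[j + 1]):
                    arr = (g + 1 + syn_delay[s]) % D
                    ring[arr, syn_post[s], syn_rec[s]] += syn_w[s]

        for j in range(N):
            g_syn[j, AMPA] *= dec_a
            g_syn[j, GABA] *= dec_g

        for r in range(n_rec):
            v_rec[r, k] = V[rec_idx[r]]

    return n_sp, 0, -1, -1
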