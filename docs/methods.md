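# Methods

## Model

A local circuit is 400 pyramidal cells and 100 fast-spiking interneurons,
each a single-compartment conductance-based model integrated with classical
RK4 at dt = 0.05 ms. Interneurons follow the Wang–Buzsáki equations
(transient Na with instantaneous activation, delayed-rectifier K, leak;
gating rates scaled by φ = 5). Pyramidal cells follow the Golomb–Amitai
equations (transient Na, persistent Na, delayed-rectifier K, a slow K
adaptation gate `z` with τ_z = 75 ms, leak). All channel constants live in
dataclasses (`pingnet.neurons`) and in the YAML config schema, so any
alternative parameter set can be substituted without code changes.

Synapses are conductance-based with instantaneous rise and single-
exponential decay (AMPA: τ = 2 ms, E = 0 mV; GABA_A: τ = 8 ms, E = −75 mV).
A presynaptic spike increments the summed conductance of each of its targets
by the unitary strength after the axonal delay (1 ms within a circuit, 5 ms
between circuits; delays are exact multiples of dt and are realized by a
circular event buffer). Within one time step all applied and synaptic
currents are evaluated at the step-start voltage and held constant, matching
fixed-step network practice. Intra-circuit wiring follows the connection
table (E→E 10% / 1.2 µS cm⁻², E→I 30% / 1.0, I→I 20% / 12, I→E 60% / 5.0);
inter-circuit projections are purely excitatory onto both cell types and are
parameterized by the *total* conductance per target neuron
(probability × source count × unitary strength), with 0.22 mS cm⁻² as the
reference value.

Every neuron receives `I_inj = I_0 + I_σ` with per-neuron Gaussian jitter of
SD 0.1 µA cm⁻². Initial voltages are uniform in [−70, −50] mV with gates at
steady state; the first 500 ms of every run are discarded. All randomness
derives from independent named streams (connectivity, initial conditions,
drive jitter, pulse targets) spawned from the run seed, so adding a pulse
never perturbs the other draws — the basis of the paired pulse / no-pulse
comparisons, which branch from a snapshot of the full dynamical state so
the pre-pulse trajectory is bit-identical.

## Operating line

The reference protocols drive both populations along the diagonal
`I_I = 0.3 I_E`. On this line the circuit oscillates by the PING mechanism
from ~19 Hz (I_E = 0.5 µA cm⁻²) to ~89 Hz (I_E = 8), pyramidal volleys lead
interneuron volleys by 1–5 ms, and interneurons lock more strongly than
pyramidal cells. The pyramidal adaptation conductance is reduced to
g_z = 0.2 mS cm⁻² on this line: with the full canonical adaptation the
20–90 Hz band is only reached at drives of 4–14 µA cm⁻², where the fixed
0.1 µA cm⁻² heterogeneity becomes a ~1% perturbation and the population
locks rigidly; at g_z = 0.2 the same band sits at 0.5–8 µA cm⁻², where
heterogeneity meaningfully disperses spike timing. `calibrate_frequency`
finds drives for a target frequency by closed-loop secant search seeded
from a measured drive–frequency table, optionally nudging the E/I drive
ratio to hold pyramidal PPC in the intermediate band [0.25, 0.5).

## Analysis

* **Spike density** — population rate in 0.5 ms bins (spikes/s per neuron),
  the model's LFP proxy; all spectral analysis runs at 2000 Hz.
* **Wavelet features** — complex Morlet (bandwidth parameter f_b = 1)
  continuous transform on a 15–100 Hz grid (0.5 Hz spacing) via PyWavelets;
  the power ridge gives instantaneous phase (0 at the density peak, rising
  to 2π at the next peak) and power; instantaneous frequency is the smoothed
  derivative of the unwrapped ridge phase (10 ms boxcar), hence
  continuous-valued rather than grid-quantized. Samples within 3 wavelet SDs
  of an edge are masked. Frequency is reported as undefined when pyramidal
  PPC < 0.05; the trace-average frequency is the median over valid samples,
  since occasional phase slips inflate a plain mean.
* **PPC** — pairwise phase consistency over all spike pairs, computed in
  closed form `(|Σe^{iθ}|² − n)/(n(n−1))`; an O(n²) pair loop serves as the
  oracle in the tests.
* **Coherence** — multitaper with time–bandwidth product 30 (59 Slepian
  tapers, scipy DPSS), mean-subtracted traces, read out at the sender's mean
  ridge frequency. "High coherence" is ≥ 0.90.
* **Phase difference** — circular mean of the unwrapped instantaneous phase
  gap (sender minus receiver, i.e. the receiver's lag), reported only under
  high coherence; below it the instantaneous difference has too much
  variance for the mean to be meaningful.
* **Period metrics** — density peaks located on the ±15 Hz band-passed trace
  (minimum separation 0.6 periods), then refined on the 1 ms Gaussian-
  smoothed raw density with parabolic sub-bin interpolation (the phase
  modulation of peak advances is a fraction of the 0.5 ms bin). Per period:
  spike count, peak time, peak height, and paired Δs against a matched
  no-pulse reference.
* **Transfer signals** — per circuit, on the common 0.5 ms grid:
  instantaneous frequency; ridge power; and firing rate per oscillation
  period (period-averaged spike density, held constant within each period
  and smoothed with a boxcar one mean period wide — a raw per-period spike
  *count* confounds with period duration and is not used). Transfer is the
  zero-lag Pearson correlation per signal (the 5 ms delay is negligible
  against the 200 ms noise correlation time), cross-checked by plug-in
  mutual information on 6×6 equal-width bins (no bias correction; the bias
  is gauged by the shuffled baseline). Controls: full time-shuffling and
  one-period block shuffling of the receiver's traces.
* **Circular–linear correlation** — Mardia's ρ (combining correlations with
  cos θ and sin θ; invariant under phase shifts), p from nρ² ~ χ²(2).

## Stimuli

* **Colored noise** — Ornstein–Uhlenbeck process with τ = 200 ms, realized
  by an exact AR(1) recursion on the integration grid, stationary start.
  This reconciles the stated 200 ms correlation time with an approximate 1/f
  amplitude fall-off above the ~0.8 Hz Lorentzian corner. The SD default
  (0.4 µA cm⁻²) was calibrated once so that the induced slow instantaneous-
  frequency excursions span a few Hz (~2.5 Hz SD at 73 Hz). Because a 3 s
  trace holds only ~7 independent samples at τ = 200 ms, unscreened seed
  pairs routinely correlate at the 0.3 level; `seed_screen` searches a pool
  lazily and accepts seeds whose realized traces (at the simulation dt) are
  pairwise below |ρ| = 0.05.
* **EPSC pulses** — instantaneous rise, 2 ms exponential decay, delivered
  simultaneously to a fixed random 75% of a circuit's pyramidal cells. The
  default amplitude (2.0 µA cm⁻²) was calibrated once to the smallest ladder
  value whose rate change at the oscillation peak exceeds 3× the paired
  run-to-run SD.
* **Sinusoids and epoch schedules** — for the driven-circuit entrainment
  maps and the input-selection protocol (static drives stepped between
  3000 ms epochs; 400 ms around each transition excluded from windowed
  analysis).

## Problem sizes

The shipped protocol defaults are reduced relative to exhaustive parameter
maps, chosen so each scan completes in minutes on one core while still
resolving the quantities of interest: the Arnold-tongue scan uses 7 sender
frequencies × 3 total conductances (0.10, 0.12, 0.22 mS cm⁻² — two near the
tongue edge, where the largest locked phase lags live) × 1.5 s analyzed;
the transfer scan uses 9 receiver frequencies at the reference conductance
× 3 s; pulse susceptibility uses 16 phases × 5 paired runs, with each pulsed
branch resuming from a snapshot taken 20 ms before its pulse. Full-paper
grids are available behind `--scale paper` in the CLI.

## Numerical and design choices

* RK4 with inputs frozen at step start; no gating-variable clipping —
  non-finite state aborts the run with the neuron index (blow-up is an
  error, not silently repaired).
* Spike detection by upward threshold crossing (−20 mV pyramidal, 0 mV
  interneuron), no refractory window: these waveforms cross once per spike.
* Self-synapses excluded; at most one synapse per ordered pair per
  connection class.
* The optimal transfer phase is the argmax over high-coherence conditions
  of the mean of the rate and power correlations.
* Regime classification: ING if pyramidal rate < 1 Hz and interneuron
  PPC ≥ 0.25; PING if both PPCs ≥ 0.25 and the E→I cross-correlogram lag is
  in (0, 5] ms; otherwise asynchronous. Thresholds are exposed as arguments.
* Significance marks on susceptibility curves: per-phase one-sample t-test
  across runs, α = 0.05, no multiple-testing correction (configurable).

## What the synthetic inputs do and do not emulate

The stimulus module generates the study's "data": tonic drives with
per-neuron jitter, shared colored-noise currents uncorrelated across
circuits, EPSC pulses, sinusoids. These emulate slowly varying, circuit-wide
input fluctuations; they do not emulate spiking afferents (shot noise),
per-neuron independent noise, conduction-delay jitter, or synaptic
short-term plasticity. Passing tests therefore validate the mechanism —
entrainment within a tilted tongue, phase-dependent susceptibility windows,
phase-dependent transfer — not quantitative rates or synchrony levels of
any real cortical recording.

## Known limitations

* The locked phase difference saturates near 0.75 of a period at the tongue
  edge in this parameterization; the susceptibility window for rate
  increases sits early in the cycle rather than exactly at the density
  peak. Both are properties of the model at the reference operating line,
  and both shift with synapse kinetics and the E/I drive ratio.
* At the reference projection (equal E→E and E→I total conductance) the
  feedforward inhibition nearly cancels rate recruitment, so the rate
  correlation is the weakest of the three transfer channels; lowering the
  E→I share strengthens it markedly (`ei_ratio` in `transfer_scan`).
* Pulse-susceptibility correlations computed over all paired runs come out
  more sinusoidal (higher ρ) than typical experimental curves because the
  paired-branch design cancels almost all shared trajectory noise.
* Under two competing projections of equal total conductance (the
  input-selection network) the receiver does not hard-lock to either
  sender: the losing sender's volleys keep perturbing it, and the direct
  synaptic echo of each sender in the receiver's density contributes
  coherence at the sender's frequency even without locking (the multitaper
  band at TW = 30 is ±10–15 Hz for epoch-length windows, wide enough to
  admit it). Input selection therefore shows up most cleanly as the
  receiver's oscillation frequency following the selected sender and as the
  ordinal coherence switch, not as single-pair-level coherence values;
  per-epoch transfer correlations carry large sampling noise (a 2–3 s epoch
  holds ~10 independent noise samples at τ = 200 ms).
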