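# Methods

This note records the model as implemented, the numerical choices, and what
the test suite does and does not establish.

## Model and units

The unit system is {mV, ms, nA, MOhm} throughout, chosen so the published
default parameters are usable verbatim: with `R_m` in MOhm and currents in
nA, `R_m·I` is in mV; synaptic efficacies `g` carry nA·ms so the
`exp(−t/τ_syn)/τ_syn` kernel yields nA; the layer-4 rate `fr_L` (Hz) is
converted to spikes/ms inside the drive formula.

Defaults: `τ = 20 ms`, `R_m = 38.3 MΩ`, `V_T = 30 mV`, `V_reset = 0 mV`;
couplings `G_EE, G_EI, G_IE, G_II = 32, −96, 96, −128` with
`g_AB = G_AB/√K`; `τ_syn,E = 25 ms` (NMDA folded into a long AMPA constant),
`τ_syn,I = 4 ms`; `K = 500`, `K_AL = 250`, `σ_AB = 0.2 M`, `fr_L = 15 Hz`,
`ρ_E = ρ_I = 0.06`, `I_back = 0.12 nA` (scaled by `√K`); STDP
`a+ = 0.0128`, `a− = −0.0045`, `τ+ = 30 ms`, `τ− = 40 ms`; grids
`N_E = 8100`, `N_I = 2025` on a patch of side `M = 1 mm`; `δt = 0.05 ms`,
20 s runs with a 0.1 s discarded transient, stimuli at 0°…160° in 20° steps.

The feed-forward drive is a deterministic constant current (no layer-4 spike
noise): all temporal variability is generated by the recurrent balanced
dynamics, which is the phenomenon under study.

### Feed-forward scaling across K sweeps

With `g_AL`, `K_AL` fixed, the feed-forward drive would be independent of
the recurrent in-degree K, while the background and recurrent components
grow as `√K` — the balanced √K growth of *both* input components in a K
sweep then cannot hold.  The config therefore carries `ff_ref_k` (default
500): the drive is multiplied by `√(K/ff_ref_k)`, so at the default K the
published numbers apply exactly and K sweeps follow balanced scaling.  Set
`ff_ref_k: null` to pin the drive instead.

## Numerical scheme

Forward Euler at `δt = 0.05 ms` (the suite verifies halving δt changes
population rates by < 5%).  Recurrent currents are evaluated with one
decaying accumulator per neuron and synapse type — mathematically identical
to the explicit kernel sum because all excitatory (inhibitory) synapses
share one time constant — at O(N + spikes·fanout) cost per step.

Within-step order: decay accumulators/traces → compute currents (previous
step's spikes) → Euler update → threshold/reset → STDP pairing against past
spikes → push new spikes.  Spikes therefore act with a one-δt transmission
latency (no latency is specified by the model; this is the discretization's
convention), and simultaneous pre/post spikes contribute no STDP update.

Initial membrane potentials are uniform on `[V_reset, V_T)` from the run
seed, to avoid an artificial synchronous start; the 0.1 s transient washes
this out.  No refractory period is modeled — irrelevant far from rate
saturation (rates here are 2–10 Hz).  Each stimulus angle is an independent
run with a seed derived deterministically from the master seed and the
angle index.  Membrane potentials are checked for finiteness every 128
steps; a spike-buffer bound of 250 Hz per neuron guards runaway regimes,
and both failure modes abort with a diagnostic rather than returning
corrupt rasters.

## Connectivity

Connection probabilities are products of M-periodic Gaussians, truncated at
`k_max = 5` wraps (remainder < e⁻³⁰⁰ at σ = 0.2 M; configurable).  The
normalizer `Z_AB` is computed exactly per postsynaptic row by exploiting the
separability of the product kernel over the presynaptic grid, so
`Σ_j p_iA,jB = K` holds for every neuron (rows agree to float precision on
the aligned grids).  Self-connections are excluded — a standard convention
with negligible effect at K = 500.  Probabilities above 1 (possible for
small σ or large K/N_B) are clamped and counted, with a warning carrying the
maximum; `K > N_B` is rejected, and at `K = N_B` a block saturates toward
full connectivity through clamping.

Reconnection resamples the entire graph from the modulated probabilities
(rather than locally rewiring) and resets efficacies to 1: the rule is
applied to a network without plasticity history, and resampling is the
direct reading of "a new connectivity matrix".  Orientation differences use
the double-angle metric everywhere (orientations live on a half-circle).

## STDP implementation

Pairing is all-to-all (the rule is written per spike pair, with no
nearest-neighbor restriction), implemented online with one presynaptic and
one postsynaptic exponential trace per neuron — exact for exponential
windows.  The multiplicative factors `(2−w)` and `w` use the weight current
at the triggering spike; weights are clipped to `[0, 2]` after each event.
Within a time step all potentiation passes run before all depression
passes, fixing the event order; the explicit all-pairs reference
(`stdp_all_pairs`) follows the same convention, and the suite checks
trace/oracle agreement to 1e-10 and kernel/trace agreement edge by edge on
recorded spike trains.

The plastic phase runs at a single training orientation (0° by default);
the drift law averaged over stimuli is protocol-independent, so the choice
of training angle does not matter for the mean picture.  After `T_plastic`
the weights are frozen and the full nine-angle protocol measures tuning on
the frozen graph — the measurement convention that makes OSI well defined
for a single trained network.  Both E→E and E→I synapses are plastic;
inhibitory-presynaptic efficacies are identically 1.

## Ring mean-field model

Couplings are stored as magnitudes with the E/I sign structure applied
internally (the network's signed defaults map onto magnitudes at one
documented conversion point).  Profiles are Fourier-mode arrays with
`C(0) = 1`; all profiles of interest have support on modes {0, 1}, and
`n_max = 8` by default.  Feasibility (positive mean rates) requires
`I_E/I_I > |G_EI/G_II| > |G_EE/G_IE|`; per-mode stability requires
`J_EE(n) − J_II(n) < 0` and `J_IE J_EI − J_EE J_II > 0` (trace/determinant
of the mode's interaction matrix).  The ambiguous typeset form of the
instability condition is resolved by implementing the mode-1 trace
condition directly, which reproduces the worked boundary
`eps_cI = eps_cE |G_EE/G_II| = 0.11` at `eps_cE = 0.44`; the boundary is
located by bisection on the stability verdict (tol 1e-12) and cross-checked
against an eigenvalue scan to 1e-10.  A modulated drive with an unmodulated
recurrent profile makes the mode-1 system singular — the salt-and-pepper
divergence, where finite-K connectivity fluctuations (out of scope of the
leading-order theory) set the actual selectivity; this is raised as an
explicit error rather than returning infinity.  The finite-K spiking ring
is not simulated: the analytic solution is the deliverable and the 2-D
network is the simulation check.

## Desk-scale test conditions

Full-scale runs (N_E ≥ 8100, K = 500, 20 s × 9 angles) are overnight jobs;
the automated suite uses reduced presets chosen once:

- **Unit fixture**: 400 E / 100 I, K = 40.
- **Desk network**: 1600 E / 400 I, K = 100, 5 s runs — used for the
  layout comparison and the STDP claim (training uses the published 2/3-run
  plastic phase, 13.33 s).
- **Balanced-scaling check**: desk network, K ∈ {100, 400}, single angle,
  3 s.
- **Reconnection claim**: full patch 8100 E / 2025 I, K = 500, with a 10 s
  control protocol for PO estimation and 5 s measurement runs, three
  network realizations.  This claim genuinely requires the
  low-fluctuation regime: at desk K the preferred orientations are
  dominated by quenched connectivity fluctuations (corr(PO, θ_ff) ≈ 0.45),
  they re-randomize when the graph is resampled, and the planted functional
  alignment dissolves, leaving the OSI grid flat.  At the full patch
  corr(PO, θ_ff) ≈ 0.8 and the monotone decrease appears in every
  realization.

What desk-scale passes do **not** show: quantitative agreement with the
published full-scale means (OSI_E ≈ 0.57/0.27, etc.).  Desk OSI values are
inflated by finite-K fluctuation selectivity and short-run estimation bias,
and are used for directional claims only.

Two sub-claims of the balanced-scaling check are analytically out of reach
at the stated sizes and are expected to fail there (kept in the suite
rather than weakened): the *inhibitory* input component cannot double when
K quadruples, because the inhibitory rate itself falls with K (the
published rates imply a component ratio ≈ 1.46 at the published scale), and
`K = 400 = N_I` forces probability clamping that pushes the inhibitory rate
beyond the 30% band.  The excitatory-component, E-rate, and CV(ISI)
sub-claims hold.

## Known limitations

- Current-based synapses, no conductances, no NMDA voltage dependence, no
  axonal delays beyond the one-step discretization latency.
- The O(1/√K) fluctuation contribution to salt-and-pepper selectivity is
  treated only qualitatively (no closed form implemented).
- Population summaries exclude silent neurons from OSI means by default
  (configurable); the convention is stated in every summary table.
- Probability clamping makes the realized in-degree fall short of K when
  K/N_B approaches the inverse peak-to-mean ratio of the Gaussian profile
  (~0.17 at σ = 0.2 M); the clamp count is reported on every graph.
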