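# Methods

This note documents the models, the parameter choices that matter, and what
the test suite does and does not establish.

## The control problem

The controller observes beta-band (13–35 Hz) power of GPi spiking and emits
a binary action every 2 ms control step: deliver one biphasic DBS pulse to
the STN, or stay silent. Episodes last 30 steps (60 ms of simulated
activity); training runs 150 episodes. The reward is a signed quadratic
centred on a beta-power threshold of 0.35 (scale 100): positive below the
threshold, negative above, zero exactly at it, and odd-symmetric about it.
There is no explicit stimulation-cost term; sparse stimulation has to
emerge from the shaping alone.

## Spiking environment

### Neuron and synapse model

All eight populations (CtxE, CtxI, StrD1, StrD2, STN, GPe, GPi, Thal; ten
neurons each by default) use one single-compartment conductance template in
the lineage of published basal-ganglia DBS network models: fast Na/K spike
currents with Boltzmann steady-state activation, first-order h/n kinetics,
and — in the subcortical nuclei — a low-threshold Ca (T) current, a
high-threshold Ca current and a Ca-pool-driven AHP current (conductances
zeroed for cortex and striatum). Synaptic gates rise sigmoidally with
presynaptic voltage and decay exponentially (fast kinetics for
glutamatergic sources, slower for GABAergic ones); projections carry
per-connection probability, total conductance and axonal delay. All
constants live in `src/seadbs/env/params/bg_default.yaml`, the single
versioned source of truth; every population and connection is resolvable by
name, and missing keys fail loudly.

The integrator is fixed-step classical RK4 at 0.02 ms (100 substeps per
control step), with synaptic drive, noise and injected currents frozen
across each substep. Gating variables are clamped to [0, 1] against
round-off; any non-finite membrane potential aborts with the offending time
and neuron index. Spikes are upward crossings of −20 mV with a 1 ms
refractory lockout, dated at the substep midpoint so every spike lies
strictly inside the half-open raster window.

Background drive has three parts per population: a constant bias current
(tuned so isolated-neuron rates sit in physiological ranges — cortex
~5–20 Hz, striatum ~2–15 Hz, STN ~30–45 Hz, pallidum ~50–75 Hz), white
current noise drawn per neuron per substep from a seeded stream, and — in
the parkinsonian condition — a zero-mean 17 Hz sinusoidal component of the
cortical and striatal drive.

### The dopamine-depletion switch

The healthy/parkinsonian contrast is expressed through condition-dependent
entries of the parameter file: reduced pallidal and striatal D1 bias
currents, a strengthened indirect pathway (StrD2→GPe), a weakened direct
pathway (StrD1→GPi), noisier (burstier) pallidal firing, and the rhythmic
cortical/striatal drive component above. The rhythmic drive is a modelling
choice: rather than relying on an emergent STN–GPe loop oscillation —
whose frequency is delicate to pin inside the beta band — the parkinsonian
cortex/striatum is driven at 17 Hz, placing both the fundamental and its
second harmonic (34 Hz) inside the 13–35 Hz band. The canonical
direct/indirect imbalance is essential here: with a symmetric striatum the
in-phase direct-pathway inhibition of GPi cancels the indirect-pathway
disinhibition almost exactly, and no beta reaches the output nucleus.

These knobs were tuned once, until the condition contrast held across
seeds, and then frozen; they are not fit to any data. The resulting
phenotype: GPi beta power is higher in the parkinsonian condition than in
the healthy condition on matched seeds (ratio ≈ 1.3–1.4 over 1 s
measurements), 50 Hz STN stimulation (above-band) suppresses it, and
~30 Hz stimulation (in-band, realised as one pulse per 17 steps = 29.4 Hz)
amplifies it by entrainment — the frequency-dependence the evaluation
protocols probe.

### DBS pulse

Charge-balanced biphasic square pulse, 0.3 ms total width, 300 µA/cm²,
delivered identically to every STN neuron at the start of a control step.
Amplitude was chosen so that a 500 Hz train entrains STN firing.

## Biomarker

GPi spike trains are binned at 0.5 ms (2 kHz sampling, far above twice the
band edge). PSDs are estimated per neuron with Welch's method: 256 ms Hann
segments, 50% overlap, mean detrending — over a persistent rolling raster
of 512 ms. Beta resolution needs several beta cycles (29–77 ms each), so a
60 ms episode cannot carry its own estimate; the rolling raster and the
observation window therefore persist across episodes, and a 500 ms burn-in
precedes episode 1 so the first observation is already well-formed. With
burn-in disabled the window is flagged partially filled and fills as raster
accumulates. Band power integrates each PSD over 13–35 Hz by trapezoidal
quadrature (band edges interpolated onto the grid), averages over neurons,
and applies a fixed normalization (1200, set once so the unstimulated
parkinsonian baseline reads ≈ 0.36, the operative regime of the 0.35
reward threshold). A raw periodogram path (boxcar, no detrending) exists
alongside Welch and is held to a direct-DFT oracle at 1e-6 relative error
in the tests.

The RL state is the FIFO window of the last `n_obs = 5` beta values
(zero-padded while unfilled); its arithmetic mean is the quantity the
reward thresholds.

## Surrogate backend

A scalar beta amplitude relaxes toward a condition set-point (0.40
parkinsonian, 0.15 healthy; rate κ = 0.1 per step), is depressed
multiplicatively by pulses (δ = 0.08), and carries state and observation
noise (σ = 0.01 / 0.005). Without pulses the deterministic fixed point is
the set-point; with a pulse every step it is
`(1−δ)κ b_set / (1 − (1−δ)(1−κ))` ≈ 0.19, comfortably below threshold, so
the stimulate/don't trade-off is non-trivial. The surrogate reproduces the
interface and the qualitative pulse-suppression physics but none of the
spiking substrate: no stimulation-frequency resonance, no PSD estimation
error, no spectral structure. Learning results on the surrogate therefore
demonstrate the algorithm, not the neurophysiology; the spiking phenotypes
are tested on the network backend directly.

## Agent

Actor (obs → 2 logits), critic and reward predictor (obs ⊕ one-hot action
→ scalar) are MLPs with two 128-unit ReLU hidden layers, float32
parameters, hand-written backprop and Adam. 128 units keeps a full
training sweep tractable on one CPU core; width is configurable. Target
copies of actor and critic start equal to the online networks and track
them with Polyak coefficient 0.005 after every update.

Exploration draws Gumbel noise `g = −log(−log U)`, forms the relaxed
sample `softmax((logits + g)/τ)` (shift-invariance makes raw logits
equivalent to log-probabilities), and acts on its argmax — an exact draw
from softmax(logits) by the Gumbel-max property. The temperature anneals
as `τ_t = max(0.1, 1.0·e^(−0.001 t))` per environment step. Gradients pass
through the relaxed sample (straight-through: hard action forward, softmax
Jacobian backward). The critic target adds the predictor's estimate to the
observed reward, `r + r̂ + γQ′`, exactly as specified; a config switch
(`target_reward_mode`) exposes `real_only` / `predicted_only` / `mean`
variants for ablation, since the additive form double-counts reward signal
by construction. The predictor is trained online against observed rewards
(MSE); for offline fitting, targets are standardised during optimisation
and the affine rescale folded back into the linear output layer, which is
exactly equivalent and much better conditioned given reward magnitudes up
to ~12.

The baseline configuration disables the predictor (r̂ ≡ 0, recovering the
standard DDPG bootstrap) and replaces Gumbel-Softmax with epsilon-greedy
(ε annealed 1.0 → 0.05 at the same rate); its actor update feeds the
plain softmax of the logits to the critic. One gradient update per
environment step begins once 128 transitions are buffered (capacity 8192,
uniform batches of 32 without replacement).

Seeding: a run seed derives independent streams for environment noise,
agent initialisation and exploration; every logged number is determined by
(config, seed). Checkpoints store all five networks, optimizer moments,
exploration schedule state and the exploration RNG, and round-trip to
identical greedy behaviour.

## Evaluation protocols

* **Seed switching** — greedy parkinsonian rollouts with the noise streams
  re-seeded every n ∈ {10, 20, 50, 75} steps (weights and dynamical state
  untouched), reporting mean beta power (also on the ×1000 "Avg PSD"
  scale) and mean reward.
* **Fixed-rate probes** — open-loop pulse trains on the 2 ms grid;
  requested rates map to the nearest integer period (50 Hz → 10 steps,
  30 Hz → 17 steps = 29.4 Hz; > 500 Hz is rejected).
* **Ablations** — the 2×2 grid {predictor on/off} × {Gumbel-Softmax
  on/off} trained under matched seeds and budgets; the baseline arm is
  bit-identical to the standalone baseline trainer.
* **FP16 PTQ** — all five networks cast to half precision (storage bytes
  exactly halve; non-finite casts abort naming the layer), compared on a
  1000-state greedy-action probe set and in matched-seed closed-loop
  rollouts.

## Problem sizes used in the test suite

Statistical properties run at desk scale, chosen once: environment
phenotypes use 10 matched seeds with 500 ms settling plus 1024 ms
measurements; learning curves use 150 surrogate episodes × 5 seeds for
both learners; predictor recovery uses 4500 training and 500 held-out
pairs. Sign tests are one-sided binomial tests at p < 0.05.

## Known limitations

* The absolute scale of spike-train PSD depends on unstatable
  normalization conventions; comparisons are therefore within-model
  (condition vs condition, policy vs baseline), and the 0.36 operating
  point is a calibration, not a prediction.
* Parkinsonian beta is injected as a rhythmic cortical/striatal drive
  rather than emerging from loop dynamics; the model reproduces the
  phenotype and its frequency-dependent response to stimulation, not the
  oscillation's mechanism.
* Neuron parameters are a documented stand-in assembled from the published
  single-compartment basal-ganglia lineage, not a fit to any recording.
* The surrogate's pulse effect is rate-monotone; it cannot express the
  in-band-worse-than-silence effect the spiking model shows at 30 Hz.
* No LFP forward model (the biomarker is spike-derived), no
  multi-compartment neurons, no patient data.
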