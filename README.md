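# seadbs

Sample-efficient reinforcement-learning control of closed-loop deep brain
stimulation (DBS), evaluated in a spiking basal-ganglia model of Parkinson's
disease.

## The problem

Parkinson's disease is marked by pathologically elevated beta-band
(13–35 Hz) oscillations in basal-ganglia circuits, and suppressing GPi beta
power is a standard control objective for *adaptive* DBS: instead of
stimulating continuously, a controller reads a neural biomarker in real time
and decides, every few milliseconds, whether to deliver a pulse to the
subthalamic nucleus (STN). Reinforcement learning can personalise this
policy, but clinical settings allow very few interactions and the binary
stimulate/don't-stimulate action space is awkward for the standard
continuous-control algorithms.

This package implements and tests a sample-efficient actor-critic
controller (SEA-DBS) together with the environment it learns in:

* **Spiking environment** — eight populations (CtxE, CtxI, StrD1, StrD2,
  STN, GPe, GPi, Thal) of ten single-compartment conductance-based neurons,
  integrated at 0.02 ms by fixed-step RK4 (numba-accelerated), with a
  dopamine-depletion switch that elevates GPi beta power. DBS pulses are
  biphasic current injections into every STN neuron. A fast surrogate
  beta-oscillator with the identical reset/step contract supports quick
  training runs and tests.
* **Biomarker** — per-neuron GPi spike trains are binned at 0.5 ms, Welch
  PSDs estimated over a persistent 512 ms raster, and band power integrated
  over 13–35 Hz and averaged over neurons:
  `P_beta = (1/n) * sum_j  integral_13^35 P_j(f) df`.
  The last `n_obs = 5` values form the RL state `s_t`; its mean `P̄_beta`
  drives the reward.
* **Reward** — a signed quadratic centred on the clinical threshold
  `beta_t = 0.35`:
  `r = +100 (P̄_beta − beta_t)²` if `P̄_beta < beta_t`, else
  `r = −100 (P̄_beta − beta_t)²`.
* **Agent** — DDPG-style actor/critic with target networks and a replay
  buffer (capacity 8192, batch 32, γ = 0.99, actor/critic rates
  5e-4 / 1e-3), plus two additions: a predictive reward model `f(s, a)`
  whose estimate `r̂` augments the critic target
  (`Q_target = r + r̂ + γ Q′(s′, π′(s′))`), and Gumbel-Softmax exploration
  (`ã = softmax((log π + g)/τ)`, `g = −log(−log U)`) with temperature
  annealed as `τ_t = max(τ_min, τ_0 e^(−λ t))`. Disabling both recovers
  the epsilon-greedy DDPG baseline.
* **Evaluation** — seed-switching robustness rollouts, open-loop 50 Hz vs
  30 Hz stimulation probes, the 2×2 ablation grid, and FP16 post-training
  quantization with byte-count and policy-fidelity checks.

Networks are small NumPy multilayer perceptrons with hand-written
backpropagation and Adam — the whole stack runs on a single CPU with no
deep-learning framework.

## Worked example

Train the controller on the fast surrogate backend and quantize it:

```bash
$ seadbs train --backend surrogate --seed 3 --out runs/demo
final mean episode reward: 55.568
final mean beta power:     0.2146
artifacts in runs/demo

$ seadbs quantize --checkpoint runs/demo/checkpoint.npz --backend surrogate --out runs/demo-fp16
bytes_full: 352284
bytes_half: 176142
agreement: 1.0
mean_beta_full: 0.21488524588506622
mean_beta_fp16: 0.21488524588506622
beta_rel_delta: 0.0
```

The trained policy holds mean beta power near 0.21 — well below the 0.35
threshold (positive reward ≈ `100·(0.35−0.215)² ≈ 1.85` per step, ~55 per
30-step episode) — and the FP16 copy of the policy is byte-for-byte half
the size while choosing identical actions on the probe set.

The spiking backend is exercised the same way
(`seadbs simulate --condition parkinsonian --stim-hz 50 ...` prints the
resulting GPi beta power; `seadbs train` accepts `--backend network`), and
`seadbs ablate` trains the {predictive model} × {Gumbel-Softmax} grid.

## Layout

```
src/seadbs/
  reward.py        threshold-centred signed-quadratic reward
  biomarker.py     spike binning, Welch PSD, band power, observation window
  raster.py        spike rasters and their text export
  env/             parameter file, network builder, RK4 kernel, surrogate,
                   reset/step environment API
  agent/           MLP + Adam, Gumbel-Softmax, replay buffer, SEA-DBS agent
  training.py      the per-step interaction/update loop
  evaluation.py    seed-switch, fixed-rate, ablation, FP16 PTQ protocols
  plotting.py      training/PSD/ablation figures
  cli.py           seadbs train | eval | ablate | quantize | simulate
docs/methods.md    model assumptions, parameter choices, limitations
```
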