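# Default basal-ganglia network parameterization (version 1).
#
# Single source of truth for the spiking environment.  Single-compartment
# conductance neurons: fast Na/K spike currents in every population;
# low-threshold Ca (T), high-threshold Ca and Ca-dependent AHP currents in
# the subcortical nuclei, in the style of published basal-ganglia DBS
# network models.  Units: conductances mS/cm^2, potentials mV, currents
# uA/cm^2, times ms, frequencies Hz.
#
# `membrane_defaults` applies to every population; populations override
# individual entries.  Values written as {healthy: x, parkinsonian: y}
# encode the dopamine-depletion switch: reduced pallidal/striatal bias
# currents, a strengthened indirect-pathway projection, and a beta-rhythmic
# component of the cortical/striatal background drive.

version: 1

membrane_defaults:
  cm: 1.0
  gl: 0.10
  el: -65.0
  gna: 100.0
  ena: 50.0
  gk: 30.0
  ek: -80.0
  gt: 0.0
  gca: 0.0
  eca: 130.0
  gahp: 0.0
  k1: 15.0
  eps_ca: 5.0e-5
  kca: 15.0
  theta_m: -35.0
  sigma_m: 9.0
  theta_h: -58.0
  sigma_h: -7.0
  phi_h: 1.0
  tau_h0: 0.5
  tau_h1: 7.5
  theta_ht: -55.0
  sigma_ht: -7.0
  theta_n: -32.0
  sigma_n: 12.0
  phi_n: 1.0
  tau_n0: 0.6
  tau_n1: 4.0
  theta_nt: -55.0
  sigma_nt: -7.0
  theta_a: -63.0
  sigma_a: 7.8
  theta_r: -67.0
  sigma_r: -2.0
  phi_r: 0.2
  tau_r0: 40.0
  tau_r1: 17.5
  theta_rt: -68.0
  sigma_rt: -2.2
  theta_s: -39.0
  sigma_s: 8.0
  alpha_syn: 5.0
  beta_syn: 1.0
  theta_g: -10.0
  sigma_g: 5.0

populations:
  CtxE:
    size: 10
    i_app: -0.3
    noise: 1.5
    osc: {freq: 17.0, amp: {healthy: 0.0, parkinsonian: 2.5}}
  CtxI:
    size: 10
    alpha_syn: 2.0
    beta_syn: 0.25
    i_app: -0.3
    noise: 1.5
  StrD1:
    size: 10
    alpha_syn: 2.0
    beta_syn: 0.25
    i_app: {healthy: -1.2, parkinsonian: -1.5}
    noise: 1.5
  StrD2:
    size: 10
    alpha_syn: 2.0
    beta_syn: 0.25
    i_app: {healthy: -1.2, parkinsonian: -0.7}
    noise: 1.5
    osc: {freq: 17.0, amp: {healthy: 0.0, parkinsonian: 3.0}}
  STN:
    size: 10
    gt: 0.5
    gca: 0.5
    gahp: 9.0
    kca: 22.5
    i_app: 0.0
    noise: 1.0
  GPe:
    size: 10
    gt: 0.5
    gca: 0.15
    gahp: 5.0
    k1: 30.0
    eps_ca: 1.0e-4
    alpha_syn: 2.0
    beta_syn: 0.25
    i_app: {healthy: 0.3, parkinsonian: -0.3}
    noise: {healthy: 0.3, parkinsonian: 0.7}
  GPi:
    size: 10
    gt: 0.5
    gca: 0.15
    gahp: 10.0
    k1: 30.0
    eps_ca: 1.0e-4
    alpha_syn: 2.0
    beta_syn: 0.25
    i_app: {healthy: 0.4, parkinsonian: 0.0}
    noise: {healthy: 0.3, parkinsonian: 1.0}
  Thal:
    size: 10
    gt: 0.5
    i_app: -1.5
    noise: 1.0

connections:
  - {source: CtxE,  target: CtxI,  sign: excitatory, weight: 0.3, p: 0.5, delay: 1.0}
  - {source: CtxI,  target: CtxE,  sign: inhibitory, weight: 0.4, p: 0.5, delay: 1.0}
  - {source: CtxE,  target: StrD1, sign: excitatory, weight: 0.3, p: 0.5, delay: 2.0}
  - {source: CtxE,  target: StrD2, sign: excitatory, weight: 0.3, p: 0.5, delay: 2.0}
  - {source: CtxE,  target: STN,   sign: excitatory, weight: 0.6, p: 0.5, delay: 2.0}
  - {source: StrD1, target: GPi,   sign: inhibitory,
     weight: {healthy: 0.8, parkinsonian: 0.3}, p: 0.5, delay: 2.0}
  - {source: StrD2, target: GPe,   sign: inhibitory,
     weight: {healthy: 0.6, parkinsonian: 1.8}, p: 0.5, delay: 2.0}
  - {source: STN,   target: GPe,   sign: excitatory, weight: 0.4, p: 0.5, delay: 1.0}
  - {source: STN,   target: GPi,   sign: excitatory, weight: 0.8, p: 0.5, delay: 1.0}
  - {source: GPe,   target: STN,   sign: inhibitory, weight: 0.3, p: 0.5, delay: 1.0}
  - {source: GPe,   target: GPi,   sign: inhibitory, weight: 0.8, p: 0.5, delay: 1.0}
  - {source: GPe,   target: GPe,   sign: inhibitory, weight: 0.1, p: 0.3, delay: 1.0}
  - {source: GPi,   target: Thal,  sign: inhibitory, weight: 0.4, p: 0.5, delay: 1.0}
  - {source: Thal,  target: CtxE,  sign: excitatory, weight: 0.2, p: 0.5, delay: 2.0}

dbs:
  target: STN
  amplitude: 300.0
  width: 0.3
  shape: biphasic

biomarker:
  # scale applied to raw band-integrated spike-count power so the
  # unstimulated parkinsonian network reads ~0.36 (see biomarker module)
  normalization: 1200.0
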