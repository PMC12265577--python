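"""Construction and integration of the cortex-basal-ganglia-thalamus network.

``build_network`` resolves the parameter file for a condition, wires the
eight populations (probabilistic or all-to-all projections, signed by the
source's transmitter), and returns a ``SimState`` whose initial voltages and
RNG streams are fully determined by the config seed.  ``integrate`` advances
the state by an exact multiple of the integration step and returns the spike
raster of the covered window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..config import EnvConfig
from ..raster import SpikeRaster
from . import _kernels
from .params import (MEMBRANE_FIELDS, POPULATIONS, DBSPulseSpec,
                     NetworkParams, load_params)

__all__ = ["SimState", "build_network", "integrate", "NumericalInstability"]


class NumericalInstability(RuntimeError):
    """Raised when the integrator encounters a non-finite state value."""


@dataclass
class SimState:
    """Full dynamical state of the network plus its static wiring.

    Dynamic: clock ``t`` (ms), per-neuron membrane potential and gating
    variables, per-neuron synaptic gates with their delay-history ring
    buffer, per-neuron refractory bookkeeping, and the noise RNG.  Static
    arrays (wiring, parameters) are carried along so that ``integrate`` is
    self-contained.
    """

    config: EnvConfig
    params: NetworkParams
    t: float
    V: np.ndarray
    h: np.ndarray
    n: np.ndarray
    r: np.ndarray
    ca: np.ndarray
    s: np.ndarray
    s_hist: np.ndarray
    hist_pos: int
    last_spike: np.ndarray
    rng: np.random.Generator
    # static wiring
    pop_of: np.ndarray = field(repr=False, default=None)
    P: np.ndarray = field(repr=False, default=None)
    i_app: np.ndarray = field(repr=False, default=None)
    noise_sig: np.ndarray = field(repr=False, default=None)
    osc_amp: np.ndarray = field(repr=False, default=None)
    osc_freq: np.ndarray = field(repr=False, default=None)
    csrc: np.ndarray = field(repr=False, default=None)
    ctgt: np.ndarray = field(repr=False, default=None)
    cw: np.ndarray = field(repr=False, default=None)
    cexc: np.ndarray = field(repr=False, default=None)
    cdel: np.ndarray = field(repr=False, default=None)
    dbs_mask: np.ndarray = field(repr=False, default=None)

    @property
    def n_neurons(self) -> int:
        return self.V.shape[0]

    def neuron_slice(self, pop: str) -> np.ndarray:
        """Indices of one population's neurons."""
        p = POPULATIONS.index(pop)
        return np.where(self.pop_of == p)[0]

    def reseed_noise(self, seed: int) -> None:
        """Swap the background-noise stream without touching dynamics."""
        self.rng = np.random.default_rng(seed)


def build_network(config: EnvConfig) -> SimState:
    """Wire and initialise the network; identical seed, identical state."""
    params = load_params(config.condition, config.param_file,
                         population_size=config.population_size)
    sizes = [p.size for p in params.populations]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    n_total = int(offsets[-1])

    pop_of = np.zeros(n_total, dtype=np.int64)
    P = np.zeros((len(POPULATIONS), len(MEMBRANE_FIELDS)))
    i_app = np.zeros(n_total)
    noise_sig = np.zeros(n_total)
    osc_amp = np.zeros(n_total)
    osc_freq = np.zeros(n_total)
    for k, pop in enumerate(params.populations):
        lo, hi = offsets[k], offsets[k + 1]
        pop_of[lo:hi] = k
        for j, f in enumerate(MEMBRANE_FIELDS):
            P[k, j] = pop.intrinsic[f]
        i_app[lo:hi] = pop.i_app
        noise_sig[lo:hi] = pop.noise
        osc_amp[lo:hi] = pop.osc_amp
        osc_freq[lo:hi] = pop.osc_freq

    ss = np.random.SeedSequence(config.seed).spawn(3)
    wiring_rng = np.random.default_rng(ss[0])
    init_rng = np.random.default_rng(ss[1])
    noise_rng = np.random.default_rng(ss[2])

    dt = config.integration_step
    csrc, ctgt, cw, cexc, cdel = [], [], [], [], []
    for c in params.connections:
        si = POPULATIONS.index(c.source)
        ti = POPULATIONS.index(c.target)
        src = np.arange(offsets[si], offsets[si + 1])
        tgt = np.arange(offsets[ti], offsets[ti + 1])
        g = c.weight / (c.p * src.size)  # per-synapse conductance
        d_sub = int(round(c.delay / dt))
        for i_t in tgt:
            for i_s in src:
                if i_s == i_t:
                    continue
                if c.p >= 1.0 or wiring_rng.uniform() < c.p:
                    csrc.append(i_s)
                    ctgt.append(i_t)
                    cw.append(g)
                    cexc.append(1 if c.sign == "excitatory" else 0)
                    cdel.append(d_sub)

    max_delay = max(cdel) if cdel else 0
    hist_len = max(max_delay + 1, 1)

    V = init_rng.uniform(-72.0, -55.0, size=n_total)
    state = SimState(
        config=config, params=params, t=0.0,
        V=V,
        h=_xinf(V, P[pop_of, MEMBRANE_FIELDS.index("theta_h")],
                P[pop_of, MEMBRANE_FIELDS.index("sigma_h")]),
        n=_xinf(V, P[pop_of, MEMBRANE_FIELDS.index("theta_n")],
                P[pop_of, MEMBRANE_FIELDS.index("sigma_n")]),
        r=_xinf(V, P[pop_of, MEMBRANE_FIELDS.index("theta_r")],
                P[pop_of, MEMBRANE_FIELDS.index("sigma_r")]),
        ca=np.full(n_total, 0.05),
        s=np.zeros(n_total),
        s_hist=np.zeros((hist_len, n_total)),
        hist_pos=0,
        last_spike=np.full(n_total, -1e9),
        rng=noise_rng,
        pop_of=pop_of, P=P, i_app=i_app, noise_sig=noise_sig,
        osc_amp=osc_amp, osc_freq=osc_freq,
        csrc=np.array(csrc, dtype=np.int64),
        ctgt=np.array(ctgt, dtype=np.int64),
        cw=np.array(cw, dtype=float),
        cexc=np.array(cexc, dtype=np.int64),
        cdel=np.array(cdel, dtype=np.int64),
        dbs_mask=np.zeros(n_total, dtype=np.bool_),
    )
    for idx in state.neuron_slice(params.dbs.target):
        state.dbs_mask[idx] = True
    return state


def _xinf(v, theta, sigma):
    return 1.0 / (1.0 + np.exp(-(np.asarray(v) - theta) / sigma))


def _pulse_current(pulse_times_ms, n_sub, dt, spec: DBSPulseSpec) -> np.ndarray:
    """Per-substep injected current for a train of pulse onsets (call-relative)."""
    out = np.zeros(n_sub)
    if pulse_times_ms is None or len(pulse_times_ms) == 0:
        return out
    half = spec.width / 2.0
    for t_on in pulse_times_ms:
        k0 = int(round(t_on / dt))
        if spec.shape == "biphasic":
            k_mid = int(round((t_on + half) / dt))
            k_end = int(round((t_on + spec.width) / dt))
            out[max(k0, 0):min(k_mid, n_sub)] += spec.amplitude
            out[max(k_mid, 0):min(k_end, n_sub)] -= spec.amplitude
        else:
            k_end = int(round((t_on + spec.width) / dt))
            out[max(k0, 0):min(k_end, n_sub)] += spec.amplitude
    return out


def integrate(state: SimState, duration: float,
              pulse_times: np.ndarray | None = None,
              pulse: DBSPulseSpec | None = None) -> SpikeRaster:
    """Advance ``duration`` ms (an exact multiple of the integration step).

    ``pulse_times`` are pulse onsets in ms relative to the call start; the
    pulse shape defaults to the parameter file's DBS spec.  The state is
    modified in place; the returned raster covers exactly [t, t+duration).
    """
    dt = state.config.integration_step
    n_sub = duration / dt
    if abs(n_sub - round(n_sub)) > 1e-9:
        raise ValueError(
            f"duration {duration} ms is not a multiple of the step {dt} ms"
        )
    n_sub = int(round(n_sub))
    spec = pulse if pulse is not None else state.params.dbs
    if spec.width >= state.config.control_step:
        raise ValueError("pulse width must be shorter than a control step")
    idbs = _pulse_current(pulse_times, n_sub, dt, spec)

    cap = state.n_neurons * (int(duration) + 2)
    spike_i = np.zeros(cap, dtype=np.int64)
    spike_t = np.zeros(cap)
    kernel_seed = int(state.rng.integers(2**31 - 1))

    status, n_spk, bad_t, bad_i = _kernels.integrate_kernel(
        state.V, state.h, state.n, state.r, state.ca, state.s,
        state.s_hist, state.hist_pos, state.last_spike,
        state.pop_of, state.P,
        state.i_app, state.noise_sig, state.osc_amp, state.osc_freq,
        state.csrc, state.ctgt, state.cw, state.cexc, state.cdel,
        idbs, state.dbs_mask,
        state.params.esyn_exc, state.params.esyn_inh,
        state.t, dt, n_sub, kernel_seed,
        spike_i, spike_t,
    )
    if status != 0:
        raise NumericalInstability(
            f"non-finite membrane potential at t={bad_t:.3f} ms, "
            f"neuron {bad_i}"
        )
    t0 = state.t
    state.t = t0 + n_sub * dt
    state.hist_pos = (state.hist_pos + n_sub) % state.s_hist.shape[0]

    spikes = [np.empty(0)] * state.n_neurons
    if n_spk:
        si, st = spike_i[:n_spk], spike_t[:n_spk]
        order = np.argsort(st, kind="stable")
        si, st = si[order], st[order]
        for i in range(state.n_neurons):
            spikes[i] = st[si == i]
    return SpikeRaster(spikes, t0, state.t)
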