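"""Fixed-step integrator for the conductance-based network (numba-compiled).

One kernel call advances the whole network by ``n_sub`` substeps of ``dt`` ms
using a classical 4th-order Runge-Kutta scheme per neuron, with synaptic
drive conductances, background noise and injected currents held frozen over
each substep (evaluated at the substep start).  Membrane equations follow the
usual single-compartment form

    C dV/dt = -IL - INa - IK - IT - ICa - IAHP - Isyn + Iapp + Iosc + Idbs + noise

with Boltzmann steady-state gating x_inf(V) = 1/(1+exp(-(V-theta)/sigma)),
first-order kinetics for h, n, r, instantaneous m/a/s activation, and a
calcium pool driving the AHP current.  Synaptic gates rise with a sigmoidal
function of presynaptic voltage and decay exponentially; propagation delays
are realised by reading the gate history buffer.

Spikes are upward crossings of -20 mV with a 1 ms refractory lockout.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import MEMBRANE_FIELDS

# column indices into the per-population membrane-parameter matrix
_IDX = {name: i for i, name in enumerate(MEMBRANE_FIELDS)}
CM = _IDX["cm"]; GL = _IDX["gl"]; EL = _IDX["el"]
GNA = _IDX["gna"]; ENA = _IDX["ena"]; GK = _IDX["gk"]; EK = _IDX["ek"]
GT = _IDX["gt"]; GCA = _IDX["gca"]; ECA = _IDX["eca"]
GAHP = _IDX["gahp"]; K1 = _IDX["k1"]; EPS = _IDX["eps_ca"]; KCA = _IDX["kca"]
THM = _IDX["theta_m"]; SGM = _IDX["sigma_m"]
THH = _IDX["theta_h"]; SGH = _IDX["sigma_h"]; PHH = _IDX["phi_h"]
TH0 = _IDX["tau_h0"]; TH1 = _IDX["tau_h1"]; THT = _IDX["theta_ht"]; SHT = _IDX["sigma_ht"]
THN = _IDX["theta_n"]; SGN = _IDX["sigma_n"]; PHN = _IDX["phi_n"]
TN0 = _IDX["tau_n0"]; TN1 = _IDX["tau_n1"]; TNT = _IDX["theta_nt"]; SNT = _IDX["sigma_nt"]
THA = _IDX["theta_a"]; SGA = _IDX["sigma_a"]
THR = _IDX["theta_r"]; SGR = _IDX["sigma_r"]; PHR = _IDX["phi_r"]
TR0 = _IDX["tau_r0"]; TR1 = _IDX["tau_r1"]; TRT = _IDX["theta_rt"]; SRT = _IDX["sigma_rt"]
THS = _IDX["theta_s"]; SGS = _IDX["sigma_s"]
ASN = _IDX["alpha_syn"]; BSN = _IDX["beta_syn"]
THG = _IDX["theta_g"]; SGG = _IDX["sigma_g"]

SPIKE_THRESH = -20.0
REFRACTORY = 1.0  # ms


@njit(cache=True, fastmath=True, error_model="numpy")
def _xinf(v, theta, sigma):
    return 1.0 / (1.0 + np.exp(-(v - theta) / sigma))


@njit(cache=True, fastmath=True, error_model="numpy")
def _derivs(v, h, n, r, ca, s, p, i_in, g_exc, g_inh, e_exc, e_inh,
            out):
    """Membrane + gate derivatives for one neuron; p = its parameter row."""
    minf = _xinf(v, p[THM], p[SGM])
    ainf = _xinf(v, p[THA], p[SGA])
    sinf = _xinf(v, p[THS], p[SGS])
    il = p[GL] * (v - p[EL])
    ina = p[GNA] * minf * minf * minf * h * (v - p[ENA])
    ik = p[GK] * (n * n * n * n) * (v - p[EK])
    it = p[GT] * (ainf * ainf * ainf) * r * (v - p[ECA])
    ica = p[GCA] * sinf * sinf * (v - p[ECA])
    iahp = p[GAHP] * (v - p[EK]) * ca / (ca + p[K1])
    isyn = g_exc * (v - e_exc) + g_inh * (v - e_inh)
    out[0] = (-il - ina - ik - it - ica - iahp - isyn + i_in) / p[CM]

    hinf = _xinf(v, p[THH], p[SGH])
    tauh = p[TH0] + p[TH1] / (1.0 + np.exp(-(v - p[THT]) / p[SHT]))
    out[1] = p[PHH] * (hinf - h) / tauh

    ninf = _xinf(v, p[THN], p[SGN])
    taun = p[TN0] + p[TN1] / (1.0 + np.exp(-(v - p[TNT]) / p[SNT]))
    out[2] = p[PHN] * (ninf - n) / taun

    rinf = _xinf(v, p[THR], p[SGR])
    taur = p[TR0] + p[TR1] / (1.0 + np.exp(-(v - p[TRT]) / p[SRT]))
    out[3] = p[PHR] * (rinf - r) / taur

    out[4] = p[EPS] * (-ica - it - p[KCA] * ca)

    hsyn = _xinf(v, p[THG], p[SGG])
    out[5] = p[ASN] * hsyn * (1.0 - s) - p[BSN] * s


@njit(cache=True, error_model="numpy")
def integrate_kernel(
    V, H, N_, R, CA, S,           # dynamic state, modified in place [N]
    s_hist, hist_pos,             # gate history ring buffer [Hlen, N], int
    last_spike,                   # last spike time per neuron [N], ms
    pop_of, P,                    # neuron -> population, [n_pop, n_par]
    i_app, noise_sig, osc_amp, osc_freq,   # per-neuron drives [N]
    csrc, ctgt, cw, cexc, cdel,   # connection lists
    idbs, dbs_mask,               # per-substep DBS current [n_sub], bool [N]
    e_exc, e_inh,
    t0, dt, n_sub, seed,
    spike_i, spike_t,             # preallocated output buffers
):
    """Advance the network n_sub substeps; returns (status, n_spikes, bad_t, bad_i).

    status 0 = ok, 1 = non-finite state encountered (bad_t/bad_i say where).
    """
    np.random.seed(seed)
    n = V.shape[0]
    hlen = s_hist.shape[0]
    ncon = csrc.shape[0]
    g_exc = np.zeros(n)
    g_inh = np.zeros(n)
    i_in = np.zeros(n)
    k1 = np.empty(6); k2 = np.empty(6); k3 = np.empty(6); k4 = np.empty(6)
    sqdt = np.sqrt(dt)
    pos = hist_pos
    n_spk = 0

    for step in range(n_sub):
        t = t0 + step * dt
        # record current gates into history, then accumulate delayed drive
        for i in range(n):
            s_hist[pos, i] = S[i]
            g_exc[i] = 0.0
            g_inh[i] = 0.0
        for c in range(ncon):
            row = pos - cdel[c]
            if row < 0:
                row += hlen
            w = cw[c] * s_hist[row, csrc[c]]
            if cexc[c] == 1:
                g_exc[ctgt[c]] += w
            else:
                g_inh[ctgt[c]] += w

        for i in range(n):
            drive = i_app[i]
            if noise_sig[i] > 0.0:
                drive += noise_sig[i] * np.random.standard_normal() / sqdt
            if osc_amp[i] > 0.0:
                # zero-mean rhythmic drive: modulates without biasing rates
                drive += osc_amp[i] * np.sin(2.0e-3 * np.pi * osc_freq[i] * t)
            if dbs_mask[i]:
                drive += idbs[step]
            i_in[i] = drive

        for i in range(n):
            p = P[pop_of[i]]
            v0 = V[i]; h0 = H[i]; n0 = N_[i]; r0 = R[i]; c0 = CA[i]; s0 = S[i]
            ge = g_exc[i]; gi = g_inh[i]; ii = i_in[i]
            _derivs(v0, h0, n0, r0, c0, s0, p, ii, ge, gi, e_exc, e_inh, k1)
            _derivs(v0 + 0.5 * dt * k1[0], h0 + 0.5 * dt * k1[1],
                    n0 + 0.5 * dt * k1[2], r0 + 0.5 * dt * k1[3],
                    c0 + 0.5 * dt * k1[4], s0 + 0.5 * dt * k1[5],
                    p, ii, ge, gi, e_exc, e_inh, k2)
            _derivs(v0 + 0.5 * dt * k2[0], h0 + 0.5 * dt * k2[1],
                    n0 + 0.5 * dt * k2[2], r0 + 0.5 * dt * k2[3],
                    c0 + 0.5 * dt * k2[4], s0 + 0.5 * dt * k2[5],
                    p, ii, ge, gi, e_exc, e_inh, k3)
            _derivs(v0 + dt * k3[0], h0 + dt * k3[1],
                    n0 + dt * k3[2], r0 + dt * k3[3],
                    c0 + dt * k3[4], s0 + dt * k3[5],
                    p, ii, ge, gi, e_exc, e_inh, k4)
            vn = v0 + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            if not np.isfinite(vn):
                return 1, n_spk, t, i
            hn = h0 + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            nn = n0 + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
            rn = r0 + dt / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
            cn = c0 + dt / 6.0 * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
            sn = s0 + dt / 6.0 * (k1[5] + 2 * k2[5] + 2 * k3[5] + k4[5])
            # gating variables are fractions; clamp round-off excursions
            H[i] = min(max(hn, 0.0), 1.0)
            N_[i] = min(max(nn, 0.0), 1.0)
            R[i] = min(max(rn, 0.0), 1.0)
            S[i] = min(max(sn, 0.0), 1.0)
            CA[i] = max(cn, 0.0)
            # crossing happens inside (t, t+dt]; date it at the midpoint so
            # every spike lies strictly inside the half-open raster window
            t_cross = t + 0.5 * dt
            if vn >= SPIKE_THRESH and v0 < SPIKE_THRESH:
                if t_cross - last_spike[i] >= REFRACTORY:
                    spike_i[n_spk] = i
                    spike_t[n_spk] = t_cross
                    last_spike[i] = t_cross
                    n_spk += 1
            V[i] = vn
        pos += 1
        if pos >= hlen:
            pos = 0

    return 0, n_spk, 0.0, -1
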