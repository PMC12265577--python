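"""Gumbel-Softmax sampling and temperature annealing.

Adding Gumbel(0,1) noise to logits and taking the argmax draws exactly from
the categorical distribution softmax(logits) (the Gumbel-max trick); the
temperature-scaled softmax of the same perturbed logits is a differentiable
relaxation of that draw.  Annealing the temperature from ``tau0`` toward
``tau_min`` moves the policy from soft exploratory samples to near-one-hot
actions.

Note the relaxation is shift-invariant: softmax((log softmax(l) + g)/tau)
equals softmax((l + g)/tau), so raw logits are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "sample_gumbel",
    "gs_sample",
    "gs_backward",
    "GumbelExplorationState",
    "anneal",
]


def sample_gumbel(u):
    """Map uniform(0,1) draws to Gumbel(0,1): g = -log(-log u)."""
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0) or np.any(u >= 1):
        raise ValueError("uniform draws must lie strictly inside (0, 1)")
    return -np.log(-np.log(u))


def gs_sample(logits, tau: float, noise) -> np.ndarray:
    """Relaxed categorical sample: softmax((logits + g) / tau).

    Computed with the max-shift trick so arbitrarily large logits do not
    overflow.  Works on a single logit vector or a batch (last axis = class).
    """
    if tau <= 0:
        raise ValueError(f"temperature must be positive, got {tau}")
    z = (np.asarray(logits, dtype=float) + np.asarray(noise, dtype=float)) / tau
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def gs_backward(grad_out, a_tilde, tau: float) -> np.ndarray:
    """Gradient of a loss through gs_sample, back to the logits.

    Uses the softmax Jacobian: dL/dl = (a * (g - <g, a>)) / tau, applied
    rowwise; ``a_tilde`` is the forward output.
    """
    a = np.asarray(a_tilde, dtype=float)
    g = np.asarray(grad_out, dtype=float)
    inner = (g * a).sum(axis=-1, keepdims=True)
    return a * (g - inner) / tau


@dataclass
class GumbelExplorationState:
    """Exponentially annealed softmax temperature with a floor.

    tau(t) = max(tau_min, tau0 * exp(-decay * t)); ``t`` counts environment
    steps globally across episodes.
    """

    tau0: float = 1.0
    tau_min: float = 0.1
    decay: float = 1e-3
    t: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.tau_min <= self.tau0):
            raise ValueError("need 0 < tau_min <= tau0")
        if self.decay < 0:
            raise ValueError("decay must be nonnegative")

    @property
    def tau(self) -> float:
        return max(self.tau_min, self.tau0 * np.exp(-self.decay * self.t))

    def step(self) -> float:
        """Temperature for the current step; advances the step counter."""
        tau = self.tau
        self.t += 1
        return tau


def anneal(state: GumbelExplorationState) -> float:
    """Current annealed temperature, without advancing the counter."""
    return state.tau
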