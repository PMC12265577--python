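"""Fast surrogate environment: a stochastic beta-band amplitude model.

The surrogate replaces the spiking network with a scalar beta-power state
``b`` that relaxes toward a condition-dependent set-point and is depressed
multiplicatively by stimulation pulses.  Per 2 ms control step, in order:

    b <- b + kappa * (b_set - b) + sigma_state * xi        (relaxation + noise)
    b <- b * (1 - delta)                  if a pulse is delivered this step
    P_beta = max(b + sigma_obs * zeta, 0)                  (observation)

with xi, zeta independent standard normals.  With no pulses the deterministic
fixed point is ``b_set``; with a pulse every step it is

    b* = (1 - delta) * kappa * b_set / (1 - (1 - delta) * (1 - kappa)).

The surrogate exposes the same observation/reward step contract as the
network backend and is intended for fast training runs and tests; it does
not model spiking, stimulation-frequency resonance, or PSD estimation error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SurrogateParams", "SurrogateModel"]


@dataclass(frozen=True)
class SurrogateParams:
    """Dynamics constants of the surrogate oscillator."""

    b_set_pd: float = 0.40       # parkinsonian beta set-point
    b_set_healthy: float = 0.15
    kappa: float = 0.10          # relaxation rate per control step
    delta: float = 0.08          # multiplicative depression per pulse
    sigma_state: float = 0.010   # state noise per step
    sigma_obs: float = 0.005     # observation noise

    def set_point(self, condition: str) -> float:
        return self.b_set_pd if condition == "parkinsonian" else self.b_set_healthy

    def pulsed_fixed_point(self) -> float:
        """Deterministic fixed point under a pulse every step."""
        q = (1.0 - self.delta)
        return q * self.kappa * self.b_set_pd / (1.0 - q * (1.0 - self.kappa))


class SurrogateModel:
    """State-update core shared by the surrogate environment."""

    def __init__(self, params: SurrogateParams, condition: str,
                 rng: np.random.Generator):
        self.params = params
        self.condition = condition
        self.rng = rng
        self.b = params.set_point(condition)

    def step(self, pulse: bool) -> float:
        """Advance one control step; returns the observed beta power."""
        p = self.params
        self.b += p.kappa * (p.set_point(self.condition) - self.b)
        if p.sigma_state > 0:
            self.b += p.sigma_state * self.rng.standard_normal()
        if pulse:
            self.b *= (1.0 - p.delta)
        self.b = max(self.b, 0.0)
        obs = self.b
        if p.sigma_obs > 0:
            obs += p.sigma_obs * self.rng.standard_normal()
        return max(obs, 0.0)
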