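"""Threshold-centred signed-quadratic reward for beta-band suppression.

The controller's objective is to keep the mean beta-band power of the GPi
population below a clinical threshold ``beta_t`` (default 0.35).  The reward
is a signed quadratic centred on that threshold:

    r = +scale * (P - beta_t)**2   if P <  beta_t
    r = -scale * (P - beta_t)**2   otherwise

so the agent is rewarded quadratically for driving beta power below threshold
and penalised quadratically for excess beta activity.  There is no explicit
energy-cost term: sparse stimulation emerges from the shaping alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["RewardSpec", "compute_reward"]


@dataclass(frozen=True)
class RewardSpec:
    """Parameters of the signed-quadratic reward.

    Attributes
    ----------
    threshold : float
        The beta-power set-point ``beta_t`` separating reward from penalty.
    scale : float
        Multiplier applied to the squared excursion (default 100, i.e. the
        reward is naturally read in units of 10^-2).
    """

    threshold: float = 0.35
    scale: float = 100.0

    def __post_init__(self) -> None:
        if not (self.threshold > 0):
            raise ValueError(f"threshold must be positive, got {self.threshold}")
        if not (self.scale > 0):
            raise ValueError(f"scale must be positive, got {self.scale}")


def compute_reward(mean_beta: float, spec: RewardSpec = RewardSpec()) -> float:
    """Signed-quadratic reward of the windowed mean beta power.

    Parameters
    ----------
    mean_beta : float
        Mean beta-band power over the observation window; must be finite
        and nonnegative.
    spec : RewardSpec
        Threshold and scale.

    Returns
    -------
    float
        ``+scale*(mean_beta-threshold)**2`` below threshold, the negative of
        that at or above it.  Zero exactly at the threshold.
    """
    p = float(mean_beta)
    if not math.isfinite(p):
        raise ValueError(f"mean beta power must be finite, got {p!r}")
    if p < 0:
        raise ValueError(f"mean beta power must be nonnegative, got {p!r}")
    dev = p - spec.threshold
    mag = spec.scale * dev * dev
    return mag if p < spec.threshold else -mag
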