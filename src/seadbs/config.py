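"""Run configuration dataclasses and YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .reward import RewardSpec

__all__ = ["EnvConfig", "TrainConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class EnvConfig:
    """Environment geometry and timing.

    A control step lasts 2 ms and contains exactly
    ``control_step / integration_step`` substeps (100 at the defaults); an
    episode is 30 control steps = 60 ms of simulated activity.  The network
    backend integrates the spiking model; the surrogate backend runs a fast
    stochastic beta oscillator with the same reset/step contract.
    """

    integration_step: float = 0.02  # ms
    control_step: float = 2.0       # ms
    steps_per_episode: int = 30
    condition: str = "parkinsonian"
    seed: int = 0
    backend: str = "network"
    n_obs: int = 5
    burn_in: float = 500.0          # ms of settling before episode 1
    population_size: int = 10
    raster_window: float = 512.0    # ms of persistent raster for PSD
    param_file: str | None = None   # None -> bundled default parameter set
    reward: RewardSpec = field(default_factory=RewardSpec)

    def __post_init__(self) -> None:
        n_sub = self.control_step / self.integration_step
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise ValueError(
                f"control step {self.control_step} ms is not an integer "
                f"multiple of the integration step {self.integration_step} ms"
            )
        if self.condition not in ("healthy", "parkinsonian"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.backend not in ("network", "surrogate"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.steps_per_episode < 1 or self.population_size < 1:
            raise ValueError("steps_per_episode and population_size must be >= 1")

    @property
    def substeps_per_control(self) -> int:
        return int(round(self.control_step / self.integration_step))

    @property
    def episode_duration(self) -> float:
        """Episode length in ms (60 at the defaults)."""
        return self.steps_per_episode * self.control_step


@dataclass(frozen=True)
class TrainConfig:
    """End-to-end training run description."""

    n_episodes: int = 150
    env: EnvConfig = field(default_factory=EnvConfig)
    seed: int = 0
    out_dir: str | None = None
    # agent knobs mirrored here so a single YAML file describes a run
    predictive: bool = True
    exploration: str = "gumbel"
    hidden: tuple = (128, 128)
    target_reward_mode: str = "sum"

    @property
    def steps_total(self) -> int:
        return self.n_episodes * self.env.steps_per_episode


def _to_plain(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(cfg, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=False)


def load_config(path: str | Path, kind: str = "train"):
    """Load a TrainConfig ('train') or EnvConfig ('env') from YAML."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}

    def build_env(ed: dict) -> EnvConfig:
        ed = dict(ed)
        if "reward" in ed:
            ed["reward"] = RewardSpec(**ed["reward"])
        return EnvConfig(**ed)

    if kind == "env":
        return build_env(d)
    if "env" in d:
        d["env"] = build_env(d["env"])
    if "hidden" in d:
        d["hidden"] = tuple(d["hidden"])
    return TrainConfig(**d)
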