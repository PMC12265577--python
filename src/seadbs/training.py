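"""End-to-end training: the per-step interaction/update loop over episodes.

Per control step the loop anneals the exploration temperature, queries the
actor for logits, draws a Gumbel-Softmax action, applies it to the
environment, obtains the predictor's reward estimate, stores the transition
and performs one update of critic, actor and predictor with soft target
refreshes.  The baseline configuration runs the identical loop with the
predictor disabled and epsilon-greedy exploration.

All logged numbers are fully determined by (config, seed): the run seed
derives independent streams for environment noise, agent initialisation and
exploration noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .agent import Hyperparams, SEADBSAgent, Transition
from .config import TrainConfig, save_config
from . import make_env

__all__ = ["TrainResult", "train", "train_baseline", "build_agent"]


@dataclass
class TrainResult:
    """Artifacts of one training run."""

    agent: SEADBSAgent
    env: object
    metrics: pd.DataFrame    # one row per executed step
    episodes: pd.DataFrame   # one summary row per episode
    config: TrainConfig

    def save(self, out_dir: str | Path) -> Path:
        """Write metrics CSVs, the config echo and the final checkpoint."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        self.episodes.to_csv(out / "episodes.csv", index=False)
        save_config(self.config, out / "config.yaml")
        self.agent.save(out / "checkpoint.npz")
        return out


def _derive_seeds(run_seed: int) -> tuple[int, int]:
    """(environment seed, agent seed), both < 2**31, from the run seed."""
    ss = np.random.SeedSequence(run_seed)
    env_s, agent_s = (int(s) % (2**31 - 1) for s in ss.generate_state(2))
    return env_s, agent_s


def build_agent(config: TrainConfig, *, predictive: bool | None = None,
                exploration: str | None = None) -> SEADBSAgent:
    _, agent_seed = _derive_seeds(config.seed)
    hp = Hyperparams(hidden=tuple(config.hidden),
                     target_reward_mode=config.target_reward_mode)
    return SEADBSAgent(
        obs_dim=config.env.n_obs, hp=hp,
        predictive=config.predictive if predictive is None else predictive,
        exploration=config.exploration if exploration is None else exploration,
        seed=agent_seed,
    )


def train(config: TrainConfig, *, agent: SEADBSAgent | None = None,
          env=None) -> TrainResult:
    """Run the full training procedure and return logged artifacts."""
    env_seed, _ = _derive_seeds(config.seed)
    if env is None:
        env = make_env(replace(config.env, seed=env_seed))
    if agent is None:
        agent = build_agent(config)

    rows = []
    ep_rows = []
    for ep in range(config.n_episodes):
        obs = env.reset()
        ep_reward = 0.0
        ep_beta = []
        for t in range(config.env.steps_per_episode):
            s_vec = obs.as_vector()
            tau = agent.gs.tau if agent.exploration == "gumbel" else np.nan
            a, logits, _ = agent.select_action(s_vec, explore=True)
            obs, r, _, info = env.step(a)
            r_hat = agent.predict_reward(s_vec, a)
            agent.store(Transition(s_vec, a, np.asarray(logits), r, r_hat,
                                   obs.as_vector()))
            losses = agent.update() or {"critic": np.nan, "actor": np.nan,
                                        "predictor": np.nan}
            ep_reward += r
            ep_beta.append(info["mean_beta"])
            rows.append({
                "episode": ep, "step": t, "action": a,
                "p_beta": info["p_beta"], "mean_beta": info["mean_beta"],
                "reward": r, "r_hat": r_hat, "tau": tau,
                "critic_loss": losses["critic"], "actor_loss": losses["actor"],
                "predictor_loss": losses["predictor"],
            })
        ep_rows.append({
            "episode": ep,
            "mean_beta": float(np.mean(ep_beta)),
            "cumulative_reward": ep_reward,
            "n_pulses": int(sum(r["action"] for r in rows[-config.env.steps_per_episode:])),
        })
    metrics = pd.DataFrame(rows)
    episodes = pd.DataFrame(ep_rows)
    return TrainResult(agent, env, metrics, episodes, config)


def train_baseline(config: TrainConfig, **kw) -> TrainResult:
    """The plain DDPG reference: predictor off, epsilon-greedy exploration."""
    agent = kw.pop("agent", None)
    if agent is None:
        agent = build_agent(config, predictive=False, exploration="epsilon")
    cfg = replace(config, predictive=False, exploration="epsilon")
    return train(cfg, agent=agent, **kw)
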