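"""Evaluation protocols: robustness, frequency probes, ablations and PTQ.

Four protocols mirror the study design:

* ``seed_switch_eval`` — greedy closed-loop rollout in parkinsonian mode
  with the environment noise streams re-seeded every ``n_switch`` steps
  (simulating varying disease-progression rates); reports average beta
  power (also expressed on the x1000 "Avg PSD" scale) and average reward.
* ``fixed_rate_eval`` — open-loop pulse trains at a fixed rate on the 2 ms
  action grid (50 Hz = one pulse per 10 steps; "30 Hz" = one per 17 steps,
  i.e. 29.4 Hz), probing the in-band vs above-band stimulation contrast.
* ``run_ablations`` — trains the 2x2 grid {predictive model on/off} x
  {Gumbel-Softmax on/off} under matched seeds and budgets.
* ``ptq_fp16`` — casts every network of a trained agent to half precision
  and reports byte counts, greedy-action agreement on a probe set, and
  closed-loop beta deltas against the full-precision policy.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import make_env
from .agent import SEADBSAgent
from .config import EnvConfig, TrainConfig
from .training import TrainResult, train, train_baseline

__all__ = [
    "EvalProtocol", "EvalReport", "greedy_rollout", "seed_switch_eval",
    "fixed_rate_eval", "run_ablations", "quantize_agent", "ptq_fp16",
]


@dataclass(frozen=True)
class EvalProtocol:
    """How to evaluate a policy."""

    mode: str = "seed_switch"          # seed_switch | fixed_rate | ablation | ptq
    n_switch: int = 50                 # steps between environment re-seeds
    rate_hz: float = 0.0               # fixed_rate mode
    n_steps: int = 300                 # evaluation steps per seed
    seeds: tuple = (0, 1, 2, 3, 4)

    def __post_init__(self) -> None:
        if self.n_switch <= 0:
            raise ValueError("n_switch must be positive")
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")


@dataclass
class EvalReport:
    """Per-protocol summary plus the per-step traces it was computed from."""

    avg_beta: float          # mean windowed beta power over all steps/seeds
    avg_reward: float
    traces: pd.DataFrame     # seed, step, action, mean_beta, reward
    extras: dict = field(default_factory=dict)

    @property
    def avg_psd(self) -> float:
        """Average beta power on the x1000 'Avg PSD' reporting scale."""
        return 1000.0 * self.avg_beta


def greedy_rollout(agent_or_policy, env, n_steps: int,
                   switch_every: int | None = None,
                   switch_seeds=None,
                   forced_actions=None) -> pd.DataFrame:
    """Roll a policy greedily for ``n_steps``, re-resetting at episode ends.

    ``agent_or_policy`` is an agent (greedy_action) or a callable obs->action;
    ``forced_actions`` overrides the policy with a fixed action sequence
    (open-loop probes).  Environment noise is re-seeded every
    ``switch_every`` steps from ``switch_seeds``.
    """
    if hasattr(agent_or_policy, "greedy_action"):
        policy = agent_or_policy.greedy_action
    else:
        policy = agent_or_policy
    T = env.config.steps_per_episode
    switch_iter = iter(switch_seeds) if switch_seeds is not None else None
    obs = env.reset()
    rows = []
    for k in range(n_steps):
        if k > 0 and k % T == 0:
            obs = env.reset()
        if forced_actions is not None:
            a = int(forced_actions[k])
        else:
            a = int(policy(obs.as_vector()))
        obs, r, _, info = env.step(a)
        rows.append({"step": k, "action": a, "p_beta": info["p_beta"],
                     "mean_beta": info["mean_beta"], "reward": r})
        if switch_every and (k + 1) % switch_every == 0 and switch_iter is not None:
            env.reseed(next(switch_iter))
    return pd.DataFrame(rows)


def _report_from_traces(traces: list[pd.DataFrame], seeds, **extras) -> EvalReport:
    for df, s in zip(traces, seeds):
        df["seed"] = s
    all_df = pd.concat(traces, ignore_index=True)
    return EvalReport(
        avg_beta=float(all_df["mean_beta"].mean()),
        avg_reward=float(all_df["reward"].mean()),
        traces=all_df, extras=extras,
    )


def seed_switch_eval(agent, protocol: EvalProtocol,
                     env_config: EnvConfig) -> EvalReport:
    """Greedy rollout with periodic noise re-seeding (PD-progression probe)."""
    traces = []
    for seed in protocol.seeds:
        env = make_env(replace(env_config, seed=seed))
        sw_rng = np.random.default_rng(np.random.SeedSequence((seed, 911)))
        sw_seeds = [int(s) for s in
                    sw_rng.integers(2**31 - 1, size=protocol.n_steps)]
        traces.append(greedy_rollout(agent, env, protocol.n_steps,
                                     switch_every=protocol.n_switch,
                                     switch_seeds=sw_seeds))
    return _report_from_traces(traces, protocol.seeds,
                               n_switch=protocol.n_switch)


def fixed_rate_eval(rate_hz: float, protocol: EvalProtocol,
                    env_config: EnvConfig) -> EvalReport:
    """Open-loop pulse train at a grid-expressible rate (0 = no stimulation)."""
    step_hz = 1000.0 / env_config.control_step   # 500 Hz at defaults
    if rate_hz > step_hz:
        raise ValueError(
            f"rate {rate_hz} Hz exceeds the {step_hz:.0f} Hz action grid"
        )
    if rate_hz > 0:
        period = int(round(step_hz / rate_hz))
        actions = [1 if k % period == 0 else 0 for k in range(protocol.n_steps)]
        realized = step_hz / period
    else:
        actions = [0] * protocol.n_steps
        realized = 0.0
    traces = []
    for seed in protocol.seeds:
        env = make_env(replace(env_config, seed=seed))
        traces.append(greedy_rollout(None, env, protocol.n_steps,
                                     forced_actions=actions))
    return _report_from_traces(traces, protocol.seeds,
                               rate_hz=rate_hz, realized_hz=realized)


_ABLATION_ARMS = {
    "baseline":    {"predictive": False, "exploration": "epsilon"},
    "baseline_pm": {"predictive": True, "exploration": "epsilon"},
    "baseline_gs": {"predictive": False, "exploration": "gumbel"},
    "sea_dbs":     {"predictive": True, "exploration": "gumbel"},
}


def run_ablations(config: TrainConfig, eval_steps: int = 10) -> dict:
    """Train the 2x2 {predictive, Gumbel-Softmax} grid under matched seeds.

    Returns {arm: (TrainResult, EvalReport)} where the report traces the
    greedy policy over ``eval_steps`` post-training stimulation steps.
    """
    out = {}
    for arm, flags in _ABLATION_ARMS.items():
        cfg = replace(config, **flags)
        result = train(cfg)
        env = make_env(replace(config.env, seed=config.seed + 7919))
        tr = greedy_rollout(result.agent, env, eval_steps)
        report = _report_from_traces([tr], [config.seed], arm=arm, **flags)
        out[arm] = (result, report)
    return out


def quantize_agent(agent: SEADBSAgent) -> SEADBSAgent:
    """Deep copy with every network's parameters cast to float16 storage."""
    q = copy.deepcopy(agent)
    for name, net in q.networks.items():
        with np.errstate(over="ignore"):  # out-of-range values checked below
            cast = net.astype(np.float16)
        bad = [i for i, w in enumerate(cast.W) if not np.all(np.isfinite(w))]
        bad += [i for i, b in enumerate(cast.b) if not np.all(np.isfinite(b))]
        if bad:
            raise FloatingPointError(
                f"non-finite values after FP16 cast in {name}, layer(s) {bad}"
            )
        setattr(q, name, cast)
    return q


def ptq_fp16(agent: SEADBSAgent, *, probe_size: int = 1000,
             probe_seed: int = 0, env_config: EnvConfig | None = None,
             eval_steps: int = 300, eval_seeds=(0, 1, 2)) -> tuple:
    """Post-training FP16 quantization with fidelity measurements.

    Returns ``(quantized_agent, report)`` where the report's extras carry
    parameter byte counts (exactly halved), greedy-action agreement on a
    fixed probe set of observation vectors, and — when ``env_config`` is
    given — closed-loop mean-beta comparison on matched seeds.
    """
    q = quantize_agent(agent)
    bytes_full = agent.parameter_bytes
    bytes_half = q.parameter_bytes

    rng = np.random.default_rng(probe_seed)
    probes = rng.uniform(0.0, 0.7, size=(probe_size, agent.obs_dim))
    a_full = np.array([agent.greedy_action(p) for p in probes])
    a_half = np.array([q.greedy_action(p) for p in probes])
    agreement = float(np.mean(a_full == a_half))

    extras = {
        "bytes_full": bytes_full,
        "bytes_half": bytes_half,
        "agreement": agreement,
    }
    traces = []
    if env_config is not None:
        betas = {}
        for tag, pol in (("full", agent), ("fp16", q)):
            per_seed = []
            for seed in eval_seeds:
                env = make_env(replace(env_config, seed=seed))
                df = greedy_rollout(pol, env, eval_steps)
                df["policy"] = tag
                df["seed"] = seed
                traces.append(df)
                per_seed.append(df["mean_beta"].mean())
            betas[tag] = float(np.mean(per_seed))
        extras["mean_beta_full"] = betas["full"]
        extras["mean_beta_fp16"] = betas["fp16"]
        extras["beta_rel_delta"] = abs(
            betas["fp16"] - betas["full"]) / max(betas["full"], 1e-12)
    all_df = (pd.concat(traces, ignore_index=True)
              if traces else pd.DataFrame())
    report = EvalReport(
        avg_beta=extras.get("mean_beta_fp16", float("nan")),
        avg_reward=float(all_df[all_df.get("policy", "") == "fp16"]["reward"].mean())
        if len(all_df) else float("nan"),
        traces=all_df, extras=extras,
    )
    return q, report
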