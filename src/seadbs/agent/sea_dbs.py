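"""The sample-efficient actor-critic DBS controller.

A DDPG-style learner over a binary stimulate/don't-stimulate action space,
augmented with (i) a predictive reward model f(s, a) whose estimate is added
into the critic's bootstrap target, and (ii) Gumbel-Softmax exploration whose
temperature anneals over training.  Disabling both recovers the plain DDPG
baseline with epsilon-greedy exploration.

Update rules per environment step (after a warm-up):
  critic     minimises MSE(Q(s,a), r + r_hat + gamma * Q'(s', pi'(s')))
  actor      maximises the critic's value of its own (relaxed) action
  predictor  minimises MSE(f(s,a), r)
followed by Polyak soft updates of both target networks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .gumbel import GumbelExplorationState, gs_backward, gs_sample, sample_gumbel
from .nn import MLP, Adam
from .replay import ReplayBuffer, Transition

__all__ = ["Hyperparams", "SEADBSAgent", "fit_reward_predictor"]

_TARGET_REWARD_MODES = ("sum", "real_only", "predicted_only", "mean")


@dataclass(frozen=True)
class Hyperparams:
    """Training hyperparameters (actor/critic rates, discount, batch)."""

    actor_lr: float = 5e-4
    critic_lr: float = 1e-3
    predictor_lr: float = 1e-3
    gamma: float = 0.99
    batch_size: int = 32
    buffer_capacity: int = 8192
    hidden: tuple = (128, 128)
    rho_soft: float = 0.005
    warmup: int = 128
    target_reward_mode: str = "sum"
    # epsilon-greedy schedule for the baseline configuration
    eps0: float = 1.0
    eps_min: float = 0.05
    eps_decay: float = 1e-3

    def __post_init__(self) -> None:
        if not (0 <= self.gamma < 1):
            raise ValueError("discount must lie in [0, 1)")
        if self.target_reward_mode not in _TARGET_REWARD_MODES:
            raise ValueError(
                f"target_reward_mode must be one of {_TARGET_REWARD_MODES}"
            )
        if not (0 < self.rho_soft <= 1):
            raise ValueError("rho_soft must lie in (0, 1]")


def _onehot(a: np.ndarray) -> np.ndarray:
    a = np.atleast_1d(np.asarray(a, dtype=int))
    out = np.zeros((a.size, 2), dtype=np.float32)
    out[np.arange(a.size), a] = 1.0
    return out


class SEADBSAgent:
    """Actor, critic, their target copies, and the reward predictor.

    Parameters
    ----------
    obs_dim : int
        Length of the observation-window state vector.
    hp : Hyperparams
    predictive : bool
        If False the reward predictor is disabled (r_hat = 0 everywhere) and
        the Q-target reduces to the standard DDPG bootstrap.
    exploration : {'gumbel', 'epsilon'}
        Gumbel-Softmax with annealed temperature, or the baseline's
        epsilon-greedy over the two actions.
    seed : int
        Seeds two independent streams: network initialisation and
        exploration/minibatch noise.
    """

    def __init__(self, obs_dim: int = 5, hp: Hyperparams = Hyperparams(), *,
                 predictive: bool = True, exploration: str = "gumbel",
                 seed: int = 0,
                 gs: GumbelExplorationState | None = None):
        if exploration not in ("gumbel", "epsilon"):
            raise ValueError(f"unknown exploration mode {exploration!r}")
        self.obs_dim = int(obs_dim)
        self.hp = hp
        self.predictive = bool(predictive)
        self.exploration = exploration
        init_ss, expl_ss = np.random.SeedSequence(seed).spawn(2)
        init_rng = np.random.default_rng(init_ss)
        self.rng = np.random.default_rng(expl_ss)

        h = tuple(hp.hidden)
        self.actor = MLP((obs_dim, *h, 2), init_rng)
        self.critic = MLP((obs_dim + 2, *h, 1), init_rng)
        self.predictor = MLP((obs_dim + 2, *h, 1), init_rng)
        self.target_actor = self.actor.clone()
        self.target_critic = self.critic.clone()

        self.opt_actor = Adam(self.actor, hp.actor_lr)
        self.opt_critic = Adam(self.critic, hp.critic_lr)
        self.opt_predictor = Adam(self.predictor, hp.predictor_lr)

        self.gs = gs if gs is not None else GumbelExplorationState()
        self.eps_t = 0
        self.buffer = ReplayBuffer(hp.buffer_capacity, obs_dim)
        self.updates = 0

    # -- acting ------------------------------------------------------------
    def logits(self, obs: np.ndarray) -> np.ndarray:
        return self.actor.forward(np.atleast_2d(obs), cache=False)[0].astype(float)

    def select_action(self, obs: np.ndarray, explore: bool = True):
        """Pick a binary action; returns (a, logits, relaxed probabilities).

        Exploring with Gumbel-Softmax advances the temperature schedule by
        one step; the hard action is the argmax of the relaxed sample (which
        coincides with argmax(logits + gumbel noise), i.e. an exact draw from
        softmax(logits)).
        """
        lg = self.logits(obs)
        if not explore:
            a = int(np.argmax(lg))
            return a, lg, _onehot(a)[0]
        if self.exploration == "gumbel":
            tau = self.gs.step()
            g = sample_gumbel(self.rng.uniform(size=2))
            a_tilde = gs_sample(lg, tau, g)
            return int(np.argmax(a_tilde)), lg, a_tilde
        # epsilon-greedy baseline
        eps = max(self.hp.eps_min, self.hp.eps0 * np.exp(-self.hp.eps_decay * self.eps_t))
        self.eps_t += 1
        if self.rng.uniform() < eps:
            a = int(self.rng.integers(2))
        else:
            a = int(np.argmax(lg))
        return a, lg, _onehot(a)[0]

    def greedy_action(self, obs: np.ndarray) -> int:
        return int(np.argmax(self.logits(obs)))

    # -- reward prediction ---------------------------------------------------
    def predict_reward(self, obs: np.ndarray, a: int) -> float:
        """Predictor estimate r_hat = f(s, a); 0 when the predictor is off."""
        if not self.predictive:
            return 0.0
        x = np.concatenate([np.asarray(obs, dtype=np.float32), _onehot(a)[0]])
        return float(self.predictor.forward(x[None], cache=False)[0, 0])

    # -- learning ------------------------------------------------------------
    def q_target(self, batch: dict) -> np.ndarray:
        """Bootstrap targets r (+ r_hat) + gamma * Q'(s', pi'(s')); no grad."""
        s_next = batch["s_next"]
        tl = self.target_actor.forward(s_next, cache=False)
        a_next = _onehot(np.argmax(tl, axis=1))
        qn = self.target_critic.forward(
            np.concatenate([s_next, a_next], axis=1), cache=False
        )[:, 0]
        mode = self.hp.target_reward_mode
        r, rh = batch["r"].astype(float), batch["r_hat"].astype(float)
        if not self.predictive:
            rh = np.zeros_like(rh)
        if mode == "sum":
            base = r + rh
        elif mode == "real_only":
            base = r
        elif mode == "predicted_only":
            base = rh
        else:  # mean
            base = 0.5 * (r + rh)
        return base + self.hp.gamma * qn.astype(float)

    def store(self, tr: Transition) -> None:
        self.buffer.add(tr)

    def update(self, batch: dict | None = None) -> dict | None:
        """One gradient step on critic, actor and predictor + soft updates.

        Returns per-network losses, or None if the buffer is still below the
        warm-up size (the update is skipped).
        """
        hp = self.hp
        if batch is None:
            if len(self.buffer) < max(hp.batch_size, hp.warmup):
                return None
            batch = self.buffer.sample(hp.batch_size, self.rng)
        s, a = batch["s"], batch["a"]
        bsz = s.shape[0]
        losses = {}

        # critic
        target = self.q_target(batch)
        xa = np.concatenate([s, _onehot(a)], axis=1)
        q = self.critic.forward(xa)[:, 0]
        err = q.astype(float) - target
        losses["critic"] = float(np.mean(err**2))
        self.critic.backward((2.0 * err / bsz)[:, None])
        self.opt_critic.step()

        # actor: maximise Q(s, relaxed pi(s))
        lg = self.actor.forward(s)
        if self.exploration == "gumbel":
            tau = self.gs.tau
            noise = sample_gumbel(self.rng.uniform(size=lg.shape))
            a_pi = gs_sample(lg, tau, noise)
        else:
            tau = 1.0
            a_pi = gs_sample(lg, 1.0, np.zeros_like(lg))  # plain softmax
        x_pi = np.concatenate([s, a_pi.astype(np.float32)], axis=1)
        q_pi = self.critic.forward(x_pi)[:, 0]
        losses["actor"] = float(-np.mean(q_pi))
        g_x = self.critic.backward(np.full((bsz, 1), -1.0 / bsz))
        g_logits = gs_backward(g_x[:, self.obs_dim:], a_pi, tau)
        self.actor.backward(g_logits)
        self.opt_actor.step()

        # reward predictor
        if self.predictive:
            rp = self.predictor.forward(xa)[:, 0]
            perr = rp.astype(float) - batch["r"].astype(float)
            losses["predictor"] = float(np.mean(perr**2))
            self.predictor.backward((2.0 * perr / bsz)[:, None])
            self.opt_predictor.step()
        else:
            losses["predictor"] = 0.0

        # soft target updates
        self.target_actor.copy_from(self.actor, hp.rho_soft)
        self.target_critic.copy_from(self.critic, hp.rho_soft)
        self.updates += 1
        return losses

    # -- persistence -----------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint every network, optimizer, schedule and RNG state."""
        d = {}
        for name in ("actor", "critic", "predictor", "target_actor", "target_critic"):
            d.update(getattr(self, name).state_dict(prefix=name + "."))
        for name in ("opt_actor", "opt_critic", "opt_predictor"):
            d.update(getattr(self, name).state_dict(prefix=name + "."))
        meta = {
            "obs_dim": self.obs_dim,
            "predictive": self.predictive,
            "exploration": self.exploration,
            "hp": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(self.hp).items()},
            "gs": vars(self.gs),
            "eps_t": self.eps_t,
            "updates": self.updates,
            "rng": self.rng.bit_generator.state,
        }
        d["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **d)

    @classmethod
    def load(cls, path) -> "SEADBSAgent":
        with np.load(path) as z:
            d = {k: z[k] for k in z.files}
        meta = json.loads(bytes(d.pop("meta")).decode())
        hp = Hyperparams(**{k: (tuple(v) if k == "hidden" else v)
                            for k, v in meta["hp"].items()})
        agent = cls(meta["obs_dim"], hp, predictive=meta["predictive"],
                    exploration=meta["exploration"], seed=0,
                    gs=GumbelExplorationState(**meta["gs"]))
        for name in ("actor", "critic", "predictor", "target_actor", "target_critic"):
            getattr(agent, name).load_state_dict(d, prefix=name + ".")
        for name in ("opt_actor", "opt_critic", "opt_predictor"):
            getattr(agent, name).load_state_dict(d, prefix=name + ".")
        agent.eps_t = int(meta["eps_t"])
        agent.updates = int(meta["updates"])
        agent.rng.bit_generator.state = meta["rng"]
        return agent

    # -- introspection ----------------------------------------------------------
    @property
    def networks(self) -> dict:
        return {"actor": self.actor, "critic": self.critic,
                "predictor": self.predictor,
                "target_actor": self.target_actor,
                "target_critic": self.target_critic}

    @property
    def parameter_bytes(self) -> int:
        return int(sum(net.nbytes for net in self.networks.values()))


def fit_reward_predictor(net: MLP, X: np.ndarray, y: np.ndarray, *,
                         epochs: int = 200, batch_size: int = 64,
                         lr: float = 1e-3,
                         rng: np.random.Generator | None = None) -> float:
    """Supervised minibatch fit of a predictor network to reward labels.

    Returns the final full-batch MSE.  Used for offline predictor training
    and for checking that the predictor family can recover the reward
    surface from labelled (state, action) pairs.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.float64)
    # train against standardised targets, then fold the affine rescale back
    # into the linear output layer (exactly equivalent network on raw units)
    mu, sd = float(y.mean()), float(y.std() + 1e-12)
    z = (y - mu) / sd
    opt = Adam(net, lr)
    n = X.shape[0]
    polish = max(1, epochs // 4)  # final quarter at a tenth of the rate
    for ep in range(epochs):
        if ep == epochs - polish:
            opt.lr = lr / 10.0
        order = rng.permutation(n)
        for k in range(0, n, batch_size):
            idx = order[k:k + batch_size]
            pred = net.forward(X[idx])[:, 0]
            err = pred.astype(float) - z[idx]
            net.backward((2.0 * err / idx.size)[:, None])
            opt.step()
    net.W[-1] *= np.float32(sd)
    net.b[-1] = (net.b[-1] * sd + mu).astype(net.b[-1].dtype)
    final = net.forward(X, cache=False)[:, 0]
    return float(np.mean((final - y) ** 2))
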