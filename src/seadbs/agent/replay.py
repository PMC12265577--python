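"""FIFO replay buffer over (s, a, logits, r, r_hat, s') transitions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Transition", "ReplayBuffer"]


@dataclass(frozen=True)
class Transition:
    """One step of experience.

    ``s`` and ``s_next`` are observation-window vectors; ``a`` is the binary
    action; ``a_logits`` the actor's two logits at selection time; ``r`` the
    environment reward and ``r_hat`` the predictor's estimate at collection
    time.
    """

    s: np.ndarray
    a: int
    a_logits: np.ndarray
    r: float
    r_hat: float
    s_next: np.ndarray

    def __post_init__(self) -> None:
        if self.a not in (0, 1):
            raise ValueError(f"action must be binary, got {self.a}")
        for name in ("r", "r_hat"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite")


class ReplayBuffer:
    """Fixed-capacity FIFO store with uniform minibatch sampling.

    Sampling is uniform without replacement within a batch; eviction is
    strictly first-in-first-out once capacity is reached.
    """

    def __init__(self, capacity: int = 8192, obs_dim: int = 5):
        self.capacity = int(capacity)
        self.obs_dim = int(obs_dim)
        self._s = np.zeros((self.capacity, obs_dim), dtype=np.float32)
        self._a = np.zeros(self.capacity, dtype=np.int64)
        self._logits = np.zeros((self.capacity, 2), dtype=np.float32)
        self._r = np.zeros(self.capacity, dtype=np.float32)
        self._rhat = np.zeros(self.capacity, dtype=np.float32)
        self._s_next = np.zeros((self.capacity, obs_dim), dtype=np.float32)
        self._head = 0
        self._size = 0

    def __len__(self) -> int:
        return self._size

    def add(self, tr: Transition) -> None:
        i = self._head
        self._s[i] = tr.s
        self._a[i] = tr.a
        self._logits[i] = tr.a_logits
        self._r[i] = tr.r
        self._rhat[i] = tr.r_hat
        self._s_next[i] = tr.s_next
        self._head = (i + 1) % self.capacity
        self._size = min(self._size + 1, self.capacity)

    def sample(self, batch_size: int, rng: np.random.Generator) -> dict:
        """Uniform minibatch as a dict of stacked arrays."""
        if batch_size > self._size:
            raise ValueError(f"batch {batch_size} > buffer size {self._size}")
        idx = rng.choice(self._size, size=batch_size, replace=False)
        return {
            "s": self._s[idx],
            "a": self._a[idx],
            "a_logits": self._logits[idx],
            "r": self._r[idx],
            "r_hat": self._rhat[idx],
            "s_next": self._s_next[idx],
        }
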