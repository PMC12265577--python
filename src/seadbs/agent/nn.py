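"""Minimal dense networks with explicit reverse-mode gradients.

The actor, critic and reward predictor are small multilayer perceptrons; at
this scale a hand-written forward/backward pass over NumPy arrays is fast,
dependency-free and easy to audit.  Parameters are float32 so that FP16
post-training quantisation halves storage exactly.

Layout: ``MLP`` holds a list of (W, b) pairs, `forward` caches layer inputs,
`backward` consumes an output gradient and returns the input gradient while
accumulating parameter gradients in ``grads``.  ``Adam`` is the usual
first-order adaptive-moment optimizer.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam"]

_DTYPE = np.float32


def _relu(x):
    return np.maximum(x, 0.0)


class MLP:
    """Fully connected network with ReLU hidden layers and a linear head.

    Parameters
    ----------
    sizes : sequence of int
        Layer widths, input first, output last, e.g. ``(5, 128, 128, 2)``.
    rng : numpy.random.Generator
        Source for the He-uniform hidden init and the small-uniform head init.
    final_scale : float
        Half-width of the uniform init of the output layer (small values keep
        early Q-estimates and logits near zero, the usual actor-critic init).
    """

    def __init__(self, sizes, rng: np.random.Generator, final_scale: float = 3e-3):
        self.sizes = tuple(int(s) for s in sizes)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for i, (n_in, n_out) in enumerate(zip(self.sizes[:-1], self.sizes[1:])):
            last = i == len(self.sizes) - 2
            if last:
                w = rng.uniform(-final_scale, final_scale, size=(n_in, n_out))
                bb = rng.uniform(-final_scale, final_scale, size=n_out)
            else:
                lim = np.sqrt(6.0 / n_in)
                w = rng.uniform(-lim, lim, size=(n_in, n_out))
                bb = np.zeros(n_out)
            self.W.append(w.astype(_DTYPE))
            self.b.append(bb.astype(_DTYPE))
        self._cache = None
        self.grads = None

    # -- inference ---------------------------------------------------------
    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        """Batch forward pass; ``x`` has shape (B, sizes[0])."""
        x = np.asarray(x, dtype=_DTYPE)
        acts = [x]
        h = x
        n = len(self.W)
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            h = h @ w + b
            if i < n - 1:
                h = _relu(h)
            if cache:
                acts.append(h)
        if cache:
            self._cache = acts
        return h

    __call__ = forward

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        """Backprop ``grad_out`` (B, sizes[-1]) through the cached forward.

        Returns the gradient with respect to the input batch; parameter
        gradients (mean-free: summed over the batch) land in ``self.grads``.
        """
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        acts = self._cache
        g = np.asarray(grad_out, dtype=_DTYPE)
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        for i in range(len(self.W) - 1, -1, -1):
            if i < len(self.W) - 1:
                g = g * (acts[i + 1] > 0)  # through this layer's ReLU
            gW[i] = acts[i].T @ g
            gb[i] = g.sum(axis=0)
            g = g @ self.W[i].T
        self.grads = (gW, gb)
        return g

    # -- parameter plumbing ------------------------------------------------
    @property
    def parameters(self) -> list[np.ndarray]:
        return self.W + self.b

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters))

    @property
    def nbytes(self) -> int:
        return int(sum(p.nbytes for p in self.parameters))

    def copy_from(self, other: "MLP", rho: float = 1.0) -> None:
        """Soft update: p <- rho * p_other + (1 - rho) * p."""
        for p, q in zip(self.parameters, other.parameters):
            p *= _DTYPE(1.0 - rho)
            p += _DTYPE(rho) * q

    def clone(self) -> "MLP":
        out = MLP.__new__(MLP)
        out.sizes = self.sizes
        out.W = [w.copy() for w in self.W]
        out.b = [b.copy() for b in self.b]
        out._cache = None
        out.grads = None
        return out

    def astype(self, dtype) -> "MLP":
        """Copy with parameters cast to ``dtype`` (e.g. float16 for PTQ)."""
        out = self.clone()
        out.W = [w.astype(dtype) for w in out.W]
        out.b = [b.astype(dtype) for b in out.b]
        return out

    def state_dict(self, prefix: str = "") -> dict:
        d = {}
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            d[f"{prefix}W{i}"] = w
            d[f"{prefix}b{i}"] = b
        return d

    def load_state_dict(self, d: dict, prefix: str = "") -> None:
        for i in range(len(self.W)):
            self.W[i] = np.array(d[f"{prefix}W{i}"])
            self.b[i] = np.array(d[f"{prefix}b{i}"])


class Adam:
    """Adaptive-moment estimation over one MLP's parameters."""

    def __init__(self, net: MLP, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p, dtype=np.float64) for p in net.parameters]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in net.parameters]

    def step(self) -> None:
        """Apply the gradients accumulated by the net's last backward()."""
        gW, gb = self.net.grads
        grads = gW + gb
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.net.parameters, grads, self.m, self.v):
            g = np.asarray(g, dtype=np.float64)
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)

    def state_dict(self, prefix: str = "") -> dict:
        d = {f"{prefix}t": np.array(self.t)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            d[f"{prefix}m{i}"] = m
            d[f"{prefix}v{i}"] = v
        return d

    def load_state_dict(self, d: dict, prefix: str = "") -> None:
        self.t = int(d[f"{prefix}t"])
        for i in range(len(self.m)):
            self.m[i] = np.array(d[f"{prefix}m{i}"])
            self.v[i] = np.array(d[f"{prefix}v{i}"])
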