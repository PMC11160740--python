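"""Minimal dense-network machinery: parameter dicts, Adam, residual MLP.

All gradients are hand-derived and checked against finite differences in the
test-suite.  float32 throughout, matching common deep-learning practice;
optimizer state lives alongside the parameters so checkpoints restore the
training trajectory exactly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["linear_init", "Adam", "ResidualMLP"]


def linear_init(rng: np.random.Generator, fan_in: int, fan_out: int):
    """Uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) weight and bias init."""
    bound = 1.0 / np.sqrt(fan_in)
    w = rng.uniform(-bound, bound, size=(fan_in, fan_out)).astype(np.float32)
    b = rng.uniform(-bound, bound, size=(fan_out,)).astype(np.float32)
    return w, b


class Adam:
    """Adam over a dict of named parameter arrays (updates in place)."""

    def __init__(self, params: dict, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            p = self.params[k]
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def state_dict(self) -> dict:
        out = {"t": self.t, "lr": self.lr}
        for k in self.params:
            out[f"m::{k}"] = self.m[k]
            out[f"v::{k}"] = self.v[k]
        return out

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        for k in self.params:
            self.m[k] = np.asarray(state[f"m::{k}"], dtype=np.float32).copy()
            self.v[k] = np.asarray(state[f"v::{k}"], dtype=np.float32).copy()


class ResidualMLP:
    """x -> Linear -> [res block]*depth -> Linear, scalar output.

    Each residual block computes y = relu(x + W_b relu(W_a x + b_a) + b_b).
    The first layer is a plain linear map ``in_dim -> width``; the block
    nonlinearity supplies the activation.  ``backward`` returns parameter
    gradients and the gradient with respect to the input batch.
    """

    def __init__(self, in_dim: int, width: int, depth: int, rng: np.random.Generator):
        self.in_dim = in_dim
        self.width = width
        self.depth = depth
        p = {}
        p["W0"], p["b0"] = linear_init(rng, in_dim, width)
        for i in range(depth):
            p[f"Wa{i}"], p[f"ba{i}"] = linear_init(rng, width, width)
            p[f"Wb{i}"], p[f"bb{i}"] = linear_init(rng, width, width)
        p["Wo"], p["bo"] = linear_init(rng, width, 1)
        self.params = p

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (M, in_dim) float32 -> (M,) float32 (+ activation cache)."""
        p = self.params
        cache = {"x": x}
        h = x @ p["W0"]
        h += p["b0"]
        for i in range(self.depth):
            cache[f"h{i}"] = h
            u = h @ p[f"Wa{i}"]
            u += p[f"ba{i}"]
            np.maximum(u, 0.0, out=u)
            cache[f"u{i}"] = u
            s = u @ p[f"Wb{i}"]
            s += p[f"bb{i}"]
            s += h
            cache[f"s{i}"] = s
            h = np.maximum(s, 0.0)
        cache["hlast"] = h
        out = h @ p["Wo"]
        out += p["bo"]
        out = out[:, 0]
        if want_cache:
            return out, cache
        return out

    def backward(self, cache: dict, grad_out: np.ndarray):
        """Backprop d(loss)/d(out) of shape (M,) -> (param grads, d/d input)."""
        p = self.params
        g = grad_out.astype(np.float32)[:, None]  # (M, 1)
        grads = {}
        h = cache["hlast"]
        grads["Wo"] = h.T @ g
        grads["bo"] = g.sum(axis=0)
        gh = g @ p["Wo"].T
        for i in reversed(range(self.depth)):
            s = cache[f"s{i}"]
            gs = gh * (s > 0)
            grads[f"bb{i}"] = gs.sum(axis=0)
            u = cache[f"u{i}"]
            grads[f"Wb{i}"] = u.T @ gs
            gu = gs @ p[f"Wb{i}"].T
            gu *= u > 0
            grads[f"ba{i}"] = gu.sum(axis=0)
            hi = cache[f"h{i}"]
            grads[f"Wa{i}"] = hi.T @ gu
            gh = gs + gu @ p[f"Wa{i}"].T
        x = cache["x"]
        grads["W0"] = x.T @ gh
        grads["b0"] = gh.sum(axis=0)
        gx = gh @ p["W0"].T
        return grads, gx
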