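"""Minimal numpy MLP core with hand-written backprop.

Provides exactly what the generators and the discrete-time survival network
need: dense ReLU stacks, Adam, inverted dropout, per-example gradient norms
(for DP-SGD clipping) and a mixed sigmoid/per-block-softmax output head for
encoded tabular rows.  Deliberately small: no autograd, no graph.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class MLP:
    """Dense stack: linear → ReLU → … → linear (raw output)."""

    Ws: list = field(default_factory=list)
    bs: list = field(default_factory=list)

    @classmethod
    def create(cls, sizes: list[int], rng: np.random.Generator,
               out_scale: float = 1.0) -> "MLP":
        """He-initialized stack; ``out_scale`` shrinks the final layer's init
        (keeps sigmoid/softmax heads un-saturated at the start of training)."""
        Ws, bs = [], []
        last = len(sizes) - 2
        for i, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            s = np.sqrt(2.0 / n_in) * (out_scale if i == last else 1.0)
            Ws.append(rng.normal(0.0, s, size=(n_in, n_out)))
            bs.append(np.zeros(n_out))
        return cls(Ws, bs)

    @property
    def params(self) -> list[np.ndarray]:
        return self.Ws + self.bs

    def forward(self, x: np.ndarray, dropout: float = 0.0,
                rng: np.random.Generator | None = None):
        """Returns (output, cache).  Dropout (inverted) on hidden activations."""
        acts = [x]
        masks = []
        h = x
        last = len(self.Ws) - 1
        for i, (W, b) in enumerate(zip(self.Ws, self.bs)):
            z = h @ W + b
            if i < last:
                h = relu(z)
                if dropout > 0.0:
                    m = (rng.uniform(size=h.shape) >= dropout) / (1.0 - dropout)
                    h = h * m
                    masks.append(m)
                else:
                    masks.append(None)
                acts.append(h)
            else:
                h = z
        return h, (acts, masks)

    def backward(self, cache, grad_out: np.ndarray):
        """Mean-over-batch gradients; returns (grads_W, grads_b, grad_input)."""
        acts, masks = cache
        B = grad_out.shape[0]
        delta = grad_out
        gW = [None] * len(self.Ws)
        gb = [None] * len(self.bs)
        for i in range(len(self.Ws) - 1, -1, -1):
            a = acts[i]
            gW[i] = a.T @ delta / B
            gb[i] = delta.mean(axis=0)
            if i > 0:
                delta = delta @ self.Ws[i].T
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
                delta = delta * (acts[i] > 0)
        grad_input = delta @ self.Ws[0].T
        return gW, gb, grad_input

    def backward_dp(self, cache, grad_out: np.ndarray, clip_norm: float,
                    noise_sigma: float, rng: np.random.Generator):
        """DP-SGD gradients: per-example clipping at ``clip_norm`` then
        Gaussian noise N(0, (noise_sigma·clip_norm)²) on the sum, divided by B."""
        acts, _ = cache
        B = grad_out.shape[0]
        # collect per-layer deltas (batch kept)
        deltas = [None] * len(self.Ws)
        delta = grad_out
        for i in range(len(self.Ws) - 1, -1, -1):
            deltas[i] = delta
            if i > 0:
                delta = (delta @ self.Ws[i].T) * (acts[i] > 0)
        # per-example squared norms: |outer(a, d)|^2 = |a|^2 |d|^2 ; bias |d|^2
        sq = np.zeros(B)
        for i in range(len(self.Ws)):
            a2 = (acts[i] ** 2).sum(axis=1)
            d2 = (deltas[i] ** 2).sum(axis=1)
            sq += a2 * d2 + d2
        norms = np.sqrt(sq)
        scale = np.minimum(1.0, clip_norm / np.maximum(norms, 1e-12))
        gW, gb = [], []
        for i in range(len(self.Ws)):
            a_s = acts[i] * scale[:, None]
            gw = a_s.T @ deltas[i]
            gbv = (deltas[i] * scale[:, None]).sum(axis=0)
            gw += rng.normal(0.0, noise_sigma * clip_norm, size=gw.shape)
            gbv += rng.normal(0.0, noise_sigma * clip_norm, size=gbv.shape)
            gW.append(gw / B)
            gb.append(gbv / B)
        return gW, gb


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class TabularHead:
    """Maps raw MLP outputs to encoded rows: sigmoid for continuous/binary
    columns, Gumbel-softmax (temperature ``tau``) within each one-hot block.

    The Gumbel reparametrization keeps categorical outputs near the one-hot
    corners the discriminator sees in real data while category *frequencies*
    stay controlled by moderate logits — this avoids the irreversible softmax
    saturation a plain-softmax head collapses into.  Block logits are also
    squashed through ``bound * tanh(logit / bound)`` before the softmax so
    logit differences stay bounded and any collapse remains recoverable."""

    def __init__(self, d: int, onehot_blocks: list[slice], tau: float = 0.6,
                 bound: float = 2.5):
        self.d = d
        self.blocks = onehot_blocks
        self.tau = tau
        self.bound = bound
        in_block = np.zeros(d, bool)
        for sl in onehot_blocks:
            in_block[sl] = True
        self.scalar_cols = ~in_block

    def forward(self, raw: np.ndarray, rng: np.random.Generator | None = None):
        """Returns (out, cache).  Gumbel-softmax blocks when ``rng`` is given,
        plain softmax otherwise."""
        out = np.empty_like(raw)
        out[:, self.scalar_cols] = sigmoid(raw[:, self.scalar_cols])
        tanh_terms = {}
        for sl in self.blocks:
            t = np.tanh(raw[:, sl] / self.bound)
            u = self.bound * t
            tanh_terms[(sl.start, sl.stop)] = t
            if rng is not None:
                u = (u + rng.gumbel(size=u.shape)) / self.tau
            out[:, sl] = softmax(u, axis=1)
        return out, (tanh_terms, rng is not None)

    def backward(self, cache, out: np.ndarray, grad_out: np.ndarray) -> np.ndarray:
        """d loss / d raw given d loss / d transformed output."""
        tanh_terms, sampled = cache
        grad = np.empty_like(grad_out)
        s = out[:, self.scalar_cols]
        grad[:, self.scalar_cols] = grad_out[:, self.scalar_cols] * s * (1 - s)
        inv_tau = 1.0 / self.tau if sampled else 1.0
        for sl in self.blocks:
            p = out[:, sl]
            g = grad_out[:, sl]
            gb = inv_tau * p * (g - (p * g).sum(axis=1, keepdims=True))
            grad[:, sl] = gb * (1.0 - tanh_terms[(sl.start, sl.stop)] ** 2)
        return grad

    def harden(self, out: np.ndarray) -> np.ndarray:
        """Exact one-hot per block (argmax; on Gumbel-softmax output this is
        an exact categorical draw from the softmax probabilities)."""
        hard = out.copy()
        for sl in self.blocks:
            p = out[:, sl]
            c = np.argmax(p, axis=1)
            block = np.zeros_like(p)
            block[np.arange(p.shape[0]), c] = 1.0
            hard[:, sl] = block
        return hard
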