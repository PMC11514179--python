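"""Desk-scale discrete-time deep survival model.

A dropout MLP maps covariates to a softmax over discrete time bins (20
equal-quantile bins of observed times by default).  The loss mixes the
discrete-time likelihood with a pairwise ranking term,

    L = alpha * L_NLL + (1 - alpha) * L_rank,

where an event contributes the probability mass at its bin, a censored
subject the survivor mass past its bin, and L_rank averages
exp((F(t_i|x_j) - F(t_i|x_i)) / sigma) over comparable within-batch pairs
(i failed before j's observed time).  alpha, sigma and the dropout rate are
the three hyperparameters that matter most for this model family; batch
size, hidden width, learning rate and early-stopping patience are generic.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines.utils import concordance_index

from .nn import MLP, Adam, softmax


@dataclass
class SurvNetConfig:
    alpha: float = 0.5          # likelihood vs ranking mix, in [0, 1]
    sigma: float = 0.25         # ranking kernel scale, > 0
    dropout: float = 0.1        # hidden-layer dropout, in [0, 1)
    batch_size: int = 128
    hidden_dim: int = 32
    learning_rate: float = 1e-3
    patience: int = 5           # early stopping on validation loss (epochs)
    time_bins: int = 20
    max_epochs: int = 60
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.time_bins < 2:
            raise ValueError("need >= 2 time bins")


@dataclass
class SurvNet:
    net: MLP
    bin_edges: np.ndarray    # len time_bins - 1 interior quantile edges
    config: SurvNetConfig

    def bin_index(self, t: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.bin_edges, t, side="right")

    def predict_cif(self, x: np.ndarray, horizon: float) -> np.ndarray:
        """Predicted cumulative incidence F̂(horizon | x)."""
        logits, _ = self.net.forward(np.asarray(x, float))
        p = softmax(logits, axis=1)
        k = int(np.searchsorted(self.bin_edges, horizon, side="right"))
        return p[:, : k + 1].sum(axis=1)


def _loss_and_grad(p: np.ndarray, k: np.ndarray, e: np.ndarray,
                   alpha: float, sigma: float):
    """Mixed loss and its gradient w.r.t. the softmax probabilities."""
    B, nbins = p.shape
    eps = 1e-10
    g = np.zeros_like(p)
    # likelihood part
    ev = e == 1
    nll = 0.0
    if ev.any():
        pk = p[ev, k[ev]]
        nll -= np.log(pk + eps).sum()
        g[ev, k[ev]] -= alpha / (pk + eps) / B
    cs = ~ev
    if cs.any():
        kc = np.minimum(k[cs], nbins - 2)
        past = np.zeros(cs.sum())
        mask = np.arange(nbins)[None, :] > kc[:, None]
        past = (p[cs] * mask).sum(axis=1)
        nll -= np.log(past + eps).sum()
        g[cs] -= alpha * mask / (past + eps)[:, None] / B
    nll /= B
    # ranking part: anchors i with event, partners j observed later
    F = np.cumsum(p, axis=1)
    rank_loss = 0.0
    if alpha < 1.0 and ev.any():
        ki = k
        Fi = F[np.arange(B), ki]                       # F(t_i | x_i)
        Fj_at_i = F[:, ki]                             # (j, i): F(t_i | x_j)
        # comp[i, j] True when i is an event anchor and j's bin is later
        comp = ev[:, None] & (k[None, :] > k[:, None])
        if comp.any():
            diff = (Fj_at_i.T - Fi[:, None]) / sigma   # (i, j)
            eta = np.exp(np.clip(diff, -50, 50)) * comp
            npairs = comp.sum()
            rank_loss = eta.sum() / npairs
            w = eta / sigma / npairs                    # dL/dF_j(t_i), per pair
            dF = np.zeros_like(p)                       # accumulate dL/dF(b)
            # for each anchor i: +w[i, j] on F_j(k_i); −sum_j w[i, j] on F_i(k_i)
            for i in np.flatnonzero(ev):
                wi = w[i]
                if not wi.any():
                    continue
                dF[:, ki[i]] += wi * (1 - alpha)
                dF[i, ki[i]] -= wi.sum() * (1 - alpha)
            # chain through F = cumsum(p): dL/dp_b = sum_{b' >= b} dF_{b'}
            g += np.cumsum(dF[:, ::-1], axis=1)[:, ::-1]
    return alpha * nll + (1 - alpha) * rank_loss, g


def _softmax_backprop(p: np.ndarray, grad_p: np.ndarray) -> np.ndarray:
    return p * (grad_p - (p * grad_p).sum(axis=1, keepdims=True))


def train_survnet(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                  config: SurvNetConfig,
                  val: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
                  ) -> SurvNet:
    """Train with early stopping on validation loss (an internal 80:20 split
    if ``val`` is not supplied).  Deterministic given the config seed."""
    config.validate()
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    rng = np.random.default_rng(config.seed)
    if val is None:
        n = len(x)
        perm = rng.permutation(n)
        n_tr = int(round(0.8 * n))
        tr, va = perm[:n_tr], perm[n_tr:]
        val = (x[va], time[va], event[va])
        x, time, event = x[tr], time[tr], event[tr]
    edges = np.quantile(time, np.linspace(0, 1, config.time_bins + 1)[1:-1])
    net = MLP.create([x.shape[1], config.hidden_dim, config.time_bins], rng,
                     out_scale=0.1)
    model = SurvNet(net, edges, config)
    k = model.bin_index(time)
    kv = model.bin_index(val[1])
    ev_val = np.asarray(val[2], int)
    opt = Adam(net.params, lr=config.learning_rate)
    n = len(x)
    B = min(config.batch_size, n)
    steps = max(1, n // B)
    best, best_params, wait = np.inf, None, 0
    if (event == 1).sum() == 0:
        raise ValueError("no events in training data (empty risk sets)")
    for _ in range(config.max_epochs):
        for _ in range(steps):
            idx = rng.choice(n, size=B, replace=False)
            logits, cache = net.forward(x[idx], dropout=config.dropout, rng=rng)
            p = softmax(logits, axis=1)
            loss, gp = _loss_and_grad(p, k[idx], event[idx], config.alpha, config.sigma)
            if not np.isfinite(loss):
                raise RuntimeError("NaN/inf loss during training")
            glogit = _softmax_backprop(p, gp * B)  # _loss_and_grad already /B
            gW, gb, _ = net.backward(cache, glogit)
            opt.step(net.params, gW + gb)
        logits, _ = net.forward(val[0])
        p = softmax(logits, axis=1)
        vloss, _ = _loss_and_grad(p, kv, ev_val, config.alpha, config.sigma)
        if vloss < best - 1e-5:
            best, wait = vloss, 0
            best_params = [w.copy() for w in net.Ws], [b.copy() for b in net.bs]
        else:
            wait += 1
            if wait >= config.patience:
                break
    if best_params is not None:
        net.Ws, net.bs = best_params
    return model


def validation_cindex(model: SurvNet, x: np.ndarray, time: np.ndarray,
                      event: np.ndarray, horizon: float | None = None) -> float:
    """Concordance of predicted cumulative incidence (higher = riskier)."""
    horizon = horizon if horizon is not None else float(np.median(time))
    risk = model.predict_cif(x, horizon)
    return float(concordance_index(time, -risk, event))
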