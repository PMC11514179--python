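"""Differential-privacy accounting for the generators.

Two accountants are provided:

* :func:`epsilon_dpsgd` — Rényi-DP accounting for DP-SGD: the data-independent
  upper bound on the Rényi divergence of the subsampled Gaussian mechanism at
  integer orders, composed linearly over steps and converted to (ε, δ).
* :func:`compose_pate` — a deliberately conservative pure-DP bound for noisy
  teacher-vote aggregation: each Laplace(1/λ)-perturbed vote release is 2λ-DP
  (vote-count sensitivity 1 per teacher, two counts change), composed basically.
  This is an upper bound, not the data-dependent moments accountant.

Both drive the :class:`PrivacyLedger` that generator training updates step by
step; training must halt before the spent ε exceeds the budget.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.special import gammaln, logsumexp

RDP_ORDERS = tuple(range(2, 65))


def _log_binom(n: int, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rdp_subsampled_gaussian(q: float, sigma: float, alpha: int) -> float:
    """Per-step Rényi-DP cost of the Poisson-subsampled Gaussian at integer order.

    Uses the binomial-expansion upper bound
    (1/(α−1)) log Σ_k C(α,k) (1−q)^{α−k} q^k exp(k(k−1)/(2σ²)),
    which is exact for q = 1 (plain Gaussian mechanism: α/(2σ²)).
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if alpha < 2:
        raise ValueError("alpha must be >= 2")
    if q == 1.0:
        return alpha / (2.0 * sigma**2)
    k = np.arange(alpha + 1)
    log_terms = (
        _log_binom(alpha, k)
        + (alpha - k) * np.log1p(-q)
        + k * np.log(q)
        + k * (k - 1) / (2.0 * sigma**2)
    )
    return float(logsumexp(log_terms) / (alpha - 1))


def epsilon_dpsgd(q: float, sigma: float, steps: int, delta: float,
                  orders: Iterable[int] = RDP_ORDERS) -> float:
    """(ε, δ)-DP guarantee of ``steps`` DP-SGD iterations at sampling rate ``q``.

    ε = min over orders α of [steps · RDP(α) + log(1/δ)/(α−1)].
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if not 0 < delta < 1:
        raise ValueError("delta must be in (0, 1)")
    eps = [steps * rdp_subsampled_gaussian(q, sigma, a) + np.log(1.0 / delta) / (a - 1)
           for a in orders]
    return float(min(eps))


def calibrate_sigma(q: float, steps: int, delta: float, target_epsilon: float,
                    sigma_min: float = 0.3, sigma_max: float = 1e4,
                    rtol: float = 1e-3) -> float:
    """Smallest noise multiplier (within ``rtol``) meeting the ε budget.

    Binary search on the monotone map σ → ε.  Raises if the budget is
    unattainable even at ``sigma_max``.
    """
    if target_epsilon <= 0:
        raise ValueError("target_epsilon must be > 0")
    if epsilon_dpsgd(q, sigma_max, steps, delta) > target_epsilon:
        raise ValueError("privacy budget unattainable at sigma_max")
    if epsilon_dpsgd(q, sigma_min, steps, delta) <= target_epsilon:
        return sigma_min
    lo, hi = sigma_min, sigma_max
    while hi / lo > 1 + rtol:
        mid = np.sqrt(lo * hi)
        if epsilon_dpsgd(q, mid, steps, delta) <= target_epsilon:
            hi = mid
        else:
            lo = mid
    return float(hi)


def compose_pate(laplace_lambda: float, n_queries: int) -> float:
    """Basic composition of 2λ-DP noisy-vote queries: ε = 2λ·n_queries."""
    if laplace_lambda <= 0:
        raise ValueError("laplace_lambda must be > 0")
    if n_queries < 0:
        raise ValueError("n_queries must be >= 0")
    return 2.0 * laplace_lambda * n_queries


@dataclass
class PrivacyLedger:
    """Running (ε, δ) account attached to a generator training run."""

    method: str
    delta: float | None = None
    epsilon_spent: float = 0.0
    steps: int = 0
    per_step_log: list = field(default_factory=list)
    note: str = ""

    def log_dpsgd_step(self, q: float, sigma: float) -> None:
        self.steps += 1
        self.per_step_log.append({"q": q, "sigma": sigma, "count": 1})
        eps = epsilon_dpsgd(q, sigma, self.steps, self.delta)
        if eps < self.epsilon_spent - 1e-12:
            raise RuntimeError("epsilon accounting must be nondecreasing")
        self.epsilon_spent = eps

    def log_pate_queries(self, laplace_lambda: float, count: int) -> None:
        self.steps += 1
        self.per_step_log.append({"lambda": laplace_lambda, "count": count})
        # recompute from the cumulative count (one multiply) so repeated
        # additions cannot drift above the budget by accumulated rounding
        total = sum(e["count"] for e in self.per_step_log)
        self.epsilon_spent = compose_pate(laplace_lambda, total)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "delta": self.delta,
            "epsilon_spent": self.epsilon_spent,
            "steps": self.steps,
            "note": self.note,
            "per_step_log": list(self.per_step_log),
        }
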