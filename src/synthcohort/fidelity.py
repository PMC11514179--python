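"""Distributional fidelity metrics for synthetic tables.

Per-variable descriptives (the side-by-side cohort table), Gaussian-KDE
marginal curves, per-feature 1-D Wasserstein distances and Jensen-Shannon
divergences, and the three-part generative-model scorecard: α-precision
(fidelity), β-recall (diversity) and authenticity (non-memorization).

The precision/recall/authenticity triple is computed in the normalized
encoded feature space with Euclidean distances — a deliberately
embedding-free rendering of those metrics' definitions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import jensenshannon
from sklearn.neighbors import NearestNeighbors

from .schema import Cohort


@dataclass
class FidelityReport:
    descriptive: dict
    wasserstein_per_feature: dict
    wasserstein_mean: float
    jsd_per_feature: dict
    jsd_mean: float
    alpha_precision_delta: float
    beta_recall_delta: float
    authenticity: float

    def to_dict(self) -> dict:
        return {
            "descriptive": self.descriptive,
            "wasserstein_per_feature": self.wasserstein_per_feature,
            "wasserstein_mean": self.wasserstein_mean,
            "jsd_per_feature": self.jsd_per_feature,
            "jsd_mean": self.jsd_mean,
            "alpha_precision_delta": self.alpha_precision_delta,
            "beta_recall_delta": self.beta_recall_delta,
            "authenticity": self.authenticity,
        }


def describe_table(cohort: Cohort) -> dict:
    """Table-1-style summary: continuous → (mean, SD); categorical/binary →
    per-level (count, %)."""
    out: dict = {}
    n = cohort.n
    for v in cohort.schema.variables:
        col = cohort.data[v.name]
        if v.vtype in ("continuous", "derived"):
            x = col.to_numpy(float)
            out[v.name] = {"mean": float(x.mean()), "sd": float(x.std(ddof=1))}
        elif v.vtype == "binary":
            k = int((col == 1).sum())
            out[v.name] = {"1": {"n": k, "pct": 100.0 * k / n}}
        else:
            levels = {}
            for c in v.categories:
                k = int((col == c).sum())
                levels[c] = {"n": k, "pct": 100.0 * k / n}
            out[v.name] = levels
    return out


def describe_markdown(real: dict, synths: dict[str, dict]) -> str:
    """Side-by-side markdown table of descriptives (real column last)."""
    names = list(synths)
    lines = ["| Variable | " + " | ".join(names) + " | Real |",
             "|" + "---|" * (len(names) + 2)]

    def fmt(d):
        if "mean" in d:
            return f"{d['mean']:.2f} ({d['sd']:.2f})"
        return " / ".join(f"{lvl}: {v['pct']:.1f}%" for lvl, v in d.items())

    for var in real:
        row = [var] + [fmt(synths[m][var]) for m in names] + [fmt(real[var])]
        lines.append("| " + " | ".join(row) + " |")
    return "\n".join(lines)


def marginal_kde(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Gaussian KDE (Scott bandwidth) evaluated on ``grid``."""
    values = np.asarray(values, float)
    if np.unique(values).size < 2:
        raise ValueError("need >=2 distinct values for a KDE")
    return stats.gaussian_kde(values)(grid)


def wasserstein_1d(a: np.ndarray, b: np.ndarray) -> float:
    """1-D W1 distance (integral of |ECDF difference|)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    return float(stats.wasserstein_distance(a, b))


def wasserstein_matrix(real: np.ndarray, synth: np.ndarray,
                       columns: list[str]) -> tuple[dict, float]:
    per = {c: wasserstein_1d(real[:, j], synth[:, j]) for j, c in enumerate(columns)}
    return per, float(np.mean(list(per.values())))


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence (base 2, in [0, 1]) between two histograms."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape:
        raise ValueError("histograms must share bins")
    return float(jensenshannon(p, q, base=2) ** 2)


def jsd_features(real: np.ndarray, synth: np.ndarray, columns: list[str],
                 n_bins: int = 20) -> tuple[dict, float]:
    """Per-feature JSD on the encoded scale; continuous features binned into
    ``n_bins`` equal-width bins on [0, 1], indicators into 2 bins."""
    per = {}
    for j, c in enumerate(columns):
        r, s = real[:, j], synth[:, j]
        binary = set(np.unique(np.concatenate([r, s]))) <= {0.0, 1.0}
        edges = np.array([-0.5, 0.5, 1.5]) if binary else np.linspace(0, 1, n_bins + 1)
        hr = np.histogram(r, bins=edges)[0].astype(float)
        hs = np.histogram(s, bins=edges)[0].astype(float)
        per[c] = js_divergence(hr / hr.sum(), hs / hs.sum())
    return per, float(np.mean(list(per.values())))


def _coverage_curve(ref: np.ndarray, query: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Fraction of ``query`` points inside the ball centred at ``ref``'s medoid
    with radius the level-quantile of ``ref`` distances-to-medoid."""
    d2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(-1) if len(ref) <= 1500 else None
    if d2 is not None:
        medoid = ref[np.argmin(d2.sum(1))]
    else:  # medoid approximated by distances to the mean's nearest row
        nn = NearestNeighbors(n_neighbors=1).fit(ref)
        medoid = ref[nn.kneighbors(ref.mean(0, keepdims=True))[1][0][0]]
    r_ref = np.sqrt(((ref - medoid) ** 2).sum(1))
    r_query = np.sqrt(((query - medoid) ** 2).sum(1))
    radii = np.quantile(r_ref, grid)
    return (r_query[None, :] <= radii[:, None]).mean(axis=1)


def precision_recall_authenticity(real_encoded: np.ndarray, synth_encoded: np.ndarray,
                                  alpha_grid: np.ndarray | None = None
                                  ) -> tuple[float, float, float]:
    """(ΔP_α, ΔR_β, authenticity) in the encoded space.

    α-precision: fraction of synthetic points inside the α-ball of the real
    medoid; ΔP = 1 − 2·∫|P(α) − α|dα.  β-recall swaps the roles.
    Authenticity: fraction of synthetic points strictly farther from their
    nearest real neighbour than that neighbour is from its own nearest other
    real point (1 = no memorization, 0 = exact copies).
    """
    real = np.asarray(real_encoded, float)
    synth = np.asarray(synth_encoded, float)
    if len(real) < 2:
        raise ValueError("need at least 2 real rows")
    if len(real) < 50 or len(synth) < 50:
        raise ValueError("need >=50 rows per table")
    grid = alpha_grid if alpha_grid is not None else np.linspace(0, 1, 21)
    p_curve = _coverage_curve(real, synth, grid)
    r_curve = _coverage_curve(synth, real, grid)
    dp = 1.0 - 2.0 * np.trapezoid(np.abs(p_curve - grid), grid)
    dr = 1.0 - 2.0 * np.trapezoid(np.abs(r_curve - grid), grid)

    nn_real = NearestNeighbors(n_neighbors=2).fit(real)
    d_rr = nn_real.kneighbors(real)[0][:, 1]
    d_sr, idx = nn_real.kneighbors(synth, n_neighbors=1)
    auth = float(np.mean(d_sr[:, 0] > d_rr[idx[:, 0]]))
    return float(dp), float(dr), auth


def fidelity_report(real: Cohort, synth: Cohort, real_encoded: np.ndarray,
                    synth_encoded: np.ndarray, columns: list[str]) -> FidelityReport:
    w_per, w_mean = wasserstein_matrix(real_encoded, synth_encoded, columns)
    j_per, j_mean = jsd_features(real_encoded, synth_encoded, columns)
    dp, dr, auth = precision_recall_authenticity(real_encoded, synth_encoded)
    return FidelityReport(
        descriptive={"real": describe_table(real), "synthetic": describe_table(synth)},
        wasserstein_per_feature=w_per, wasserstein_mean=w_mean,
        jsd_per_feature=j_per, jsd_mean=j_mean,
        alpha_precision_delta=dp, beta_recall_delta=dr, authenticity=auth,
    )
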