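"""Empirical privacy-risk auditing: k-anonymity and density-ratio
membership inference.

k-anonymity measures reidentification risk: the size of the smallest
equivalence class over (binned) quasi-identifiers.  The membership-inference
score follows the density-ratio recipe: score(x) = p̂_synth(x) / p̂_ref(x),
where both densities are Gaussian KDEs in a PCA-reduced encoded space, and
risk is summarized as the AUROC separating training members from
non-members.  Full-dimensional KDE on one-hot data is degenerate, hence the
PCA reduction; this is an implementation of the score's definition, not of
any particular published estimator.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score

from .schema import Cohort

DEFAULT_QUASI_IDENTIFIERS = ("age", "sex", "ethnicity")


@dataclass
class PrivacyReport:
    k_anonymity: int | None = None
    quasi_identifiers: tuple[str, ...] | None = None
    bins: dict | None = None
    mia_auc: float | None = None
    domias_scores: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "k_anonymity": self.k_anonymity,
            "quasi_identifiers": list(self.quasi_identifiers or []),
            "mia_auc": self.mia_auc,
        }


def k_anonymity(cohort: Cohort, quasi_identifiers=DEFAULT_QUASI_IDENTIFIERS,
                bins: dict | None = None) -> int:
    """Minimum equivalence-class size over the joint binned quasi-identifiers.

    ``bins`` maps a continuous QI name to its bin edges; default is 5-year
    age bins.  Categorical/binary QIs are used as-is.
    """
    if cohort.n == 0:
        raise ValueError("empty cohort")
    bins = dict(bins or {})
    if "age" in quasi_identifiers and "age" not in bins:
        bins["age"] = np.arange(40, 76, 5)
    keys = []
    for q in quasi_identifiers:
        if q not in cohort.data.columns:
            raise KeyError(f"quasi-identifier {q!r} not in cohort")
        col = cohort.data[q]
        v = cohort.schema[q]
        if v.vtype in ("continuous", "derived"):
            if q not in bins:
                raise ValueError(f"continuous quasi-identifier {q!r} needs bin edges")
            keys.append(pd.Series(np.digitize(col.to_numpy(float), bins[q]), name=q))
        else:
            keys.append(col)
    groups = pd.concat(keys, axis=1).groupby([k.name for k in keys], observed=True)
    return int(groups.size().min())


def domias(synth_encoded: np.ndarray, members_encoded: np.ndarray,
           nonmembers_encoded: np.ndarray, reference_encoded: np.ndarray,
           n_components: int = 5, bandwidth_factor: float = 0.05) -> PrivacyReport:
    """Density-ratio membership inference in a PCA(5)-reduced encoded space.

    score(x) = p̂_synth(x) / p̂_ref(x) (Gaussian KDE); ``mia_auc`` is the
    AUROC of members (label 1) vs non-members (label 0).  ``reference`` must
    be population data disjoint from the members.

    The KDE bandwidth is ``bandwidth_factor`` times Scott's rule: the
    memorization signal is a near-point-mass elevation of the synthetic
    density at member records, which the plain Scott bandwidth smooths away
    entirely; the sharpened default reliably separates exact copies
    (AUC ~0.75 at n=2000) while independent synthetic data stays at chance.
    """
    pca = PCA(n_components=n_components).fit(reference_encoded)

    def proj(x):
        return pca.transform(np.asarray(x, float)).T  # (k, n) for gaussian_kde

    def bw(k):
        return k.scotts_factor() * bandwidth_factor

    try:
        kde_synth = stats.gaussian_kde(proj(synth_encoded), bw_method=bw)
        kde_ref = stats.gaussian_kde(proj(reference_encoded), bw_method=bw)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"degenerate KDE (singular covariance): {e}") from e
    pts = np.concatenate([members_encoded, nonmembers_encoded])
    log_ratio = kde_synth.logpdf(proj(pts)) - kde_ref.logpdf(proj(pts))
    labels = np.r_[np.ones(len(members_encoded)), np.zeros(len(nonmembers_encoded))]
    auc = float(roc_auc_score(labels, log_ratio))
    return PrivacyReport(mia_auc=auc, domias_scores=np.exp(log_ratio))
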