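"""Exploratory-analysis transfer: can PCA and K-means models developed on
synthetic data stand in for models developed on the real data?

Three experiments, all scored on held-out real data:
scree profiles (explained variance), probabilistic-PCA test log-likelihood
of a 4-component model, and K-means cluster assignments (BIC curve for
choosing K; ARI/AMI agreement between real-trained and synthetic-trained
clusterings of the same test rows).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_mutual_info_score, adjusted_rand_score


def _canonical_order(x: np.ndarray) -> np.ndarray:
    """Row order invariant to input permutation (lexicographic), so seeded
    K-means gives identical solutions on identical-but-reordered data."""
    return x[np.lexsort(x.T[::-1])]


@dataclass
class EDAReport:
    explained_variance_train: list | None = None
    explained_variance_synth: list | None = None
    ppca_test_loglik: float | None = None
    bic_curve: dict | None = None
    chosen_k: int | None = None
    ari: float | None = None
    ami: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def explained_variance_profile(encoded: np.ndarray) -> np.ndarray:
    """Eigenvalues of the sample covariance, sorted descending, / trace."""
    x = np.asarray(encoded, float)
    cov = np.cov(x, rowvar=False)
    ev = np.linalg.eigvalsh(cov)[::-1]
    ev = np.clip(ev, 0.0, None)
    return ev / ev.sum()


def ppca_transfer_loglik(train_encoded: np.ndarray, test_encoded: np.ndarray,
                         n_components: int = 4) -> float:
    """Average per-sample log-likelihood of ``test`` under a probabilistic
    PCA model fit by maximum likelihood on ``train``.

    The ML solution keeps the top-``n_components`` eigenpairs as loadings and
    sets the isotropic residual variance to the mean of the discarded
    eigenvalues; the test density is N(μ, WWᵀ + σ²I).
    """
    train = np.asarray(train_encoded, float)
    test = np.asarray(test_encoded, float)
    if n_components >= train.shape[1]:
        raise ValueError("n_components must be < number of features")
    pca = PCA(n_components=n_components).fit(train)
    if pca.noise_variance_ <= 0:
        raise ValueError("non-positive residual variance (degenerate train data)")
    return float(pca.score(test))


def kmeans_bic_curve(encoded: np.ndarray, k_range=range(2, 29), seed: int = 0,
                     n_init: int = 10) -> dict[int, float]:
    """BIC of a spherical-Gaussian-mixture reading of the K-means solution.

    BIC = −2 ln L̂ + p ln n with shared variance σ² = SSE/(n·d) and
    p = k·d + k + 1 free parameters (means, mixing weights, variance).
    """
    x = np.asarray(encoded, float)
    n, d = x.shape
    out = {}
    for k in k_range:
        if k >= n:
            raise ValueError(f"k={k} must be < n={n}")
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(_canonical_order(x))
        sse = km.inertia_
        counts = np.bincount(km.labels_, minlength=k).astype(float)
        if (counts == 0).any():
            km = KMeans(n_clusters=k, n_init=n_init, random_state=seed + 1).fit(_canonical_order(x))
            counts = np.bincount(km.labels_, minlength=k).astype(float)
            sse = km.inertia_
            if (counts == 0).any():
                raise RuntimeError(f"empty cluster at k={k} after re-seeded retry")
        sigma2 = max(sse / (n * d), 1e-12)
        loglik = (counts * np.log(counts / n)).sum() \
            - 0.5 * n * d * np.log(2 * np.pi * sigma2) - sse / (2 * sigma2)
        p = k * d + k + 1
        out[k] = float(-2.0 * loglik + p * np.log(n))
    return out


def cluster_transfer_agreement(train_a: np.ndarray, train_b: np.ndarray,
                               test: np.ndarray, n_clusters: int = 15,
                               seed: int = 0, n_init: int = 10
                               ) -> tuple[float, float]:
    """Fit K-means separately on A (oracle source) and B (candidate), assign
    the same test rows under both, and report chance-adjusted agreement
    (ARI, AMI) between the two labelings."""
    if n_clusters < 2:
        raise ValueError("need K >= 2")
    km_a = KMeans(n_clusters=n_clusters, n_init=n_init,
                  random_state=seed).fit(_canonical_order(np.asarray(train_a, float)))
    km_b = KMeans(n_clusters=n_clusters, n_init=n_init,
                  random_state=seed).fit(_canonical_order(np.asarray(train_b, float)))
    la = km_a.predict(test)
    lb = km_b.predict(test)
    ari = float(adjusted_rand_score(la, lb))
    ami = float(adjusted_mutual_info_score(la, lb, average_method="max"))
    return ari, ami


def eda_report(real_train: np.ndarray, synth: np.ndarray, real_test: np.ndarray,
               n_components: int = 4, n_clusters: int = 15, seed: int = 0,
               bic_ks=range(2, 29), include_bic: bool = True) -> EDAReport:
    ari, ami = cluster_transfer_agreement(real_train, synth, real_test,
                                          n_clusters=n_clusters, seed=seed)
    bic = kmeans_bic_curve(synth, bic_ks, seed=seed) if include_bic else None
    return EDAReport(
        explained_variance_train=list(map(float, explained_variance_profile(real_train))),
        explained_variance_synth=list(map(float, explained_variance_profile(synth))),
        ppca_test_loglik=ppca_transfer_loglik(synth, real_test, n_components),
        bic_curve=bic,
        chosen_k=min(bic, key=bic.get) if bic else None,
        ari=ari, ami=ami,
    )
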