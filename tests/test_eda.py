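from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from synthcohort.eda import (cluster_transfer_agreement, explained_variance_profile,
                             kmeans_bic_curve, ppca_transfer_loglik)


class TestExplainedVariance:
    def test_isotropic_near_uniform(self):
        rng = np.random.default_rng(0)
        f = explained_variance_profile(rng.standard_normal((5000, 6)))
        assert np.abs(f - 1 / 6).max() < 0.02

    def test_rank_one_concentrates(self):
        rng = np.random.default_rng(1)
        u = rng.standard_normal((2000, 1))
        x = u @ rng.standard_normal((1, 5)) + 1e-6 * rng.standard_normal((2000, 5))
        f = explained_variance_profile(x)
        assert f[0] > 0.999

    def test_sums_to_one(self):
        rng = np.random.default_rng(2)
        f = explained_variance_profile(rng.uniform(size=(300, 8)))
        assert abs(f.sum() - 1.0) < 1e-9


class TestPPCA:
    def test_matches_closed_form_on_constructed_data(self):
        """Data from a known 4-factor + isotropic-noise model: the fitted
        average log-likelihood matches the known-parameter Gaussian density."""
        rng = np.random.default_rng(3)
        d, q, n = 10, 4, 200_000
        W = rng.standard_normal((d, q))
        sigma2 = 0.01
        mu = rng.standard_normal(d)
        z = rng.standard_normal((n, q))
        x = mu + z @ W.T + np.sqrt(sigma2) * rng.standard_normal((n, d))
        test = x[-20_000:]
        ll_fit = ppca_transfer_loglik(x[:180_000], test, n_components=q)
        cov = W @ W.T + sigma2 * np.eye(d)
        ll_true = stats.multivariate_normal(mu, cov).logpdf(test).mean()
        assert abs(ll_fit - ll_true) < 1e-3 * abs(ll_true)

    def test_self_fit_beats_perturbed_mean(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((2000, 6))
        from sklearn.decomposition import PCA
        pca = PCA(n_components=2).fit(x)
        ll_self = pca.score(x)
        ll_shift = pca.score(x + 1.0)
        assert ll_self >= ll_shift

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        train = rng.standard_normal((3000, 6)) * np.array([3, 2, 1.5, 1, 1, 1])
        test = rng.standard_normal((500, 6)) * np.array([3, 2, 1.5, 1, 1, 1])
        q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        a = ppca_transfer_loglik(train, test, 3)
        b = ppca_transfer_loglik(train @ q, test @ q, 3)
        assert a == pytest.approx(b, rel=1e-6)

    def test_too_many_components_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            ppca_transfer_loglik(rng.uniform(size=(100, 4)),
                                 rng.uniform(size=(10, 4)), 4)


class TestBIC:
    @pytest.fixture(scope="class")
    def three_blobs(self):
        rng = np.random.default_rng(7)
        centers = np.array([[0, 0], [10, 0], [0, 10]], float)
        return np.vstack([c + rng.normal(0, 1.0, (300, 2)) for c in centers])

    def test_minimized_at_true_cluster_count(self, three_blobs):
        bic = kmeans_bic_curve(three_blobs, range(2, 7), seed=0)
        assert min(bic, key=bic.get) == 3

    def test_deterministic(self, three_blobs):
        a = kmeans_bic_curve(three_blobs, range(2, 5), seed=1)
        b = kmeans_bic_curve(three_blobs, range(2, 5), seed=1)
        assert a == b

    def test_row_order_invariant(self, three_blobs):
        perm = np.random.default_rng(8).permutation(len(three_blobs))
        a = kmeans_bic_curve(three_blobs, range(2, 5), seed=1)
        b = kmeans_bic_curve(three_blobs[perm], range(2, 5), seed=1)
        assert a == pytest.approx(b)

    def test_degenerate_k_rejected(self, three_blobs):
        with pytest.raises(ValueError):
            kmeans_bic_curve(three_blobs[:5], range(2, 7), seed=0)


def brute_force_ari(la, lb):
    """Pair-counting adjusted Rand index by explicit enumeration."""
    n = len(la)
    ss = sd = ds = dd = 0
    for i, j in combinations(range(n), 2):
        a = la[i] == la[j]
        b = lb[i] == lb[j]
        ss += a and b
        sd += a and not b
        ds += b and not a
        dd += not a and not b
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    max_index = 0.5 * ((ss + sd) + (ss + ds))
    return (ss - expected) / (max_index - expected)


class TestClusterTransfer:
    def test_identical_source_gives_perfect_agreement(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(size=(600, 4))
        test = rng.uniform(size=(200, 4))
        ari, ami = cluster_transfer_agreement(x, x.copy(), test, n_clusters=5, seed=0)
        assert ari == 1.0 and ami == 1.0

    def test_row_permuted_source_gives_perfect_agreement(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(size=(600, 4))
        test = rng.uniform(size=(200, 4))
        ari, ami = cluster_transfer_agreement(x, x[rng.permutation(600)], test,
                                              n_clusters=5, seed=0)
        assert ari == 1.0 and ami == 1.0

    def test_random_permutation_of_labels_scores_chance(self):
        rng = np.random.default_rng(11)
        from sklearn.metrics import adjusted_rand_score
        labels = rng.integers(0, 15, 10_000)
        aris = [adjusted_rand_score(labels, rng.permutation(labels))
                for _ in range(100)]
        assert abs(np.mean(aris)) < 0.01

    def test_ari_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(12)
        from sklearn.metrics import adjusted_rand_score
        la = rng.integers(0, 2, 6)
        lb = rng.integers(0, 2, 6)
        if len(set(la)) < 2 or len(set(lb)) < 2:
            la, lb = [0, 0, 1, 1, 0, 1], [0, 1, 1, 1, 0, 0]
        assert adjusted_rand_score(la, lb) == pytest.approx(brute_force_ari(la, lb))

    def test_symmetry(self):
        rng = np.random.default_rng(13)
        a = rng.uniform(size=(400, 3))
        b = rng.uniform(size=(400, 3))
        test = rng.uniform(size=(150, 3))
        r1 = cluster_transfer_agreement(a, b, test, n_clusters=4, seed=2)
        r2 = cluster_transfer_agreement(b, a, test, n_clusters=4, seed=2)
        assert r1 == pytest.approx(r2)

    def test_k_below_two_rejected(self):
        rng = np.random.default_rng(14)
        x = rng.uniform(size=(50, 3))
        with pytest.raises(ValueError):
            cluster_transfer_agreement(x, x, x, n_clusters=1)
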