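import math

import numpy as np
import pytest
from scipy.stats import wasserstein_distance

from synthcohort.accounting import compose_pate
from synthcohort.generators import (GanConfig, build_ensemble,
                                    identifiability_penalty, sample, train_gan)
from synthcohort.preprocess import Encoder


@pytest.fixture(scope="module")
def nonprivate_model(toy_matrix):
    cfg = GanConfig(method="dpgan", epochs=120, seed=1,
                    epsilon_budget=math.inf)
    model, ledger = train_gan(toy_matrix, cfg)
    return model, ledger


def test_nonprivate_gan_learns_toy_marginals(toy_matrix, nonprivate_model):
    """Adversarial-core sanity: per-feature Wasserstein < 0.05 at n = 5000."""
    model, _ = nonprivate_model
    synth = sample(model, 5000, 7)
    for j in range(toy_matrix.d):
        w = wasserstein_distance(toy_matrix.values[:, j], synth.values[:, j])
        assert w < 0.05, (toy_matrix.columns[j], w)


def test_sampling_is_seeded_and_onehot_exact(nonprivate_model):
    model, _ = nonprivate_model
    a = sample(model, 100, 7)
    b = sample(model, 100, 7)
    assert np.array_equal(a.values, b.values)
    assert np.allclose(a.values[:, 1] + a.values[:, 2], 1.0)
    assert set(np.unique(a.values[:, 1:])) <= {0.0, 1.0}
    assert a.values.min() >= 0.0 and a.values.max() <= 1.0


def test_sample_rejects_zero_rows(nonprivate_model):
    with pytest.raises(ValueError):
        sample(nonprivate_model[0], 0, 1)


def test_training_is_deterministic(toy_matrix):
    cfg = GanConfig(method="adsgan", epochs=3, seed=9)
    m1, _ = train_gan(toy_matrix, cfg)
    m2, _ = train_gan(toy_matrix, GanConfig(method="adsgan", epochs=3, seed=9))
    assert np.array_equal(sample(m1, 50, 0).values, sample(m2, 50, 0).values)


def test_dpgan_respects_budget(toy_matrix):
    cfg = GanConfig(method="dpgan", epochs=10, seed=2, epsilon_budget=1.0)
    _, ledger = train_gan(toy_matrix, cfg)
    assert 0 < ledger.epsilon_spent <= 1.0
    assert ledger.steps >= 1


def test_dpgan_budget_exhausted_before_first_step(toy_matrix):
    cfg = GanConfig(method="dpgan", epochs=5, seed=2, epsilon_budget=1e-4,
                    noise_multiplier=0.5)
    with pytest.raises(RuntimeError, match="budget exhausted"):
        train_gan(toy_matrix, cfg)


def test_pategan_ledger_matches_composition(toy_matrix):
    cfg = GanConfig(method="pategan", seed=3, epsilon_budget=1.0,
                    laplace_lambda=0.001, vote_batch=100, n_teachers=2)
    _, ledger = train_gan(toy_matrix, cfg)
    n_queries = sum(e["count"] for e in ledger.per_step_log)
    assert ledger.epsilon_spent == pytest.approx(compose_pate(0.001, n_queries))
    assert ledger.epsilon_spent <= 1.0


def test_pategan_stops_after_budgeted_queries(toy_matrix):
    # budget 1.0, lambda 0.05, one sample per round => exactly 10 query rounds
    cfg = GanConfig(method="pategan", seed=3, epsilon_budget=1.0,
                    laplace_lambda=0.05, vote_batch=1, n_teachers=2)
    _, ledger = train_gan(toy_matrix, cfg)
    assert sum(e["count"] for e in ledger.per_step_log) == 10
    assert ledger.epsilon_spent == pytest.approx(1.0)


def test_adsgan_ledger_declares_not_private(toy_matrix):
    cfg = GanConfig(method="adsgan", epochs=2, seed=4)
    _, ledger = train_gan(toy_matrix, cfg)
    assert "not differentially private" in ledger.note


def test_identifiability_penalty_zero_cases():
    rng = np.random.default_rng(0)
    syn = rng.uniform(size=(20, 4))
    src = rng.uniform(size=(20, 4))
    dw = np.zeros(20)   # nearest-neighbour distance 0: nothing can be too close
    val, grad = identifiability_penalty(syn, src, dw, lam=5.0)
    assert val == 0.0 and not grad.any()
    val0, grad0 = identifiability_penalty(syn, src, np.ones(20), lam=0.0)
    assert val0 == 0.0 and not grad0.any()


def test_identifiability_penalty_gradient_matches_finite_differences():
    rng = np.random.default_rng(1)
    syn = rng.uniform(size=(6, 3))
    src = syn + 0.05 * rng.standard_normal((6, 3))
    dw = np.full(6, 0.5)
    val, grad = identifiability_penalty(syn, src, dw, lam=2.0)
    assert val > 0
    eps = 1e-6
    for idx in [(0, 0), (3, 2)]:
        orig = syn[idx]
        syn[idx] = orig + eps
        vp, _ = identifiability_penalty(syn, src, dw, 2.0)
        syn[idx] = orig - eps
        vm, _ = identifiability_penalty(syn, src, dw, 2.0)
        syn[idx] = orig
        assert abs(grad[idx] - (vp - vm) / (2 * eps)) < 1e-6


def test_invalid_configs_rejected(toy_matrix):
    with pytest.raises(ValueError):
        GanConfig(method="vae").validate()
    with pytest.raises(ValueError):
        GanConfig(epsilon_budget=-1.0).validate()
    with pytest.raises(ValueError):
        GanConfig(n_teachers=1).validate()
    with pytest.raises(ValueError):
        train_gan(toy_matrix, GanConfig(lambda_identifiability=-2.0))


class TestEnsemble:
    def test_row_counts_and_member_allocation(self, toy_matrix):
        cfg = GanConfig(method="adsgan", epochs=2, seed=5)
        synth = build_ensemble(toy_matrix, cfg, n_members=10, total_rows=1000)
        assert synth.n == 1000
        assert synth.provenance["n_members"] == 10
        assert len(synth.provenance["ledgers"]) == 10

    def test_single_member_equals_plain_train_and_sample(self, toy_matrix):
        cfg = GanConfig(method="adsgan", epochs=2, seed=6)
        ens = build_ensemble(toy_matrix, cfg, n_members=1, total_rows=200)
        model, _ = train_gan(toy_matrix, GanConfig(method="adsgan", epochs=2, seed=6))
        direct = sample(model, 200, seed=6 + 10_000)
        assert np.array_equal(ens.values, direct.values)

    def test_requires_enough_rows(self, toy_matrix):
        with pytest.raises(ValueError):
            build_ensemble(toy_matrix, GanConfig(epochs=1), n_members=10,
                           total_rows=5)

    def test_ensemble_reports_max_member_epsilon(self, toy_matrix):
        cfg = GanConfig(method="dpgan", epochs=4, seed=7, epsilon_budget=1.0)
        synth = build_ensemble(toy_matrix, cfg, n_members=2, total_rows=100)
        eps = [l["epsilon_spent"] for l in synth.provenance["ledgers"]]
        assert synth.provenance["epsilon_max_member"] == pytest.approx(max(eps))
        assert synth.provenance["epsilon_strict_composition"] == pytest.approx(sum(eps))
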