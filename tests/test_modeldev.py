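import numpy as np
import pandas as pd
import pytest

import synthcohort as sc
from synthcohort.modeldev import (cox_feature_pvalues, design_matrix,
                                  hyperparam_transfer, sample_survnet_grid,
                                  selection_concordance)
from synthcohort.preprocess import Encoder
from synthcohort.survnet import SurvNetConfig, train_survnet, validation_cindex


@pytest.fixture(scope="module")
def survival_fixture():
    """200 rows, 3 covariates, continuous times (no ties)."""
    rng = np.random.default_rng(0)
    n = 200
    x = pd.DataFrame(rng.standard_normal((n, 3)), columns=["a", "b", "c"])
    lp = 0.8 * x["a"] - 0.5 * x["b"]
    t_event = rng.exponential(1.0 / np.exp(lp))
    c = rng.exponential(2.0, n)
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    return x, time, event


def test_cox_matches_scikit_survival_reference(survival_fixture):
    """Coefficients agree with an independent implementation to 1e-4
    (no ties, so Efron and Breslow likelihoods coincide)."""
    from sksurv.linear_model import CoxPHSurvivalAnalysis
    from sksurv.util import Surv
    x, time, event = survival_fixture
    p, cph = cox_feature_pvalues(x, time, event, penalizer=0.0, step_size=0.9)
    ref = CoxPHSurvivalAnalysis(alpha=1e-12, tol=1e-12).fit(
        x.to_numpy(), Surv.from_arrays(event=event.astype(bool), time=time))
    assert np.allclose(cph.params_.to_numpy(), ref.coef_, atol=1e-4)


def test_constant_covariate_dropped(survival_fixture):
    x, time, event = survival_fixture
    x2 = x.copy()
    x2["flat"] = 1.0
    with pytest.warns(UserWarning, match="constant"):
        p, _ = cox_feature_pvalues(x2, time, event)
    assert "flat" not in p.index


def test_cox_requires_events(survival_fixture):
    x, time, _ = survival_fixture
    with pytest.raises(ValueError):
        cox_feature_pvalues(x, time, np.zeros(len(x), int))


def test_wald_pvalue_decreases_with_effect_size():
    rng = np.random.default_rng(1)
    n = 800
    med_p = {}
    for beta in (0.2, 0.8):
        ps = []
        for rep in range(10):
            x = pd.DataFrame({"a": rng.standard_normal(n)})
            t_ev = rng.exponential(1.0 / np.exp(beta * x["a"]))
            ps.append(cox_feature_pvalues(x, t_ev, np.ones(n, int))[0]["a"])
        med_p[beta] = np.median(ps)
    assert med_p[0.8] < med_p[0.2]


class TestSelectionConcordance:
    def test_identical_pvalues_score_perfect(self):
        p = pd.Series({"a": 0.001, "b": 0.2, "c": 0.03, "d": 0.9})
        rep = selection_concordance(p, p)
        assert rep.precision == rep.recall == rep.auroc == 1.0

    def test_definitional_counts(self):
        feats = list("abcdefghij")
        p_real = pd.Series({f: (0.01 if f in "abc" else 0.5) for f in feats})
        p_syn = pd.Series({f: (0.01 if f in "abd" else 0.5) for f in feats})
        rep = selection_concordance(p_real, p_syn)
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.recall == pytest.approx(2 / 3)

    def test_uniform_synth_pvalues_score_chance_auroc(self):
        rng = np.random.default_rng(2)
        feats = [f"f{i}" for i in range(20)]
        p_real = pd.Series({f: (0.001 if i < 8 else 0.8) for i, f in enumerate(feats)})
        aucs = [selection_concordance(
            p_real, pd.Series(rng.uniform(size=20), index=feats)).auroc
            for _ in range(200)]
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_auroc_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(3)
        feats = [f"f{i}" for i in range(12)]
        p_real = pd.Series({f: (0.01 if i < 5 else 0.5) for i, f in enumerate(feats)})
        p_syn = pd.Series(rng.uniform(size=12), index=feats)
        rep = selection_concordance(p_real, p_syn)
        score = -np.log10(p_syn)
        truth = (p_real < 0.05)
        num = tot = 0.0
        for i in feats:
            for j in feats:
                if truth[i] and not truth[j]:
                    tot += 1
                    num += (score[i] > score[j]) + 0.5 * (score[i] == score[j])
        assert rep.auroc == pytest.approx(num / tot)

    def test_empty_real_selection_rejected(self):
        p = pd.Series({"a": 0.5, "b": 0.9})
        with pytest.raises(ValueError, match="recall undefined"):
            selection_concordance(p, p)


class TestSurvNet:
    def test_pure_likelihood_mode_trains(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(size=(500, 2))
        t = rng.exponential(1, 500) + 0.01
        e = rng.integers(0, 2, 500)
        m = train_survnet(x, t, e, SurvNetConfig(alpha=1.0, max_epochs=5, seed=0))
        assert np.isfinite(m.predict_cif(x, 1.0)).all()

    def test_strong_predictor_gives_good_discrimination(self):
        rng = np.random.default_rng(5)
        n = 3000
        x = rng.uniform(size=(n, 1))
        lp = 4.0 * x[:, 0]
        t_ev = rng.exponential(1.0 / np.exp(lp))
        c = rng.exponential(2.0, n)
        t, e = np.minimum(t_ev, c), (t_ev <= c).astype(int)
        m = train_survnet(x, t, e, SurvNetConfig(seed=3))
        xv = rng.uniform(size=(1000, 1))
        tv_ev = rng.exponential(1.0 / np.exp(4.0 * xv[:, 0]))
        cv = rng.exponential(2.0, 1000)
        cidx = validation_cindex(m, xv, np.minimum(tv_ev, cv), (tv_ev <= cv).astype(int))
        assert cidx > 0.7

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(size=(400, 3))
        t = rng.exponential(1, 400) + 0.01
        e = rng.integers(0, 2, 400)
        cfg = SurvNetConfig(seed=7, max_epochs=8)
        m1 = train_survnet(x, t, e, cfg)
        m2 = train_survnet(x, t, e, SurvNetConfig(seed=7, max_epochs=8))
        assert all(np.array_equal(a, b) for a, b in zip(m1.net.Ws, m2.net.Ws))

    def test_no_events_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError):
            train_survnet(rng.uniform(size=(100, 2)), rng.exponential(1, 100) + 0.1,
                          np.zeros(100, int), SurvNetConfig(seed=0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SurvNetConfig(alpha=1.5).validate()
        with pytest.raises(ValueError):
            SurvNetConfig(sigma=0.0).validate()
        with pytest.raises(ValueError):
            SurvNetConfig(time_bins=1).validate()


class TestHyperparamTransfer:
    @pytest.fixture(scope="class")
    def triples(self, schema, true_model):
        full = sc.simulate_outcomes(sc.simulate_covariates(schema, 2500, 20),
                                    true_model, 21)
        enc = Encoder.from_cohort(full)
        x = enc.transform(full).values
        tr = (x[:1600], full.time[:1600], full.event[:1600])
        te = (x[1600:], full.time[1600:], full.event[1600:])
        return tr, te

    def test_identical_configs_give_zero_uplift(self, triples):
        tr, te = triples
        rep = hyperparam_transfer(
            tr, tr, te, n_configs=3, seed=1,
            grid_overrides=dict(alpha=0.8, sigma=0.25, dropout=0.1, hidden_dim=16,
                                learning_rate=1e-3, batch_size=128, patience=5,
                                max_epochs=4, seed=99))
        # all grid entries identical => every test C-index equal => uplift 0
        assert rep.uplift == pytest.approx(0.0, abs=1e-12)

    def test_baseline_is_mean_of_test_cindices(self, triples):
        tr, te = triples
        rep = hyperparam_transfer(tr, tr, te, n_configs=4, seed=2,
                                  grid_overrides={"max_epochs": 3})
        assert rep.baseline == pytest.approx(np.mean(rep.test_cindex))
        assert rep.uplift == pytest.approx(rep.selected_test_cindex - rep.baseline)

    def test_grid_respects_documented_ranges(self):
        grid = sample_survnet_grid(20, 0)
        for cfg in grid:
            assert 0.1 <= cfg.alpha <= 1.0
            assert cfg.sigma in (0.1, 0.25, 0.5, 1.0)
            assert 0.0 <= cfg.dropout <= 0.5
            assert cfg.hidden_dim in (16, 32, 64)
            assert 1e-4 <= cfg.learning_rate <= 1e-2
            assert cfg.batch_size in (64, 128, 256)
            assert cfg.patience in (5, 10)


def test_design_matrix_drops_reference_levels(cohort_2k):
    enc = Encoder.from_cohort(cohort_2k)
    df = design_matrix(enc, cohort_2k)
    assert "qualification=None" not in df.columns
    assert "qualification=Degree" in df.columns
    assert "sex=Female" not in df.columns and "sex=Male" in df.columns
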