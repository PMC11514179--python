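import numpy as np
import pandas as pd
import pytest
from scipy import stats

import synthcohort as sc
from synthcohort.fidelity import (describe_table, js_divergence, jsd_features,
                                  marginal_kde, precision_recall_authenticity,
                                  wasserstein_1d)
from synthcohort.schema import Cohort, CohortSchema, VariableSpec


class TestDescribe:
    def test_two_row_toy(self):
        schema = CohortSchema((VariableSpec("x", "continuous", bounds=(0, 10)),))
        c = Cohort(schema, pd.DataFrame({"x": [1.0, 3.0]}))
        d = describe_table(c)
        assert d["x"]["mean"] == pytest.approx(2.0)
        assert d["x"]["sd"] == pytest.approx(np.sqrt(2))

    def test_all_zero_binary(self):
        schema = CohortSchema((VariableSpec("b", "binary"),))
        c = Cohort(schema, pd.DataFrame({"b": [0, 0, 0]}))
        d = describe_table(c)
        assert d["b"]["1"] == {"n": 0, "pct": 0.0}

    def test_simulated_age_mean(self, schema):
        cov = sc.simulate_covariates(schema, 100_000, 2)
        d = describe_table(cov)
        assert abs(d["age"]["mean"] - 57.4) < 0.5


class TestKDE:
    def test_close_to_normal_density(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10_000)
        grid = np.linspace(-3, 3, 121)
        dens = marginal_kde(x, grid)
        assert np.abs(dens - stats.norm.pdf(grid)).max() < 0.05

    def test_identical_values_error(self):
        with pytest.raises(ValueError):
            marginal_kde(np.ones(100), np.linspace(0, 2, 10))

    def test_integrates_to_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(5, 2, 5000)
        grid = np.linspace(-10, 20, 2001)
        dens = marginal_kde(x, grid)
        assert abs(np.trapezoid(dens, grid) - 1.0) < 0.01


class TestWasserstein:
    def test_self_distance_zero(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(size=200)
        assert wasserstein_1d(x, x) == 0.0

    def test_point_mass_shift(self):
        assert wasserstein_1d([0, 0], [1, 1]) == pytest.approx(1.0)

    def test_ecdf_integral_example(self):
        assert wasserstein_1d([0, 1], [0, 2]) == pytest.approx(0.5)

    def test_triangle_inequality_spot_check(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b, c = (rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), 50)
                       for _ in range(3))
            assert wasserstein_1d(a, c) <= wasserstein_1d(a, b) + \
                wasserstein_1d(b, c) + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wasserstein_1d([], [1.0])


class TestJSD:
    def test_identical_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert js_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_is_one(self):
        assert js_divergence([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        p = rng.dirichlet(np.ones(8))
        q = rng.dirichlet(np.ones(8))
        assert js_divergence(p, q) == pytest.approx(js_divergence(q, p))

    def test_in_unit_interval_per_feature(self):
        rng = np.random.default_rng(5)
        real = rng.uniform(size=(300, 3))
        synth = rng.uniform(size=(300, 3))
        per, mean = jsd_features(real, synth, ["a", "b", "c"])
        assert all(0 <= v <= 1 for v in per.values())


class TestPrecisionRecallAuthenticity:
    def test_copy_has_near_zero_authenticity(self):
        rng = np.random.default_rng(6)
        real = rng.uniform(size=(500, 4))
        _, _, auth = precision_recall_authenticity(real, real.copy())
        assert auth < 0.05

    def test_far_translation_gives_zero_delta_precision(self):
        rng = np.random.default_rng(7)
        real = rng.uniform(size=(300, 4))
        synth = real + 100.0
        dp, _, auth = precision_recall_authenticity(real, synth)
        assert dp == pytest.approx(0.0, abs=0.02)
        assert auth == 1.0

    def test_split_half_matches_resampling_oracle(self):
        """ΔP for two halves of one sample vs a brute-force resampling oracle."""
        rng = np.random.default_rng(8)
        x = rng.normal(size=(2000, 4))
        oracle = []
        for _ in range(100):
            perm = rng.permutation(2000)
            dp, _, _ = precision_recall_authenticity(x[perm[:1000]], x[perm[1000:]])
            oracle.append(dp)
        perm = np.random.default_rng(9).permutation(2000)
        dp, _, _ = precision_recall_authenticity(x[perm[:1000]], x[perm[1000:]])
        assert abs(dp - np.mean(oracle)) < 0.1

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(10)
        real = rng.uniform(size=(200, 3))
        synth = rng.uniform(size=(200, 3))
        a = precision_recall_authenticity(real, synth)
        b = precision_recall_authenticity(real[rng.permutation(200)],
                                          synth[rng.permutation(200)])
        assert a == pytest.approx(b)

    def test_authenticity_separates_copies_from_fresh_draws(self, schema):
        from synthcohort.preprocess import Encoder
        real = sc.simulate_covariates(schema, 2000, 1)
        fresh = sc.simulate_covariates(schema, 2000, 2)
        enc = Encoder.from_cohort(real)
        x_real = enc.transform(real).values
        x_fresh = enc.transform(fresh).values
        _, _, auth_copy = precision_recall_authenticity(x_real, x_real.copy())
        _, _, auth_fresh = precision_recall_authenticity(x_real, x_fresh)
        assert auth_copy < 0.05
        assert auth_fresh > 0.5

    def test_too_few_rows_rejected(self):
        rng = np.random.default_rng(12)
        with pytest.raises(ValueError):
            precision_recall_authenticity(rng.uniform(size=(10, 3)),
                                          rng.uniform(size=(100, 3)))
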