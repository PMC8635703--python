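"""PLSR residual scoring: SIMPLS correctness, permutation test, group split."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from oracles import nipals_pls1_residuals
from resilnet.resilience import (
    ResilienceScorer,
    SIMPLSRegression,
    compute_resilience_scores,
    fit_plsr,
    permutation_test_plsr,
    split_groups,
)

# frozen fixture: a fixed 6x3 X and 6x2 Y exercising the one-component model
X_FIX = np.array([
    [1.0, 2.0, 0.5],
    [2.0, 1.0, 1.5],
    [3.0, 4.0, 2.0],
    [4.0, 3.0, 3.5],
    [5.0, 6.0, 4.0],
    [6.0, 5.0, 5.5],
])
Y_FIX = np.array([
    [1.2, 0.8],
    [1.9, 1.4],
    [3.1, 2.6],
    [4.2, 3.4],
    [4.8, 4.4],
    [6.1, 5.3],
])


class TestSIMPLS:
    def test_noiseless_rank1_recovery(self, rng):
        X = np.outer(rng.normal(size=25), rng.normal(size=6))
        Y = X @ rng.normal(size=(6, 3))
        fit = fit_plsr(X, Y, n_components=1)
        assert fit.r2_total == pytest.approx(1.0, abs=1e-12)
        assert np.abs(fit.E).max() < 1e-10

    def test_residuals_match_nipals_oracle_on_fixture(self):
        fit = fit_plsr(X_FIX, Y_FIX, n_components=1)
        E_oracle = nipals_pls1_residuals(X_FIX, Y_FIX, n_components=1)
        assert np.max(np.abs(fit.E - E_oracle)) < 1e-8

    def test_residuals_match_sklearn(self, rng):
        X = rng.normal(size=(80, 12))
        Y = X[:, :3] @ rng.normal(size=(3, 4)) + rng.normal(size=(80, 4))
        mine = SIMPLSRegression(1).fit(X, Y)
        # sklearn's NIPALS is iterative; tighten its tolerance for comparison
        sk = PLSRegression(n_components=1, scale=False, tol=1e-12,
                           max_iter=10000).fit(X, Y)
        assert np.max(np.abs(mine.residuals_ - (Y - sk.predict(X)))) < 1e-5

    def test_internal_nipals_agrees_with_simpls(self, rng):
        X = rng.normal(size=(40, 7))
        Y = rng.normal(size=(40, 3))
        a = SIMPLSRegression(1, algorithm="simpls").fit(X, Y)
        b = SIMPLSRegression(1, algorithm="nipals").fit(X, Y)
        assert np.max(np.abs(a.residuals_ - b.residuals_)) < 1e-10

    def test_residual_identity_and_centering(self, rng):
        X = rng.normal(size=(50, 8))
        Y = rng.normal(size=(50, 4))
        fit = fit_plsr(X, Y)
        assert np.allclose(fit.E, Y - fit.Y_hat)
        assert np.abs(fit.E.mean(axis=0)).max() < 1e-10
        assert 0.0 <= fit.r2_total <= 1.0

    def test_invariant_to_predictor_permutation(self, rng):
        X = rng.normal(size=(60, 10))
        Y = rng.normal(size=(60, 4)) + X[:, :2].sum(axis=1, keepdims=True)
        perm = rng.permutation(10)
        E1 = fit_plsr(X, Y).E
        E2 = fit_plsr(X[:, perm], Y).E
        assert np.max(np.abs(E1 - E2)) < 1e-10

    def test_zero_variance_x_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_plsr(np.ones((10, 3)), np.random.default_rng(0).normal(size=(10, 2)))

    def test_too_many_components_errors(self, rng):
        X = np.outer(rng.normal(size=12), rng.normal(size=5))   # rank 1
        Y = rng.normal(size=(12, 2))
        with pytest.raises(ValueError, match="rank"):
            fit_plsr(X, Y, n_components=3)


class TestPermutationTest:
    def test_deterministic_relation_gives_min_p(self, rng):
        X = rng.normal(size=(40, 6))
        Y = X @ rng.normal(size=(6, 2))
        res = permutation_test_plsr(X, Y, n_perm=199, random_state=0)
        assert res.p_value == pytest.approx(1.0 / 200.0)

    def test_single_permutation_outcomes(self, rng):
        X = rng.normal(size=(20, 4))
        Y = rng.normal(size=(20, 2))
        res = permutation_test_plsr(X, Y, n_perm=1, random_state=1)
        assert res.p_value in (0.5, 1.0)

    def test_p_value_in_unit_interval_and_formula(self, rng):
        X = rng.normal(size=(30, 5))
        Y = rng.normal(size=(30, 2))
        res = permutation_test_plsr(X, Y, n_perm=49, random_state=3)
        expected = (1 + np.count_nonzero(res.null_stats >= res.observed_stat)) / 50
        assert res.p_value == pytest.approx(expected)
        assert 0 < res.p_value <= 1

    def test_requires_at_least_one_permutation(self, rng):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test_plsr(rng.normal(size=(10, 2)),
                                  rng.normal(size=(10, 2)), n_perm=0)


class TestScoresAndSplit:
    def test_mean_of_constant_residual_row(self):
        fit = fit_plsr(X_FIX, Y_FIX)
        fit.E = np.array([[1.0, 1, 1, 1], [2, -2, 1, -1]])
        s = compute_resilience_scores(fit)
        assert s.score[0] == pytest.approx(1.0) and s.group[0] == "high"
        # exact zero goes to the low group
        assert s.score[1] == pytest.approx(0.0) and s.group[1] == "low"

    def test_split_examples(self):
        labels, nh, nl = split_groups([0.5, -0.5, 0.0])
        assert list(labels) == ["high", "low", "low"]
        assert (nh, nl) == (1, 2)

    def test_degenerate_split_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            split_groups([0.2, 0.3, 1.0])

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            split_groups([0.1, np.nan])

    def test_scorer_recovers_resilience_offset(self, small_cohort, small_design):
        scorer = ResilienceScorer().fit(small_design.X, small_design.Y)
        r = np.corrcoef(scorer.score_, small_cohort.truth.resilience_offset)[0, 1]
        assert r > 0.7    # n=260; tightens to >0.8 at full cohort size
        assert scorer.n_high_ + scorer.n_low_ == small_cohort.n_subjects

    def test_null_cohort_scores_reduce_to_outcome_means(self):
        # without a stress effect the model has nothing to remove: scores
        # track the mean processed outcome almost perfectly
        from resilnet.preprocess import preprocess_design
        from resilnet.synthetic import SyntheticConfig, generate_cohort

        c = generate_cohort(SyntheticConfig(n_subjects=600, stress_effect=0.0,
                                            seed=21))
        d = preprocess_design(c)
        scorer = ResilienceScorer().fit(d.X, d.Y)
        r = np.corrcoef(scorer.score_, d.Y.mean(axis=1))[0, 1]
        # the fitted component still absorbs some pure noise (p=143), so
        # agreement is high but not perfect
        assert r > 0.9
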