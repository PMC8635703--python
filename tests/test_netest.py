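"""Polychoric estimation, PD repair, graphical lasso and EBIC selection."""

import numpy as np
import pytest

from oracles import polychoric_grid, proximal_gradient_glasso
from resilnet._glasso import glasso_objective, kkt_violation
from resilnet.netest import (
    EBICGraphicalLasso,
    ebic_glasso,
    glasso,
    nearest_pd,
    polychoric_matrix,
    polychoric_pair,
    precision_to_pcor,
    unregularized_pcor,
)
from resilnet.synthetic import chain_precision, sample_ordinal_from_ggm


def rand_corr(k, rng):
    A = rng.normal(size=(k, 2 * k))
    S = A @ A.T / (2 * k)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


class TestPolychoric:
    def test_exact_independence(self):
        rho, _, _ = polychoric_pair([[25, 25], [25, 25]])
        assert rho == pytest.approx(0.0, abs=1e-6)

    def test_perfect_concordance_clamped(self):
        rho, _, _ = polychoric_pair([[50, 0], [0, 50]])
        assert rho >= 0.99

    def test_tetrachoric_matches_grid_oracle(self):
        t = [[40, 10], [10, 40]]
        rho, _, _ = polychoric_pair(t)
        assert abs(rho - polychoric_grid(t)) < 1e-3

    def test_single_occupied_category_errors(self):
        with pytest.raises(ValueError, match="single"):
            polychoric_pair([[30, 20], [0, 0]])

    def test_threshold_estimates(self):
        # margins 50/50: single threshold at 0 on both axes
        _, a, b = polychoric_pair([[25, 25], [25, 25]])
        assert a == pytest.approx([0.0], abs=1e-12)
        assert b == pytest.approx([0.0], abs=1e-12)

    def test_matrix_k2_consistent_with_pair(self, rng):
        x = rng.integers(0, 3, 200)
        y = np.clip(x + rng.integers(-1, 2, 200), 0, 2)
        t = np.zeros((3, 3))
        np.add.at(t, (x, y), 1)
        rho_pair, _, _ = polychoric_pair(t)
        pm = polychoric_matrix(np.column_stack([x, y]))
        assert pm.R[0, 1] == pytest.approx(rho_pair, abs=1e-6)
        assert pm.R[0, 1] == pm.R[1, 0]

    def test_duplicate_items_clamped_and_pd(self, rng):
        x = rng.integers(1, 5, 300)
        items = np.column_stack([x, x, rng.integers(1, 5, 300)])
        pm = polychoric_matrix(items)
        assert pm.R[0, 1] > 0.99
        assert np.linalg.eigvalsh(pm.R).min() > 0

    def test_small_n_warns(self, rng):
        items = rng.integers(0, 3, size=(10, 3))
        with pytest.warns(UserWarning, match="n=10"):
            try:
                polychoric_matrix(items)
            except ValueError:
                pass   # a margin may degenerate at n=10; the warning is the point


class TestNearestPD:
    def test_identity_on_pd_input(self, rng):
        R = rand_corr(5, rng)
        assert np.allclose(nearest_pd(R), R)
        assert np.allclose(nearest_pd(np.eye(4)), np.eye(4))

    def test_repairs_slightly_indefinite_matrix(self, rng):
        # construct a near-correlation matrix with smallest eigenvalue -0.01
        base = rand_corr(5, rng)
        w, Q = np.linalg.eigh(base)
        w[0] = -0.01
        R = (Q * w) @ Q.T
        d = np.sqrt(np.diagonal(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        R = (R + R.T) / 2
        assert np.linalg.eigvalsh(R).min() < 0
        out = nearest_pd(R)
        # eigenvalue clipping is exact up to floating point round-off
        assert np.linalg.eigvalsh(out).min() >= 1e-8 * (1 - 1e-6)
        assert np.allclose(np.diagonal(out), 1.0)
        # no worse than the plain dense eigen-clipping projection by more
        # than the diagonal-restoration perturbation
        wc, Qc = np.linalg.eigh(R)
        clipped = (Qc * np.clip(wc, 1e-8, None)) @ Qc.T
        assert (np.linalg.norm(out - R) <=
                np.linalg.norm(clipped - R) + 1e-2)

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            nearest_pd(np.array([[1.0, 0.5], [0.1, 1.0]]))


class TestGlasso:
    def test_unpenalized_limit_inverts(self, rng):
        S = rand_corr(4, rng)
        assert np.max(np.abs(glasso(S, 0.0) - np.linalg.inv(S))) < 1e-6

    def test_full_shrinkage_gives_diagonal(self, rng):
        S = rand_corr(5, rng)
        lam = np.abs(S - np.diag(np.diag(S))).max()
        K = glasso(S, lam + 1e-10)
        off = K - np.diag(np.diag(K))
        assert np.max(np.abs(off)) == 0.0

    def test_kkt_conditions(self, rng):
        for lam in (0.05, 0.15, 0.4):
            S = rand_corr(6, rng)
            K = glasso(S, lam)
            assert kkt_violation(S, K, lam) < 1e-6

    def test_objective_matches_proximal_gradient_oracle(self, rng):
        S = rand_corr(5, rng)
        lam = 0.1
        K = glasso(S, lam)
        _, obj_oracle = proximal_gradient_glasso(S, lam)
        assert glasso_objective(S, K, lam) <= obj_oracle + 1e-5

    def test_path_sparsity_monotone_in_lambda(self, rng):
        S = rand_corr(8, rng)
        lams = np.linspace(0.02, 0.5, 12)
        iu = np.triu_indices(8, 1)
        edges = [int(np.count_nonzero(glasso(S, l)[iu])) for l in lams]
        assert all(a >= b for a, b in zip(edges, edges[1:]))


class TestEBICGlasso:
    def test_identity_input_gives_empty_network(self):
        with pytest.warns(UserWarning, match="empty"):
            net = ebic_glasso(np.eye(10), n=500)
        assert net.n_edges == 0
        assert np.allclose(net.weights, 0.0)

    def test_gamma_monotone_sparsity(self, rng):
        X = sample_ordinal_from_ggm(chain_precision(10, 0.3),
                                    (-1.0, 0.0, 1.0), 400, seed=5)
        pm = polychoric_matrix(X)
        e0 = ebic_glasso(pm, n=400, gamma=0.0, threshold=False).n_edges
        e5 = ebic_glasso(pm, n=400, gamma=0.5, threshold=False).n_edges
        assert e5 <= e0

    def test_lambda_zero_limit_matches_unregularized(self, rng):
        R = rand_corr(5, rng)
        net = ebic_glasso(R, n=200, n_lambda=2, lambda_min_ratio=1e-6,
                          threshold=False)
        W_unreg = unregularized_pcor(R)
        # at the tiny-lambda end of the path the estimate is near-unpenalized
        last = precision_to_pcor(glasso(R, net.lambda_path[-1]))
        assert np.max(np.abs(last - W_unreg)) < 1e-3

    def test_weight_matrix_contract(self, small_cohort):
        est = EBICGraphicalLasso().fit(small_cohort.gse)
        W = est.weights_
        assert np.allclose(W, W.T)
        assert np.allclose(np.diagonal(W), 0.0)
        assert np.abs(W).max() < 1.0

    def test_structure_recovery_single_draw(self):
        X = sample_ordinal_from_ggm(chain_precision(10, 0.35),
                                    (-1.6, -0.6, 0.6), 500, seed=1)
        net = ebic_glasso(polychoric_matrix(X), n=500)   # default settings
        iu = np.triu_indices(10, 1)
        sel = {(i, j) for i, j in zip(*iu) if net.weights[i, j] != 0}
        true = {(i, i + 1) for i in range(9)}
        assert len(sel & true) >= 8
        assert len(sel - true) <= 2


class TestUnregularizedPcor:
    def test_formula_on_known_precision(self):
        K = np.array([[1.0, -0.5], [-0.5, 1.0]])
        R = np.linalg.inv(K)
        d = np.sqrt(np.diag(R))
        W = unregularized_pcor(R / np.outer(d, d))
        assert W[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_identity_gives_zero(self):
        assert np.allclose(unregularized_pcor(np.eye(4)), 0.0)

    def test_chain_conditional_independence(self):
        # 3-variable chain: 1-2-3; marginal r13 > 0 but partial ~ 0
        K = chain_precision(3, 0.4)
        cov = np.linalg.inv(K)
        d = np.sqrt(np.diag(cov))
        R = cov / np.outer(d, d)
        assert R[0, 2] > 0.05
        W = unregularized_pcor(R)
        assert abs(W[0, 2]) < 1e-10

    def test_singular_matrix_errors(self):
        R = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError):
            unregularized_pcor(R)
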