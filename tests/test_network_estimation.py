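"""Penalised GLM paths, EBIC selection and nodewise network estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import morbinet as mn
from morbinet.network_estimation import (
    EBICConfig,
    ebic,
    ebic_select,
    fit_ising,
    fit_mgm,
    glm_lasso_path,
    kkt_violation,
    lambda_max,
)
from tests.conftest import chain_theta


class TestLassoPath:
    def test_all_zero_at_lambda_max(self, rng):
        X = rng.normal(size=(120, 6))
        y = X[:, 0] * 0.8 + rng.normal(size=120)
        Z = (X - X.mean(0)) / X.std(0)
        lmax = lambda_max(Z, y, "gaussian")
        path = glm_lasso_path(X, y, "gaussian", lambdas=np.array([lmax * 1.01, lmax * 0.5]))
        assert path.df[0] == 0
        assert (path.coef[0] == 0).all()

    def test_tiny_lambda_limit_matches_ols(self, rng):
        X = rng.normal(size=(200, 5))
        y = X @ np.array([1.0, -2.0, 0.0, 0.5, 0.0]) + rng.normal(size=200)
        lams = np.geomspace(1.0, 1e-8, 40)
        path = glm_lasso_path(X, y, "gaussian", lambdas=lams, tol=1e-10)
        ols = np.linalg.lstsq(np.column_stack([np.ones(200), X]), y, rcond=None)[0]
        assert np.abs(path.coef[-1] - ols[1:]).max() < 1e-6
        assert abs(path.intercept[-1] - ols[0]) < 1e-6

    def test_objective_matches_generic_convex_solver(self, rng):
        X = rng.normal(size=(50, 5))
        y = X @ np.array([1.2, 0.0, -0.7, 0.0, 0.3]) + rng.normal(size=50)
        Z = (X - X.mean(0)) / X.std(0)
        n = 50
        path = glm_lasso_path(X, y, "gaussian", n_lambdas=20, lambda_min_ratio=0.05)

        def objective(params, lam):
            b0, b = params[0], params[1:]
            return ((y - b0 - Z @ b) ** 2).sum() / (2 * n) + lam * np.abs(b).sum()

        for k in range(0, 20, 4):
            lam = path.lambdas[k]
            mine = objective(np.concatenate([[path.intercept_std[k]], path.coef_std[k]]), lam)
            res = minimize(
                objective, np.zeros(6), args=(lam,), method="Nelder-Mead",
                options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12},
            )
            assert mine <= res.fun + 1e-6

    @pytest.mark.parametrize("family", ["gaussian", "logistic", "poisson"])
    def test_kkt_conditions_along_path(self, family, rng):
        X = rng.normal(size=(300, 6))
        eta = X @ np.array([0.8, 0.0, -0.6, 0.0, 0.4, 0.0]) * 0.5
        if family == "gaussian":
            y = eta + rng.normal(size=300)
        elif family == "logistic":
            y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
        else:
            y = rng.poisson(np.exp(eta * 0.5)).astype(float)
        path = glm_lasso_path(X, y, family, n_lambdas=30)
        Z = (X - path.x_mean) / path.x_sd
        worst = max(kkt_violation(path, Z, y, k) for k in range(0, 30, 3))
        assert worst < 1e-5

    def test_validation_errors(self, rng):
        X = rng.normal(size=(30, 3))
        with pytest.raises(ValueError, match="finite"):
            glm_lasso_path(np.where(X > 2, np.inf, X) * np.inf, np.ones(30), "gaussian")
        with pytest.raises(ValueError, match="constant"):
            glm_lasso_path(X, np.ones(30), "logistic")
        with pytest.raises(ValueError, match="decreasing"):
            glm_lasso_path(X, X[:, 0], "gaussian", lambdas=np.array([0.1, 0.2]))


class TestEBICSelect:
    def test_gamma_zero_reduces_to_bic(self, rng):
        loglik = rng.normal(-100, 5, size=12)
        df = rng.integers(0, 6, size=12)
        n = 500
        bic = -2 * loglik + df * np.log(n)
        assert ebic_select(loglik, df, n, p_candidates=9, gamma=0.0) == int(np.argmin(bic))

    def test_single_candidate_equals_bic_for_any_gamma(self, rng):
        loglik = rng.normal(-50, 3, size=8)
        df = rng.integers(0, 2, size=8)
        assert ebic_select(loglik, df, 200, 1, gamma=0.25) == ebic_select(
            loglik, df, 200, 1, gamma=0.0
        )

    def test_null_response_selects_empty_model(self):
        hits = 0
        for r in range(30):
            rng = np.random.default_rng(60000 + r)
            X = rng.normal(size=(500, 6))
            y = rng.normal(size=500)
            path = glm_lasso_path(X, y, "gaussian", n_lambdas=40)
            k = ebic_select(path.loglik, path.df, 500, 6, 0.25)
            hits += path.df[k] == 0
        assert hits >= 28

    def test_empty_path_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ebic_select(np.array([]), np.array([]), 10, 3, 0.25)

    def test_tie_prefers_sparser_model(self):
        loglik = np.array([-10.0, -10.0])
        df = np.array([0, 0])
        assert ebic_select(loglik, df, 100, 3, 0.25) == 0


class TestFitIsing:
    def test_chain_recovery_single_replicate(self):
        theta, tau = chain_theta(8), -np.ones(8)
        X = mn.sample_ising_exact(theta, tau, 3000, seed=3).astype(float)
        net = fit_ising(X)
        est = {(i, j) for i in range(8) for j in range(i + 1, 8) if net.weights[i, j] != 0}
        assert {(i, i + 1) for i in range(7)} <= est
        assert all(net.weights[i, i + 1] > 0 for i in range(7))
        assert len(est) <= 8

    def test_and_rule_subset_of_or_rule(self, rng):
        X = mn.sample_ising_exact(chain_theta(6, 0.7), np.zeros(6), 400, seed=5).astype(float)
        net_and = fit_ising(X, EBICConfig(rule="AND"))
        net_or = fit_ising(X, EBICConfig(rule="OR"))
        assert ((net_and.weights != 0) <= (net_or.weights != 0)).all()

    def test_node_order_permutation_equivariance(self):
        X = mn.sample_ising_exact(chain_theta(5), -np.ones(5), 800, seed=6).astype(float)
        perm = np.array([3, 0, 4, 2, 1])
        net = fit_ising(pd.DataFrame(X, columns=list("abcde")))
        netp = fit_ising(pd.DataFrame(X[:, perm], columns=[list("abcde")[i] for i in perm]))
        assert np.allclose(net.weights[np.ix_(perm, perm)], netp.weights, atol=1e-8)
        assert np.allclose(net.thresholds[perm], netp.thresholds, atol=1e-8)

    def test_symmetry_and_zero_diagonal(self):
        X = mn.sample_ising_exact(chain_theta(5), np.zeros(5), 500, seed=7).astype(float)
        net = fit_ising(X)
        assert np.allclose(net.weights, net.weights.T, atol=1e-12)
        assert (np.diag(net.weights) == 0).all()

    def test_zero_variance_node_named(self, rng):
        X = rng.integers(0, 2, size=(100, 4)).astype(float)
        X[:, 2] = 1.0
        with pytest.raises(ValueError, match="x3"):
            fit_ising(X)

    def test_non_binary_rejected(self, rng):
        with pytest.raises(ValueError, match="binary"):
            fit_ising(rng.normal(size=(100, 4)))


class TestFitMGM:
    def test_all_binary_reduces_to_ising_edges(self):
        X = mn.sample_ising_exact(chain_theta(6), -np.ones(6), 1500, seed=8).astype(float)
        cfg = EBICConfig()
        ising = fit_ising(X, cfg)
        mgm = fit_mgm(X, ["binary"] * 6, cfg)
        assert ((ising.weights != 0) == (mgm.weights != 0)).all()

    def test_independent_continuous_node_isolated(self):
        hits = 0
        for r in range(10):
            rng = np.random.default_rng(70000 + r)
            Xb = (rng.random((1200, 6)) < 0.4).astype(float)
            yc = rng.normal(size=1200)
            X = np.column_stack([Xb, yc])
            net = fit_mgm(X, ["binary"] * 6 + ["continuous"])
            hits += (net.weights[6] == 0).all()
        assert hits >= 9

    def test_planted_continuous_edge_recovered(self):
        hits = 0
        for r in range(10):
            rng = np.random.default_rng(80000 + r)
            Xb = (rng.random((2000, 10)) < 0.35).astype(float)
            yc = 0.8 * Xb[:, 0] + rng.normal(size=2000)
            X = np.column_stack([Xb, yc])
            net = fit_mgm(X, ["binary"] * 10 + ["continuous"])
            hits += net.weights[10, 0] != 0 and net.signs[10, 0] > 0
        assert hits >= 9

    def test_unsupported_type_rejected(self, rng):
        X = rng.integers(0, 2, size=(50, 3)).astype(float)
        with pytest.raises(ValueError, match="unsupported"):
            fit_mgm(X, ["binary", "ordinal", "binary"])


class TestEBICOracleEquivalence:
    def test_path_selection_matches_exhaustive_subsets(self):
        """On small problems whose inactive predictors are exactly
        uncorrelated with the response, path-based EBIC selection equals
        best-subset EBIC enumeration."""
        from itertools import combinations

        def gaussian_loglik(y, yhat):
            n = len(y)
            s2 = max(((y - yhat) ** 2).sum() / n, 1e-300)
            return -0.5 * n * (np.log(2 * np.pi * s2) + 1)

        matches = 0
        for s in range(8):
            rng = np.random.default_rng(9000 + s)
            n, p = 400, int(rng.integers(2, 5))
            Q, _ = np.linalg.qr(rng.normal(size=(n, p)) - 0)
            X = Q * np.sqrt(n)
            beta = np.where(rng.random(p) < 0.5, 1.5, 0.0)
            eps = rng.normal(size=n)
            for j in np.flatnonzero(beta == 0):
                eps -= (X[:, j] @ eps) / (X[:, j] @ X[:, j]) * X[:, j]
            y = X @ beta + eps
            Z = (X - X.mean(0)) / X.std(0)
            lmax = lambda_max(Z, y, "gaussian")
            lams = (
                np.geomspace(lmax * 1.0001, lmax * 0.01, 5)
                if lmax > 0
                else np.geomspace(1.0, 0.01, 5)
            )
            path = glm_lasso_path(X, y, "gaussian", lambdas=lams)
            k = ebic_select(path.loglik, path.df, n, p, 0.25)
            sel = frozenset(int(i) for i in np.flatnonzero(path.coef[k] != 0))
            best, best_score = None, np.inf
            for kk in range(p + 1):
                for S in combinations(range(p), kk):
                    D = np.column_stack([np.ones(n)] + [X[:, j] for j in S])
                    b = np.linalg.lstsq(D, y, rcond=None)[0]
                    sc = ebic(gaussian_loglik(y, D @ b), kk, n, p, 0.25)
                    if sc < best_score - 1e-9:
                        best_score, best = sc, frozenset(S)
            matches += sel == best
        assert matches == 8
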