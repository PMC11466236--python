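"""Nodewise L1 estimation: solver correctness, CV selection, network fit."""

import numpy as np
import pandas as pd
import pytest

import clpnet as c
from clpnet.estimator import _lasso_solve, lambda_grid, standardize_columns
from clpnet.simulate import simulate_linear_panel
from conftest import make_panel


def _random_regression(seed, n=300, p=10, signal=0.3):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)
    y = X @ (rng.standard_normal(p) * signal) + rng.standard_normal(n)
    return X, y


class TestStandardize:
    def test_hand_example_population_sd(self):
        z, m, s = standardize_columns(np.array([[0.0], [2.0], [4.0]]), ["x"])
        np.testing.assert_allclose(z[:, 0], [-1.22474487, 0.0, 1.22474487])
        assert m[0] == 2.0 and s[0] == pytest.approx(np.sqrt(8 / 3))

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((50, 3))
        z1, _, _ = standardize_columns(x, list("abc"))
        z2, _, _ = standardize_columns(z1, list("abc"))
        np.testing.assert_allclose(z1, z2, atol=1e-12)

    def test_constant_column_names_node(self):
        x = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(c.DegenerateColumnError, match="N7"):
            standardize_columns(x, ["N7", "N8"])


class TestSolver:
    def test_matches_reference_coordinate_descent(self):
        """Path solutions agree with sklearn's lasso_path (independent
        implementation of the same objective) to high precision."""
        from sklearn.linear_model import lasso_path

        for seed in range(4):
            X, y = _random_regression(seed)
            y = y - y.mean()
            grid = lambda_grid(X, y, 40, 1e-3)
            mine = _lasso_solve(X, y, grid)
            _, ref, _ = lasso_path(X, y, alphas=grid, tol=1e-9, max_iter=100_000)
            np.testing.assert_allclose(mine, ref, atol=1e-6)

    def test_grid_starts_at_all_zero(self):
        X, y = _random_regression(1)
        y = y - y.mean()
        grid = lambda_grid(X, y, 30, 1e-3)
        assert np.all(np.diff(grid) < 0)
        path = _lasso_solve(X, y, grid)
        assert np.all(path[:, 0] == 0.0)  # lambda_max zeroes everything
        assert np.any(path[:, 1] != 0.0)  # and is the smallest such value

    def test_monotone_sparsity_along_grid(self):
        for seed in range(5):
            X, y = _random_regression(seed, n=200, p=15, signal=0.2)
            y = y - y.mean()
            path = _lasso_solve(X, y, lambda_grid(X, y, 100, 1e-4))
            nnz = (path != 0).sum(axis=0)
            assert np.all(np.diff(nnz) >= 0)  # grid decreasing -> nnz grows


class TestNodeRegression:
    def test_penalty_free_limit_equals_ols(self):
        """At lambda=0 the fit matches the closed-form normal equations."""
        for seed in range(5):
            X, y = _random_regression(seed, n=400, p=6)
            fit = c.fit_node_regression(y, X, penalty_free=(5,), lambda_override=0.0)
            Xd = np.column_stack([np.ones(len(y)), X])
            ols, *_ = np.linalg.lstsq(Xd, y, rcond=None)
            np.testing.assert_allclose(fit.coef, ols[1:], atol=1e-6)
            assert fit.intercept == pytest.approx(ols[0], abs=1e-6)

    def test_kkt_certificate(self):
        """Every CV-selected fit satisfies L1 stationarity: zeroed
        coordinates within 1e-6 of the subgradient bound, unpenalized
        coordinates at an exact zero gradient."""
        for seed in range(3):
            X, y = _random_regression(seed, n=250, p=12)
            fit = c.fit_node_regression(y, X, penalty_free=(0,))
            kkt = c.kkt_residuals(y, X, fit, penalty_free=(0,))
            assert kkt["zero"] <= 1e-6
            assert kkt["active"] <= 1e-6
            assert kkt["free"] <= 1e-8

    def test_null_outcome_one_se_selects_empty_model(self):
        """Pure-noise outcomes: the one-SE rule returns the all-zero
        model in >=18/20 seeds (the CV-minimum rule is deliberately more
        liberal and retains a few spurious coefficients)."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            X = rng.standard_normal((500, 24))
            X = (X - X.mean(0)) / X.std(0)
            y = rng.standard_normal(500)
            fit = c.fit_node_regression(
                y, X, config=c.EstimationConfig(lambda_rule="one_se")
            )
            hits += np.all(fit.coef == 0.0)
        assert hits >= 18

    def test_signal_recovery(self):
        """y = 0.5 x1 + noise: the CV-minimum fit localizes the
        coefficient within 0.5±0.1 in >=18/20 seeds; under the one-SE
        rule the spurious coefficients are all exactly zero."""
        in_band = 0
        clean = 0
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            X = rng.standard_normal((2000, 25))
            X = (X - X.mean(0)) / X.std(0)
            y = 0.5 * X[:, 0] + 0.5 * rng.standard_normal(2000)
            fit_min = c.fit_node_regression(y, X, config=c.EstimationConfig())
            in_band += abs(fit_min.coef[0] - 0.5) <= 0.1
            fit_1se = c.fit_node_regression(
                y, X, config=c.EstimationConfig(lambda_rule="one_se")
            )
            clean += np.all(fit_1se.coef[1:] == 0.0)
        assert in_band >= 18
        assert clean >= 18

    def test_input_validation(self):
        X, y = _random_regression(0, n=9, p=3)
        with pytest.raises(c.InputError):
            c.fit_node_regression(y, X, config=c.EstimationConfig(cv_folds=10))
        X2, y2 = _random_regression(0, n=50, p=3)
        y2[0] = np.nan
        with pytest.raises(c.InputError):
            c.fit_node_regression(y2, X2)

    def test_config_validation(self):
        with pytest.raises(c.ValidationError):
            c.EstimationConfig(cv_folds=1)
        with pytest.raises(c.ValidationError):
            c.EstimationConfig(lambda_rule="bic")


class TestNetworkFit:
    def test_shape_and_covariate_handling(self, catalog, panel_factory):
        data = panel_factory(n=200, seed=4)
        net = c.fit_clpn(data)
        assert net.W.shape == (24, 24)
        assert list(net.covariate_coefs.columns) == ["gender"]
        p = 24
        assert p * p - p == 552
        boys = c.fit_clpn(data, group_filter=c.GENDER_BOY)
        assert boys.covariate_coefs.empty
        assert boys.n_subjects == int((data.gender == 0).sum())

    def test_determinism(self, panel_factory):
        data = panel_factory(n=150, seed=9)
        w1 = c.fit_clpn(data).W
        w2 = c.fit_clpn(data).W
        np.testing.assert_array_equal(w1, w2)

    def test_empty_group_rejected(self, panel_factory):
        data = panel_factory(n=30, seed=1)
        data.gender[:] = 0
        with pytest.raises(c.InputError):
            c.fit_clpn(data, group_filter=1)

    def test_linear_truth_recovery(self, catalog6, sparse_truth6):
        """On the continuous linear generator the fitted weights land
        close to the generating coefficients."""
        B, corr = sparse_truth6
        t1, t2 = simulate_linear_panel(B, 2000, 3, corr)
        net = c.fit_network_matrices(t1, t2, catalog6)
        nz = B != 0
        assert np.all(np.sign(net.W[nz]) == np.sign(B[nz]))
        assert np.max(np.abs(net.W[nz] - B[nz])) < 0.1

    def test_network_json_roundtrip(self, catalog6, sparse_truth6, tmp_path):
        B, corr = sparse_truth6
        t1, t2 = simulate_linear_panel(B, 300, 5, corr)
        net = c.fit_network_matrices(t1, t2, catalog6)
        back = c.CrossLaggedNetwork.load(net.save(tmp_path / "net.json"))
        np.testing.assert_array_equal(back.W, net.W)
        assert back.catalog == net.catalog
        assert back.config == net.config

    def test_edge_list_types(self, network_factory, catalog6):
        W = np.zeros((6, 6))
        W[0, 0] = 0.3
        W[0, 1] = -0.2
        edges = network_factory(catalog6, W).edge_list()
        assert len(edges) == 36
        auto = edges[(edges["from"] == "N1") & (edges["to"] == "N1")]
        assert auto["edge_type"].item() == "auto"


class TestEdgeSummary:
    def test_identity_and_zero(self, catalog, network_factory):
        s = c.edge_summary(network_factory(catalog, np.eye(24) * 0.17))
        assert s.mean_abs_auto == pytest.approx(0.17)
        assert s.mean_abs_cross == 0.0
        assert s.n_cross_edges == 552
        z = c.edge_summary(network_factory(catalog, np.zeros((24, 24))))
        assert z.mean_abs_auto == 0.0 and z.mean_abs_cross == 0.0

    def test_hand_arithmetic_three_nodes(self, network_factory):
        cat3 = c.SymptomCatalog.from_records(
            [
                {"node_id": "N1", "community": "NSSI"},
                {"node_id": "D1", "community": "DEP"},
                {"node_id": "A1", "community": "ANX"},
            ]
        )
        W = np.full((3, 3), 0.05)
        np.fill_diagonal(W, [0.1, 0.2, 0.3])
        s = c.edge_summary(network_factory(cat3, W))
        assert s.mean_abs_auto == pytest.approx(0.2)
        assert s.mean_abs_cross == pytest.approx(0.05)
        assert s.n_cross_edges == 6
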