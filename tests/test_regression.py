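"""PLSR and LS-SVR: oracle equivalences, CV selection, hyperparameter search."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from teaspec.regression import (
    fit_lssvr,
    fit_plsr,
    grid_search_lssvr,
    kfold_indices,
    select_nlvs,
)


def _ols_predict(X, y, X_new):
    A = np.c_[np.ones(len(X)), X]
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return np.c_[np.ones(len(X_new)), X_new] @ coef


class TestFitPlsr:
    def test_exact_recovery_at_full_rank(self, rng):
        X = rng.standard_normal((30, 6))
        y = X @ rng.standard_normal(6) + 2.0
        model = fit_plsr(X, y, 6)
        assert np.allclose(model.predict(X), y, atol=1e-8)

    def test_full_components_match_ols(self, rng):
        X = rng.standard_normal((40, 8))
        y = X @ rng.standard_normal(8) + rng.normal(0, 0.3, 40)
        model = fit_plsr(X, y, 8)
        assert np.allclose(model.predict(X), _ols_predict(X, y, X), atol=1e-8)

    @pytest.mark.parametrize("ncomp", [1, 2, 4, 7])
    def test_matches_sklearn_pls1(self, rng, ncomp):
        X = rng.standard_normal((35, 10))
        y = X @ rng.standard_normal(10) + rng.normal(0, 0.5, 35)
        ours = fit_plsr(X, y, ncomp)
        sk = PLSRegression(n_components=ncomp, scale=False).fit(X, y[:, None])
        assert np.allclose(ours.predict(X), sk.predict(X).ravel(), atol=1e-8)

    def test_single_lv_weights_informative_column(self, rng):
        n = 60
        informative = rng.standard_normal(n)
        noise = 0.01 * rng.standard_normal((n, 5))
        X = np.column_stack([informative, *noise.T])
        model = fit_plsr(X, 3.0 * informative, 1)
        w = np.abs(model.coef)
        assert w[0] > 5 * w[1:].max()

    def test_rank_overflow_truncates_with_warning(self, rng):
        X = rng.standard_normal((5, 10))
        y = rng.standard_normal(5)
        with pytest.warns(UserWarning, match="truncated"):
            model = fit_plsr(X, y, 10)
        assert model.n_components <= 4

    def test_centering_invariance_constant_shift_in_y(self, rng):
        X = rng.standard_normal((25, 5))
        y = rng.standard_normal(25)
        base = fit_plsr(X, y, 3).predict(X)
        shifted = fit_plsr(X, y + 10.0, 3).predict(X)
        assert np.allclose(shifted, base + 10.0, atol=1e-8)


class TestSelectNlvs:
    def test_rank3_noiseless_selects_at_most_three(self, rng):
        scores = rng.standard_normal((50, 3))
        loadings = rng.standard_normal((3, 20))
        X = scores @ loadings
        y = scores @ np.array([1.0, -0.5, 0.25])
        nlvs, table = select_nlvs(X, y, max_nlvs=8, k=10, seed=0)
        assert nlvs <= 3
        assert table[nlvs] <= 1e-6

    def test_same_seed_reproduces_selection(self, rng):
        X = rng.standard_normal((40, 12))
        y = rng.standard_normal(40)
        assert select_nlvs(X, y, 6, 5, seed=3) == select_nlvs(X, y, 6, 5, seed=3)

    def test_k_equals_n_is_leave_one_out(self):
        folds = kfold_indices(12, 12, seed=1)
        assert all(len(f) == 1 for f in folds)
        assert sorted(np.concatenate(folds).tolist()) == list(range(12))

    def test_invalid_max_rejected(self, rng):
        with pytest.raises(ValueError):
            select_nlvs(rng.standard_normal((10, 3)), rng.standard_normal(10), 0)


class TestLssvr:
    def test_interpolation_limit_large_c(self, rng):
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        model = fit_lssvr(X, y, gamma=0.5, C=1e8)
        assert np.abs(model.predict(X) - y).max() < 1e-4

    def test_linear_kernel_large_c_matches_ols(self, rng):
        X = rng.standard_normal((25, 4))
        y = X @ np.array([1.0, -1.0, 0.5, 2.0]) + 0.7 + rng.normal(0, 0.1, 25)
        model = fit_lssvr(X, y, gamma=1.0, C=1e8, kernel="linear")
        assert np.allclose(model.predict(X), _ols_predict(X, y, X), atol=1e-6)

    def test_kkt_residual_small(self, rng):
        X = rng.standard_normal((15, 3))
        y = rng.standard_normal(15)
        model = fit_lssvr(X, y, gamma=0.3, C=10.0)
        assert model.kkt_residual(y) < 1e-8

    def test_vanishing_gamma_predicts_training_mean(self, rng):
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        model = fit_lssvr(X, y, gamma=1e-12, C=1.0)
        assert np.abs(model.predict(X) - y.mean()).max() < 1e-3

    def test_invalid_hyperparameters_rejected(self, rng):
        X, y = rng.standard_normal((5, 2)), rng.standard_normal(5)
        with pytest.raises(ValueError):
            fit_lssvr(X, y, gamma=0.0, C=1.0)
        with pytest.raises(ValueError):
            fit_lssvr(X, y, gamma=1.0, C=-1.0)


class TestGridSearch:
    def test_singleton_grid_returned(self, rng):
        X, y = rng.standard_normal((15, 3)), rng.standard_normal(15)
        gamma, C, surface = grid_search_lssvr(X, y, [0.5], [2.0], k=3)
        assert (gamma, C) == (0.5, 2.0)
        assert len(surface) == 1

    def test_surface_exhaustive(self, rng):
        X, y = rng.standard_normal((15, 3)), rng.standard_normal(15)
        gammas, Cs = [0.1, 1.0], [1.0, 10.0, 100.0]
        _, _, surface = grid_search_lssvr(X, y, gammas, Cs, k=3)
        assert len(surface) == 6
        assert {(g, c) for g, c, _ in surface} == {(g, c) for g in gammas for c in Cs}

    def test_argmin_verified_by_reevaluation(self, rng):
        X = rng.standard_normal((24, 4))
        y = np.sin(X[:, 0]) + 0.1 * rng.standard_normal(24)
        gamma, C, surface = grid_search_lssvr(X, y, [0.1, 1.0], [1.0, 100.0], k=4, seed=2)
        best = min(s[2] for s in surface)
        chosen = [s[2] for s in surface if s[0] == gamma and s[1] == C][0]
        assert chosen == pytest.approx(best)
        # brute re-evaluation of the chosen pair reproduces its RMSECV
        folds = kfold_indices(24, 4, seed=2)
        sse = 0.0
        for test in folds:
            train = np.setdiff1d(np.arange(24), test)
            m = fit_lssvr(X[train], y[train], gamma, C)
            sse += ((m.predict(X[test]) - y[test]) ** 2).sum()
        assert np.sqrt(sse / 24) == pytest.approx(chosen, abs=1e-10)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            grid_search_lssvr(rng.standard_normal((10, 2)), rng.standard_normal(10), [], [1.0])
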