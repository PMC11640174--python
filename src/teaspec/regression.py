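"""Calibration models: PLS1 regression with cross-validated latent-variable
selection, and least-squares support vector regression (LS-SVR).

PLSR is implemented as the univariate-response NIPALS sequence with X/y
deflation; for a single response this yields the same regression vector as
SIMPLS, and the fit is fully deterministic. The number of latent variables
(nLVs) is chosen by k-fold cross-validation (k = 10 by default), taking the
argmin-RMSECV count (smallest count on ties).

LS-SVR replaces the SVR quadratic program with one linear KKT system

    [[0, 1'], [1, K + I/C]] [b; alpha] = [0; y]

with an RBF kernel K_ij = exp(-gamma ||x_i - x_j||^2). Hyperparameters
(gamma, C) come from an exhaustive grid search under k-fold RMSECV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "PLSRModel",
    "LSSVRModel",
    "fit_plsr",
    "select_nlvs",
    "fit_lssvr",
    "grid_search_lssvr",
    "kfold_indices",
    "pls_rmsecv",
    "DEFAULT_GAMMA_GRID",
    "DEFAULT_C_GRID",
]

# libSVM-style log2 grids
DEFAULT_GAMMA_GRID = tuple(2.0 ** e for e in range(-15, 4, 2))
DEFAULT_C_GRID = tuple(2.0 ** e for e in range(-5, 16, 2))

_EPS = 1e-12


def kfold_indices(n: int, k: int, seed: int | None = 0) -> list[np.ndarray]:
    """Contiguous fold assignment after a seeded shuffle; ``seed=None``
    keeps the original order. ``k = n`` gives leave-one-out."""
    if k < 2 or k > n:
        raise ValueError("need 2 <= k <= n folds")
    idx = np.arange(n)
    if seed is not None:
        idx = np.random.default_rng(seed).permutation(n)
    return [np.sort(part) for part in np.array_split(idx, k)]


def _pls1_decompose(Xc: np.ndarray, yc: np.ndarray, ncomp: int):
    """NIPALS PLS1 with deflation. Returns (W, P, q, n_used)."""
    n, p = Xc.shape
    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    q = np.zeros(ncomp)
    Xd = Xc.copy()
    yd = yc.copy()
    used = 0
    for a in range(ncomp):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < _EPS:
            break
        w /= nw
        t = Xd @ w
        tt = t @ t
        if tt < _EPS:
            break
        P[:, a] = Xd.T @ t / tt
        q[a] = yd @ t / tt
        W[:, a] = w
        Xd -= np.outer(t, P[:, a])
        yd -= q[a] * t
        used = a + 1
    return W[:, :used], P[:, :used], q[:used], used


def _coef_path(W, P, q):
    """Regression vectors for 1..A components, shape (p, A)."""
    p, A = W.shape
    coefs = np.zeros((p, A))
    R = np.zeros((p, A))  # W (P'W)^-1, built incrementally
    for a in range(A):
        r = W[:, a].copy()
        for b in range(a):
            r -= (P[:, b] @ W[:, a]) * R[:, b]
        # normalize so that P[:, a] @ r == 1
        denom = P[:, a] @ r
        if abs(denom) < _EPS:
            coefs[:, a:] = coefs[:, a - 1 : a] if a else 0.0
            return coefs[:, : max(a, 1)]
        R[:, a] = r / denom
        coefs[:, a] = (coefs[:, a - 1] if a else 0.0) + q[a] * R[:, a]
    return coefs


@dataclass
class PLSRModel:
    """Fitted PLS1 model: centering parameters plus a regression vector."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    coef: np.ndarray
    cv_table: dict | None = None  # nLVs -> RMSECV, when CV-selected

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.coef.size:
            raise ValueError("band count mismatch with fitted model")
        return (X - self.x_mean) @ self.coef + self.y_mean


def fit_plsr(X, y, n_components: int) -> PLSRModel:
    """Deterministic PLS1 fit; a component request beyond the effective
    rank is truncated with a warning."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    cap = min(n - 1, p)
    if n_components > cap:
        warnings.warn(f"n_components truncated from {n_components} to rank bound {cap}",
                      stacklevel=2)
        n_components = cap
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, used = _pls1_decompose(X - x_mean, y - y_mean, n_components)
    if used == 0:
        return PLSRModel(0, x_mean, y_mean, np.zeros(p))
    if used < n_components:
        warnings.warn(f"n_components truncated from {n_components} to effective rank {used}",
                      stacklevel=2)
    coefs = _coef_path(W, P, q)
    return PLSRModel(coefs.shape[1], x_mean, y_mean, coefs[:, -1])


def pls_rmsecv(X, y, max_components: int, folds: list[np.ndarray]) -> np.ndarray:
    """RMSECV for 1..max_components latent variables over the given folds.

    One decomposition per fold serves every component count (the PLS1
    coefficient path is cumulative), which keeps selector loops cheap.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    n = X.shape[0]
    max_components = min(max_components, X.shape[1])
    press = np.zeros(max_components)
    counted = np.zeros(max_components)
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        max_c = min(max_components, train.size - 1)
        if max_c < 1:
            raise ValueError("fold leaves too few training rows")
        Xt, yt = X[train], y[train]
        xm, ym = Xt.mean(axis=0), yt.mean()
        W, P, q, used = _pls1_decompose(Xt - xm, yt - ym, max_c)
        if used == 0:
            preds = np.full((test.size, max_components), ym)
        else:
            coefs = _coef_path(W, P, q)  # (p, used)
            preds = (X[test] - xm) @ coefs + ym
            if coefs.shape[1] < max_components:  # rank-limited: pad with last
                pad = np.repeat(preds[:, -1:], max_components - coefs.shape[1], axis=1)
                preds = np.hstack([preds, pad])
        err = (preds - y[test, None]) ** 2
        press[: err.shape[1]] += err.sum(axis=0)
        counted[: err.shape[1]] += test.size
    return np.sqrt(press / counted)


def select_nlvs(X, y, max_nlvs: int = 15, k: int = 10, seed: int = 0):
    """Choose the number of latent variables by k-fold CV.

    Returns ``(nlvs, cv_table)``; ties take the smallest count.
    """
    if max_nlvs < 1:
        raise ValueError("max_nlvs must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    n = X.shape[0]
    k = min(k, n)
    folds = kfold_indices(n, k, seed)
    max_nlvs = min(max_nlvs, X.shape[1], n - max(len(f) for f in folds) - 1)
    max_nlvs = max(max_nlvs, 1)
    rmsecv = pls_rmsecv(X, y, max_nlvs, folds)
    best = int(np.argmin(rmsecv))  # lowest index wins ties
    table = {a + 1: float(r) for a, r in enumerate(rmsecv)}
    return best + 1, table


def fit_plsr_cv(X, y, max_nlvs: int = 15, k: int = 10, seed: int = 0) -> PLSRModel:
    """Convenience: CV-select nLVs, then fit on all rows."""
    nlvs, table = select_nlvs(X, y, max_nlvs, k, seed)
    model = fit_plsr(X, y, nlvs)
    model.cv_table = table
    return model


# ---------------------------------------------------------------------------
# LS-SVR
# ---------------------------------------------------------------------------


def _kernel(A, B, gamma: float, kind: str) -> np.ndarray:
    if kind == "rbf":
        return np.exp(-gamma * cdist(A, B, "sqeuclidean"))
    if kind == "linear":
        return A @ B.T
    raise ValueError(f"unknown kernel {kind!r}")


@dataclass
class LSSVRModel:
    gamma: float
    C: float
    alpha: np.ndarray
    b: float
    X_train: np.ndarray
    x_mean: np.ndarray
    kernel: str = "rbf"

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64)) - self.x_mean
        K = _kernel(X, self.X_train, self.gamma, self.kernel)
        return K @ self.alpha + self.b

    def kkt_residual(self, y) -> float:
        """Max residual of the solved linear system against targets y."""
        n = self.alpha.size
        K = _kernel(self.X_train, self.X_train, self.gamma, self.kernel)
        top = abs(self.alpha.sum())
        rows = K @ self.alpha + self.alpha / self.C + self.b - np.asarray(y, dtype=np.float64)
        return float(max(top, np.abs(rows).max()))


def fit_lssvr(X, y, gamma: float, C: float, kernel: str = "rbf") -> LSSVRModel:
    """Solve the LS-SVR KKT system directly; near-singular systems get a
    1e-12 ridge jitter with a warning."""
    if gamma <= 0 or C <= 0:
        raise ValueError("gamma and C must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    n = X.shape[0]
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    K = _kernel(Xc, Xc, gamma, kernel)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / C
    rhs = np.concatenate([[0.0], y])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        warnings.warn("singular LS-SVR system; adding 1e-12 ridge jitter", stacklevel=2)
        A[1:, 1:] += 1e-12 * np.eye(n)
        sol = np.linalg.solve(A, rhs)
    return LSSVRModel(gamma, C, sol[1:], float(sol[0]), Xc, x_mean, kernel)


def grid_search_lssvr(
    X,
    y,
    gamma_grid=DEFAULT_GAMMA_GRID,
    C_grid=DEFAULT_C_GRID,
    k: int = 10,
    seed: int = 0,
    kernel: str = "rbf",
):
    """Exhaustive k-fold RMSECV over the (gamma, C) grid.

    Returns ``(gamma, C, surface)`` where surface is a list of
    ``(gamma, C, rmsecv)`` triples; ties prefer smaller C, then smaller
    gamma.
    """
    gamma_grid = list(gamma_grid)
    C_grid = list(C_grid)
    if not gamma_grid or not C_grid:
        raise ValueError("grids must be non-empty")
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    n = X.shape[0]
    k = min(k, n)
    folds = kfold_indices(n, k, seed)
    surface = []
    for gamma in gamma_grid:
        for C in C_grid:
            sse = 0.0
            for test in folds:
                train = np.setdiff1d(np.arange(n), test)
                model = fit_lssvr(X[train], y[train], gamma, C, kernel)
                pred = model.predict(X[test])
                sse += float(((pred - y[test]) ** 2).sum())
            surface.append((gamma, C, np.sqrt(sse / n)))
    best = min(surface, key=lambda t: (t[2], t[1], t[0]))
    return best[0], best[1], surface
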