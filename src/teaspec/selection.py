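"""Characteristic-wavelength selection: CARS and VISSA.

CARS (competitive adaptive reweighted sampling) runs N Monte-Carlo
iterations; each iteration fits a PLS model on a random row subset of the
currently retained bands, uses the absolute regression coefficients as
band weights, enforces an exponentially decreasing retention schedule
(EDF: keep-ratio r_i = a e^{-k i} with r_1 = 1 and r_N = 2/p), then applies
adaptive reweighted sampling (a weighted draw with replacement — a band
survives if drawn at least once). The band set of the minimum-RMSECV
iteration is returned.

VISSA (variable iterative space shrinkage approach) maintains per-band
inclusion weights in [0, 1] starting at 0.5. Each iteration draws a
weighted binary sampling matrix (column j contains exactly
round(w_j * n_submodels) ones, row-shuffled), scores every sub-model by
k-fold RMSECV, and updates each weight to the band's inclusion frequency
among the best ``top_fraction`` sub-models. An iteration is accepted only
if its best RMSECV improves on the incumbent; the final band set is the
weights that reached 1.

Both selectors are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .regression import fit_plsr, kfold_indices, pls_rmsecv

__all__ = [
    "SelectionResult",
    "edf_schedule",
    "cars_select",
    "vissa_select",
    "selection_summary",
]


@dataclass
class SelectionResult:
    method: str
    selected: np.ndarray  # sorted unique band indices
    rmsecv_trace: list
    best_iteration: int
    settings: dict
    seed: int
    weights: np.ndarray | None = None  # VISSA final inclusion weights
    n_bands_trace: list | None = None  # CARS retained-band count per iteration

    def __post_init__(self):
        self.selected = np.asarray(self.selected, dtype=int)
        if self.selected.size == 0:
            raise ValueError("selected band set is empty")
        if np.unique(self.selected).size != self.selected.size:
            raise ValueError("selected band indices must be unique")
        if not np.all(np.diff(self.selected) > 0):
            raise ValueError("selected band indices must be sorted")


def edf_schedule(p: int, N: int) -> np.ndarray:
    """Exponentially decreasing retention ratios r_1..r_N with r_1 = 1 and
    r_N = 2/p."""
    if p < 2 or N < 2:
        raise ValueError("need p >= 2 bands and N >= 2 iterations")
    k = np.log(p / 2.0) / (N - 1)
    i = np.arange(1, N + 1)
    return np.exp(-k * (i - 1))


def _subset_rmsecv(X, y, bands, folds, max_components: int) -> float:
    """Best k-fold RMSECV over 1..max_components latent variables on the
    given band subset."""
    r = pls_rmsecv(X[:, bands], y, min(max_components, len(bands)), folds)
    return float(r.min())


def cars_select(
    X,
    y,
    N: int = 65,
    folds: int = 5,
    seed: int = 0,
    mc_row_fraction: float = 0.8,
    max_components: int = 10,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling band selection."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    if not (n > folds >= 2):
        raise ValueError("need n > folds >= 2")
    if p < 2 or N < 2:
        raise ValueError("need p >= 2 and N >= 2")
    rng = np.random.default_rng(seed)
    ratios = edf_schedule(p, N)
    cv_folds = kfold_indices(n, folds, seed)
    n_sub = max(2, int(np.ceil(mc_row_fraction * n)))

    retained = np.arange(p)
    trace: list[float] = []
    band_sets: list[np.ndarray] = []
    for i in range(N):
        rows = np.sort(rng.choice(n, size=min(n_sub, n), replace=False))
        ncomp = min(max_components, len(rows) - 1, retained.size)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_plsr(X[np.ix_(rows, retained)], y[rows], max(ncomp, 1))
        w = np.abs(model.coef)

        n_keep = int(np.ceil(ratios[i] * p))
        n_keep = int(np.clip(n_keep, 2, retained.size))
        # EDF: keep the top n_keep by weight (stable: ties to lowest index)
        order = np.argsort(-w, kind="stable")[:n_keep]
        retained = retained[np.sort(order)]
        w = w[np.sort(order)]

        # ARS: weighted draw with replacement; survive if drawn at least once
        if w.sum() > 0:
            draws = rng.choice(retained.size, size=n_keep, replace=True, p=w / w.sum())
            survive = np.unique(draws)
            if survive.size >= 2:
                keep_mask = np.zeros(retained.size, dtype=bool)
                keep_mask[survive] = True
                retained = retained[keep_mask]
                w = w[keep_mask]

        trace.append(_subset_rmsecv(X, y, retained, cv_folds, max_components))
        band_sets.append(retained.copy())
    n_bands_trace = [len(s) for s in band_sets]

    best = int(np.argmin(trace))
    return SelectionResult(
        method="CARS",
        selected=np.sort(band_sets[best]),
        rmsecv_trace=trace,
        best_iteration=best,
        settings={
            "N": N, "folds": folds, "mc_row_fraction": mc_row_fraction,
            "max_components": max_components,
        },
        seed=seed,
        n_bands_trace=n_bands_trace,
    )


def _binary_sampling_matrix(weights: np.ndarray, n_submodels: int, rng) -> np.ndarray:
    """Weighted binary matrix: column j holds round(w_j * n_submodels)
    ones, positions shuffled independently per column."""
    p = weights.size
    counts = np.rint(weights * n_submodels).astype(int)
    M = np.zeros((n_submodels, p), dtype=bool)
    for j in range(p):
        c = counts[j]
        if c >= n_submodels:
            M[:, j] = True
        elif c > 0:
            M[rng.permutation(n_submodels)[:c], j] = True
    return M


def vissa_select(
    X,
    y,
    n_submodels: int = 1000,
    top_fraction: float = 0.05,
    folds: int = 5,
    max_iters: int = 50,
    seed: int = 0,
    max_components: int = 10,
) -> SelectionResult:
    """Variable iterative space shrinkage approach band selection."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    if n_submodels < 100:
        raise ValueError("need n_submodels >= 100")
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    cv_folds = kfold_indices(n, folds, seed)
    n_top = max(1, int(round(top_fraction * n_submodels)))

    weights = np.full(p, 0.5)
    incumbent = np.inf
    trace: list[float] = []
    for _ in range(max_iters):
        M = _binary_sampling_matrix(weights, n_submodels, rng)
        scores = np.full(n_submodels, np.inf)
        for s in range(n_submodels):
            bands = np.nonzero(M[s])[0]
            if bands.size == 0:
                continue
            scores[s] = _subset_rmsecv(X, y, bands, cv_folds, max_components)
        order = np.argsort(scores, kind="stable")  # ties -> lower sub-model index
        best_rmsecv = float(scores[order[0]])
        if not best_rmsecv < incumbent:
            break
        weights = M[order[:n_top]].mean(axis=0)
        incumbent = best_rmsecv
        trace.append(best_rmsecv)

    selected = np.nonzero(weights >= 0.999)[0]
    if selected.size == 0:
        warnings.warn(
            "no band reached inclusion weight 1; returning bands with weight > 0.5",
            stacklevel=2,
        )
        selected = np.nonzero(weights > 0.5)[0]
    if selected.size == 0:  # fully degenerate input
        selected = np.array([int(np.argmax(weights))])
    if not trace:
        trace = [incumbent if np.isfinite(incumbent) else float("nan")]
    return SelectionResult(
        method="VISSA",
        selected=np.sort(selected),
        rmsecv_trace=trace,
        best_iteration=int(np.argmin(trace)),
        settings={
            "n_submodels": n_submodels, "top_fraction": top_fraction,
            "folds": folds, "max_iters": max_iters, "max_components": max_components,
        },
        seed=seed,
        weights=weights,
    )


def selection_summary(result: SelectionResult, total_bands: int) -> dict:
    """Count and percentage of selected bands, percentage rounded to one
    decimal (e.g. 67 of 943 -> 7.1)."""
    count = int(result.selected.size)
    if total_bands < 1:
        raise ValueError("total_bands must be >= 1")
    return {
        "method": result.method,
        "n_selected": count,
        "percent_of_total": round(100.0 * count / total_bands, 1),
        "best_rmsecv": float(np.min(result.rmsecv_trace)),
        "best_iteration": result.best_iteration,
    }
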