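"""Calibration/prediction splitting by SPXY (sample-set partitioning based
on joint X-Y distances).

SPXY extends Kennard-Stone max-min selection with a response term: the
distance between samples i and j is

    d(i, j) = ||x_i - x_j||_2 / max_kl ||x_k - x_l||_2 + |y_i - y_j| / max_kl |y_k - y_l|

so selected calibration samples cover the joint spectral/chemical space.
Selection is fully deterministic; ties break toward the lowest original
row index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = ["SplitResult", "joint_distance_matrix", "joint_distance", "spxy_split", "stratified_spxy_split"]


@dataclass(frozen=True)
class SplitResult:
    train_indices: np.ndarray
    test_indices: np.ndarray
    selection_order: np.ndarray  # train samples in the order selected
    train_fraction: float

    def __post_init__(self):
        tr, te = set(self.train_indices.tolist()), set(self.test_indices.tolist())
        if tr & te:
            raise ValueError("train/test overlap")


def joint_distance_matrix(X, y) -> np.ndarray:
    """All-pairs SPXY distance, each term normalized by its maximum."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    dx = squareform(pdist(X))
    dy = np.abs(y[:, None] - y[None, :])
    d = np.zeros_like(dx)
    for name, term in (("X", dx), ("y", dy)):
        m = term.max()
        if m == 0:
            warnings.warn(f"all samples identical in {name}; that distance term dropped",
                          stacklevel=2)
        else:
            d += term / m
    return d


def joint_distance(xi, xj, yi, yj, x_scale: float, y_scale: float) -> float:
    """Single-pair SPXY distance with externally supplied normalizers."""
    if x_scale <= 0 or y_scale <= 0:
        raise ValueError("scales must be positive")
    xi, xj = np.asarray(xi, dtype=np.float64), np.asarray(xj, dtype=np.float64)
    return float(np.linalg.norm(xi - xj) / x_scale + abs(float(yi) - float(yj)) / y_scale)


def _ks_select(d: np.ndarray, n_train: int) -> np.ndarray:
    """Greedy Kennard-Stone max-min on a precomputed distance matrix.
    Seeds with the maximum-distance pair; ties resolve to the smallest
    (row, col) index pair."""
    n = d.shape[0]
    flat = np.argmax(d)  # first occurrence = lowest flat index on ties
    i, j = divmod(int(flat), n)
    order = [min(i, j), max(i, j)]
    selected = np.zeros(n, dtype=bool)
    selected[order] = True
    # min distance from each candidate to the selected set
    mind = np.minimum(d[:, order[0]], d[:, order[1]])
    while len(order) < n_train:
        mind_masked = np.where(selected, -np.inf, mind)
        nxt = int(np.argmax(mind_masked))  # argmax returns lowest index on ties
        order.append(nxt)
        selected[nxt] = True
        mind = np.minimum(mind, d[:, nxt])
    return np.array(order, dtype=int)


def spxy_split(X, y, train_fraction: float = 0.75) -> SplitResult:
    """Deterministic SPXY split; train size = ceil(train_fraction * n)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(np.ceil(train_fraction * n))
    n_train = min(max(n_train, 2), n - 1)
    d = joint_distance_matrix(X, y)
    order = _ks_select(d, n_train)
    train = np.sort(order)
    test = np.setdiff1d(np.arange(n), train)
    return SplitResult(train, test, order, train_fraction)


def stratified_spxy_split(X, y, groups, train_fraction: float = 0.75) -> SplitResult:
    """SPXY run within each group, unioned — the comprehensive-process
    split that draws equal proportions from every process step."""
    groups = np.asarray(groups)
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    train_parts, test_parts, order_parts = [], [], []
    for g in dict.fromkeys(groups.tolist()):  # preserve first-appearance order
        idx = np.nonzero(groups == g)[0]
        sub = spxy_split(X[idx], y[idx], train_fraction)
        train_parts.append(idx[sub.train_indices])
        test_parts.append(idx[sub.test_indices])
        order_parts.append(idx[sub.selection_order])
    return SplitResult(
        np.sort(np.concatenate(train_parts)),
        np.sort(np.concatenate(test_parts)),
        np.concatenate(order_parts),
        train_fraction,
    )
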