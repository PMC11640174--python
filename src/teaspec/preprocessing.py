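"""Spectral pretreatments as fit-on-calibration / apply-anywhere transforms.

Four pretreatments are supported, each learned (where it has parameters)
exclusively from calibration rows and then applied unchanged to prediction
rows and map pixels:

* MSC — multiplicative scatter correction: each spectrum is regressed on a
  reference spectrum (the calibration mean) and the fitted offset/slope are
  removed, ``(x - b) / a``.
* CT — mean centering: subtraction of stored per-band calibration means.
* SG — Savitzky-Golay smoothing (sliding local-polynomial fit).
* D1 — first derivative via a Savitzky-Golay derivative filter, scaled by
  the channel spacing so units are reflectance per nm.

``Pretreatment`` wraps a named chain of steps with strict fit-before-apply
bookkeeping, which guarantees the exact same transformation is used on the
calibration set, the prediction set and every cube pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "Pretreatment",
    "make_pretreatment",
    "fit_msc",
    "apply_msc",
    "fit_center",
    "apply_center",
    "sg_smooth",
    "sg_derivative",
    "PRETREATMENT_NAMES",
]

PRETREATMENT_NAMES = ("MSC", "CT", "D1", "SG", "NONE")

# defaults chosen per common chemometrics practice; both config-exposed
DEFAULT_SG_WINDOW, DEFAULT_SG_POLYORDER = 11, 2
DEFAULT_D1_WINDOW, DEFAULT_D1_POLYORDER = 7, 2


def _as2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    return X[None, :] if X.ndim == 1 else X


def fit_msc(X_cal) -> np.ndarray:
    """MSC reference spectrum = mean calibration spectrum."""
    X = _as2d(X_cal)
    if X.shape[0] < 2:
        raise ValueError("MSC needs >= 2 calibration rows for a meaningful reference")
    return X.mean(axis=0)


def apply_msc(X, reference: np.ndarray) -> np.ndarray:
    """Regress each row on the reference (x = a*ref + b) and return (x-b)/a."""
    X = _as2d(X)
    ref = np.asarray(reference, dtype=np.float64)
    if X.shape[1] != ref.size:
        raise ValueError("band count mismatch with MSC reference")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise ValueError("constant MSC reference spectrum")
    a = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(a == 0):
        bad = int(np.nonzero(a == 0)[0][0])
        raise ValueError(f"row {bad} has zero MSC slope (constant spectrum)")
    b = X.mean(axis=1) - a * ref.mean()
    return (X - b[:, None]) / a[:, None]


def fit_center(X_cal) -> np.ndarray:
    return _as2d(X_cal).mean(axis=0)


def apply_center(X, means: np.ndarray) -> np.ndarray:
    X = _as2d(X)
    means = np.asarray(means, dtype=np.float64)
    if X.shape[1] != means.size:
        raise ValueError("band count mismatch with stored means")
    return X - means


def _check_sg(window: int, polyorder: int, p: int) -> None:
    if window % 2 == 0:
        raise ValueError("SG window must be odd")
    if window <= polyorder:
        raise ValueError("SG window must exceed the polynomial order")
    if window > p:
        raise ValueError(f"SG window {window} exceeds band count {p}")


def sg_smooth(X, window: int = DEFAULT_SG_WINDOW, polyorder: int = DEFAULT_SG_POLYORDER) -> np.ndarray:
    """Savitzky-Golay smoothing; edges use polynomial extrapolation of the
    terminal windows."""
    X = _as2d(X)
    _check_sg(window, polyorder, X.shape[1])
    return savgol_filter(X, window, polyorder, axis=1, mode="interp")


def sg_derivative(
    X,
    window: int = DEFAULT_D1_WINDOW,
    polyorder: int = DEFAULT_D1_POLYORDER,
    spacing_nm: float = 1.0,
) -> np.ndarray:
    """First derivative (units per nm) via the SG derivative filter."""
    if polyorder < 1:
        raise ValueError("derivative needs polyorder >= 1")
    X = _as2d(X)
    _check_sg(window, polyorder, X.shape[1])
    return savgol_filter(X, window, polyorder, deriv=1, delta=spacing_nm, axis=1, mode="interp")


@dataclass
class Pretreatment:
    """A fitted, ordered pretreatment chain.

    ``steps`` is a list of names from {MSC, CT, D1, SG, NONE}; fitting
    learns MSC references / CT means from calibration rows only (each step
    fitted on the output of the previous one), and ``apply`` replays the
    chain on any row block.
    """

    steps: list
    options: dict = field(default_factory=dict)
    fitted_: dict | None = None
    spacing_nm: float = 1.0

    def __post_init__(self):
        self.steps = [s.upper() for s in self.steps]
        for s in self.steps:
            if s not in PRETREATMENT_NAMES:
                raise ValueError(f"unknown pretreatment {s!r}")

    @property
    def name(self) -> str:
        active = [s for s in self.steps if s != "NONE"]
        return "-".join(active) if active else "NONE"

    def fit(self, X_cal) -> "Pretreatment":
        X = _as2d(X_cal).copy()
        fitted = {}
        for i, s in enumerate(self.steps):
            if s == "MSC":
                fitted[i] = fit_msc(X)
            elif s == "CT":
                fitted[i] = fit_center(X)
            X = self._apply_step(X, s, fitted.get(i))
        self.fitted_ = fitted
        return self

    def _apply_step(self, X, step: str, param):
        if step == "MSC":
            return apply_msc(X, param)
        if step == "CT":
            return apply_center(X, param)
        if step == "SG":
            return sg_smooth(
                X,
                self.options.get("sg_window", DEFAULT_SG_WINDOW),
                self.options.get("sg_polyorder", DEFAULT_SG_POLYORDER),
            )
        if step == "D1":
            return sg_derivative(
                X,
                self.options.get("d1_window", DEFAULT_D1_WINDOW),
                self.options.get("d1_polyorder", DEFAULT_D1_POLYORDER),
                self.spacing_nm,
            )
        return X  # NONE

    def apply(self, X) -> np.ndarray:
        if self.fitted_ is None:
            raise RuntimeError("pretreatment applied before fit")
        squeeze = np.asarray(X).ndim == 1
        out = _as2d(X).copy()
        for i, s in enumerate(self.steps):
            out = self._apply_step(out, s, self.fitted_.get(i))
        return out[0] if squeeze else out

    def fit_apply(self, X_cal) -> np.ndarray:
        return self.fit(X_cal).apply(X_cal)


def make_pretreatment(name: str, spacing_nm: float = 1.0, **options) -> Pretreatment:
    """Single-step chain by name; chains are built as Pretreatment([...])."""
    return Pretreatment([name], options=options, spacing_nm=spacing_nm)
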