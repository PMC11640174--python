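"""The modeling unit: an n-samples x p-bands spectral matrix with its
wavelength grid, reference chemistry vector, and process-step labels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CalibrationSet"]


@dataclass
class CalibrationSet:
    """Spectral matrix plus reference TFAA values for model building.

    Attributes
    ----------
    X : (n, p) reflectance matrix
    wavelengths_nm : (p,) ascending grid
    y : (n,) reference TFAA, % dry mass
    steps : (n,) process-step label per sample (e.g. FLS / SF / HD)
    sample_ids : (n,) unique identifiers
    """

    X: np.ndarray
    wavelengths_nm: np.ndarray
    y: np.ndarray
    steps: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.steps = np.asarray(self.steps)
        self.sample_ids = np.asarray(self.sample_ids)
        n, p = self.X.shape
        if self.wavelengths_nm.shape != (p,):
            raise ValueError("wavelength grid does not match band axis")
        for name, arr in (("y", self.y), ("steps", self.steps), ("sample_ids", self.sample_ids)):
            if arr.shape != (n,):
                raise ValueError(f"{name} length does not match number of samples")
        if len(set(self.sample_ids.tolist())) != n:
            raise ValueError("sample ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def subset(self, rows) -> "CalibrationSet":
        rows = np.asarray(rows)
        return CalibrationSet(
            self.X[rows], self.wavelengths_nm.copy(), self.y[rows],
            self.steps[rows], self.sample_ids[rows],
        )

    def select_bands(self, indices) -> "CalibrationSet":
        indices = np.asarray(indices, dtype=int)
        return CalibrationSet(
            self.X[:, indices], self.wavelengths_nm[indices], self.y.copy(),
            self.steps.copy(), self.sample_ids.copy(),
        )

    def for_step(self, step: str) -> "CalibrationSet":
        return self.subset(np.nonzero(self.steps == step)[0])

    def to_frame(self) -> pd.DataFrame:
        """Wide table: id/step/tfaa columns followed by one column per band."""
        cols = {"sample_id": self.sample_ids, "step": self.steps, "tfaa_percent": self.y}
        df = pd.DataFrame(cols)
        spec = pd.DataFrame(self.X, columns=[f"{w:.4f}" for w in self.wavelengths_nm])
        return pd.concat([df, spec], axis=1)
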