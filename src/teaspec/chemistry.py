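"""Ninhydrin-assay reference chemistry: standard-curve fitting and TFAA
computation.

Absorbance at 570 nm is converted to analyte mass ``C0`` (mg) through a
linear standard curve, and total free amino acid content is expressed as a
percentage of dry mass:

    TFAA% = 1e-3 * C0 * V1 / (M * m * V2) * 100

with ``V1`` the total test-solution volume (mL), ``V2`` the volume used for
the determination (mL), ``M`` the specimen mass (g), and ``m`` the
dry-matter content entered as a percentage and applied as a fraction
(``m / 100``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["StandardCurve", "AssayRecord", "fit_standard_curve", "compute_tfaa", "tfaa_table"]


@dataclass(frozen=True)
class StandardCurve:
    """Linear map from absorbance A(570 nm) to analyte mass C0 (mg)."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __call__(self, absorbance: float) -> float:
        return self.slope * float(absorbance) + self.intercept


@dataclass(frozen=True)
class AssayRecord:
    sample_id: str
    absorbance: float
    v1_ml: float
    v2_ml: float
    mass_g: float
    dry_matter_pct: float

    def __post_init__(self):
        if self.v1_ml <= 0 or self.v2_ml <= 0 or self.mass_g <= 0:
            raise ValueError("volumes and mass must be positive")
        if not 0 < self.dry_matter_pct <= 100:
            raise ValueError("dry matter percentage must be in (0, 100]")


def fit_standard_curve(absorbances, masses_mg) -> StandardCurve:
    """OLS line of analyte mass on absorbance over the standard series."""
    a = np.asarray(absorbances, dtype=np.float64)
    m = np.asarray(masses_mg, dtype=np.float64)
    if a.size < 2 or a.size != m.size:
        raise ValueError("need >= 2 matched (absorbance, mass) points")
    if np.ptp(a) == 0:
        raise ValueError("all absorbances identical: curve undefined")
    res = stats.linregress(a, m)
    return StandardCurve(float(res.slope), float(res.intercept),
                         float(res.rvalue) ** 2, int(a.size))


def compute_tfaa(record: AssayRecord, curve: StandardCurve) -> float:
    """TFAA as % dry mass for one assay record."""
    c0 = curve(record.absorbance)
    if c0 < 0:
        raise ValueError(
            f"standard curve gives negative analyte mass ({c0:.4g} mg) for "
            f"A = {record.absorbance}: outside assay range"
        )
    m_frac = record.dry_matter_pct / 100.0
    return 1e-3 * c0 * record.v1_ml / (record.mass_g * m_frac * record.v2_ml) * 100.0


def tfaa_table(records, curve: StandardCurve) -> pd.DataFrame:
    """Vectorized convenience: records -> (sample_id, tfaa_percent) table."""
    rows = [{"sample_id": r.sample_id, "tfaa_percent": compute_tfaa(r, curve)} for r in records]
    return pd.DataFrame(rows)
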