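"""Model evaluation: R², RMSE, RPD with credibility classes, and
report-table assembly.

RPD (ratio of performance to deviation) is the standard chemometrics form
SD(y_test; n−1 denominator) / RMSEP. A model with RPD in [1.4, 2.0] is
rated *credible*, above 2.0 *highly credible*, below 1.4 *unreliable*
(boundaries assigned to the credible class). Report tables carry one row
per (process type x pretreatment x selector x regressor) with calibration
and prediction statistics, flagging the best row per process type by
prediction R² (ties by RPD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EvaluationReport",
    "r_squared",
    "rmse",
    "rpd",
    "rpd_printed",
    "rpd_class",
    "evaluate_model",
    "build_report",
]

#: alias map normalizing inconsistent process-step labels
STEP_ALIASES = {"ST": "SF"}

RPD_CREDIBLE_LOW = 1.4
RPD_CREDIBLE_HIGH = 2.0


def _pair(y, yhat):
    y = np.asarray(y, dtype=np.float64).ravel()
    yhat = np.asarray(yhat, dtype=np.float64).ravel()
    if y.shape != yhat.shape:
        raise ValueError("y and predictions differ in length")
    return y, yhat


def r_squared(y, yhat) -> float:
    """Coefficient of determination 1 - SSE/SST."""
    y, yhat = _pair(y, yhat)
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("constant reference values: R^2 undefined")
    sse = float(((y - yhat) ** 2).sum())
    return 1.0 - sse / sst


def rmse(y, yhat) -> float:
    y, yhat = _pair(y, yhat)
    if y.size < 1:
        raise ValueError("need at least 1 observation")
    return float(np.sqrt(((y - yhat) ** 2).mean()))


def rpd(y_test, yhat_test) -> float:
    """SD(y_test, n-1 denominator) / RMSEP; perfect predictions give inf."""
    y, yhat = _pair(y_test, yhat_test)
    if y.size < 2:
        raise ValueError("need at least 2 test observations")
    e = rmse(y, yhat)
    sd = float(np.std(y, ddof=1))
    if e == 0:
        return float("inf")
    return sd / e


def rpd_printed(y_test, yhat_test) -> float:
    """Literal reading of the deviation-ratio form
    sqrt(sum (yhat - ybar)^2 / sum (yhat - ybar*)^2) with ybar the
    reference mean and ybar* the prediction mean. Kept for comparison
    only; the standard SD/RMSEP form is what reports use."""
    y, yhat = _pair(y_test, yhat_test)
    num = float(((yhat - y.mean()) ** 2).sum())
    den = float(((yhat - yhat.mean()) ** 2).sum())
    if den == 0:
        return float("inf")
    return float(np.sqrt(num / den))


def rpd_class(value: float) -> str:
    if value < 0:
        raise ValueError("RPD cannot be negative")
    if value < RPD_CREDIBLE_LOW:
        return "unreliable"
    if value <= RPD_CREDIBLE_HIGH:
        return "credible"
    return "highly credible"


@dataclass
class EvaluationReport:
    """One report row: calibration and prediction statistics for a model."""

    model_label: str
    process_type: str
    rc2: float
    rmsec: float
    rp2: float
    rmsep: float
    rpd: float
    rpd_class: str = field(default="")
    n_calibration: int = 0
    n_prediction: int = 0
    n_bands: int = 0

    def __post_init__(self):
        self.process_type = STEP_ALIASES.get(self.process_type, self.process_type)
        if not self.rpd_class:
            self.rpd_class = rpd_class(self.rpd)
        for r2 in (self.rc2, self.rp2):
            if r2 > 1.0 + 1e-12:
                raise ValueError("R^2 cannot exceed 1")
        if self.rmsec < 0 or self.rmsep < 0:
            raise ValueError("RMSE cannot be negative")


def evaluate_model(
    model_label: str,
    process_type: str,
    y_cal, yhat_cal, y_pred, yhat_pred,
    n_bands: int = 0,
) -> EvaluationReport:
    """Compute all report statistics from calibration/prediction pairs."""
    return EvaluationReport(
        model_label=model_label,
        process_type=process_type,
        rc2=r_squared(y_cal, yhat_cal),
        rmsec=rmse(y_cal, yhat_cal),
        rp2=r_squared(y_pred, yhat_pred),
        rmsep=rmse(y_pred, yhat_pred),
        rpd=rpd(y_pred, yhat_pred),
        n_calibration=len(np.asarray(y_cal).ravel()),
        n_prediction=len(np.asarray(y_pred).ravel()),
        n_bands=n_bands,
    )


def build_report(rows) -> pd.DataFrame:
    """Assemble report rows into a deterministic table.

    One row per (process type, model label); the best row per process type
    (max prediction R², ties by RPD) is flagged. Raises on duplicate keys.
    """
    records = []
    for r in rows:
        records.append({
            "process_type": r.process_type,
            "model": r.model_label,
            "Rc2": r.rc2,
            "RMSEC": r.rmsec,
            "Rp2": r.rp2,
            "RMSEP": r.rmsep,
            "RPD": r.rpd,
            "credibility": r.rpd_class,
            "n_cal": r.n_calibration,
            "n_pred": r.n_prediction,
            "n_bands": r.n_bands,
        })
    df = pd.DataFrame.from_records(
        records,
        columns=["process_type", "model", "Rc2", "RMSEC", "Rp2", "RMSEP",
                 "RPD", "credibility", "n_cal", "n_pred", "n_bands"],
    )
    if df.empty:
        df["best"] = pd.Series(dtype=bool)
        return df
    if df.duplicated(["process_type", "model"]).any():
        dup = df[df.duplicated(["process_type", "model"])].iloc[0]
        raise ValueError(f"duplicate report row: {dup['process_type']}/{dup['model']}")
    df["best"] = False
    for _, group in df.groupby("process_type", sort=False):
        ranked = group.sort_values(["Rp2", "RPD"], ascending=False, kind="stable")
        df.loc[ranked.index[0], "best"] = True
    return df


def report_to_csv(df: pd.DataFrame, path) -> None:
    """Serialize with a fixed float format so identical inputs give
    byte-identical files."""
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")
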