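"""Model evaluation statistics and the descriptor correlation matrix."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalReport:
    """Fit statistics for one data split.

    ``r2`` is the coefficient of determination 1 − SS_res/SS_tot (the
    headline value); ``pearson_r2`` is the squared Pearson correlation,
    which differs on held-out data. ``sd`` is the sample standard
    deviation of the actual values.
    """

    split_name: str
    r2: float
    pearson_r2: float
    rmse: float
    mae: float
    sd: float
    n: int

    def to_dict(self) -> dict:
        return {
            "split": self.split_name,
            "r2": self.r2,
            "pearson_r2": self.pearson_r2,
            "rmse": self.rmse,
            "mae": self.mae,
            "sd": self.sd,
            "n": self.n,
        }


def evaluate(actual: np.ndarray, predicted: np.ndarray, name: str = "") -> EvalReport:
    """R², RMSE, MAE and SD of actuals for one (actual, predicted) pair."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape or actual.ndim != 1:
        raise ValueError("actual and predicted must be 1-D vectors of equal length")
    if len(actual) < 1:
        raise ValueError("cannot evaluate an empty split")
    err = actual - predicted
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    sd = float(np.std(actual, ddof=1)) if len(actual) > 1 else 0.0
    ss_tot = float(np.sum((actual - actual.mean()) ** 2))
    if ss_tot == 0:
        logger.warning("constant actual values in split %r: R² undefined", name)
        r2 = math.nan
        pr2 = math.nan
    else:
        r2 = 1.0 - float(np.sum(err**2)) / ss_tot
        if np.std(predicted) == 0:
            pr2 = math.nan
        else:
            pr2 = float(np.corrcoef(actual, predicted)[0, 1]) ** 2
    return EvalReport(split_name=name, r2=r2, pearson_r2=pr2, rmse=rmse, mae=mae, sd=sd,
                      n=len(actual))


@dataclass(frozen=True)
class CorrelationMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # (d, d) Pearson correlations

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("correlation matrix shape/label mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def correlation_matrix(table: pd.DataFrame, columns: list[str] | None = None) -> CorrelationMatrix:
    """Pairwise Pearson correlations of the descriptor columns.

    Constant columns get NaN rows/columns with a warning rather than
    failing the whole matrix.
    """
    if columns is None:
        columns = [c for c in table.columns if np.issubdtype(table[c].dtype, np.number)]
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    x = table[columns].to_numpy(dtype=float)
    constant = x.std(axis=0) == 0
    if constant.any():
        logger.warning("constant column(s) %s: correlations reported as NaN",
                       [c for c, k in zip(columns, constant) if k])
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.corrcoef(x.T)
    values = np.atleast_2d(values)
    np.fill_diagonal(values, 1.0)
    values[constant, :] = np.nan
    values[:, constant] = np.nan
    return CorrelationMatrix(labels=tuple(columns), values=values)
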