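"""General regression neural network (Specht's GRNN).

The GRNN is Nadaraya–Watson kernel regression dressed in network
vocabulary: the prediction at a query x is the Gaussian-kernel-weighted
mean of the training targets,

    ŷ(x) = Σ_i y_i exp(−‖x̃ − x̃_i‖² / 2σ²) / Σ_i exp(−‖x̃ − x̃_i‖² / 2σ²)

with descriptors autoscaled on the training set only. The single
bandwidth σ is the model's only free parameter; it is selected by
golden-section search on log₁₀σ to minimise test-set RMSE, which is the
overtraining monitor — small σ memorises the training set, large σ
collapses to the global mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .splitting import Scaling, fit_scaling


@dataclass
class GRNNModel:
    """Fitted kernel-regression model: scaled training data plus bandwidth."""

    train_X: np.ndarray  # (n, d) autoscaled
    train_y: np.ndarray  # (n,) %F
    sigma: float  # bandwidth in scaled-descriptor units
    scaling: Scaling
    clip: bool = True  # clamp predictions to [0, 100]

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if np.isnan(self.train_X).any() or np.isnan(self.train_y).any():
            raise ValueError("training data contains NaN")


@dataclass
class SelectionTrace:
    """Bandwidths evaluated during selection, with both RMSE curves."""

    sigma: list[float] = field(default_factory=list)
    train_rmse: list[float] = field(default_factory=list)
    test_rmse: list[float] = field(default_factory=list)


def _kernel_weights(scaled_query: np.ndarray, train_X: np.ndarray, sigma: float) -> np.ndarray:
    """Row-normalised Gaussian weights, stabilised by the max-exponent shift."""
    d2 = (
        np.sum(scaled_query**2, axis=1)[:, None]
        - 2.0 * scaled_query @ train_X.T
        + np.sum(train_X**2, axis=1)[None, :]
    )
    expo = -np.maximum(d2, 0.0) / (2.0 * sigma**2)
    expo -= expo.max(axis=1, keepdims=True)  # max exponent becomes 0 → no underflow of all terms
    w = np.exp(expo)
    return w / w.sum(axis=1, keepdims=True)


def _predict_scaled(scaled_query: np.ndarray, train_X: np.ndarray, train_y: np.ndarray,
                    sigma: float) -> np.ndarray:
    return _kernel_weights(scaled_query, train_X, sigma) @ train_y


def grnn_predict(model: GRNNModel, x: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Predict %F for one or many descriptor vectors."""
    if isinstance(x, pd.DataFrame):
        scaled = model.scaling.transform(x)
    else:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != len(model.scaling.columns):
            raise ValueError(
                f"expected {len(model.scaling.columns)} features, got {x.shape[1]}"
            )
        scaled = (x - model.scaling.mean) / model.scaling.sd
    if not np.all(np.isfinite(scaled)):
        raise ValueError("query contains non-finite values")
    pred = _predict_scaled(scaled, model.train_X, model.train_y, model.sigma)
    if model.clip:
        pred = np.clip(pred, 0.0, 100.0)
    return pred


def grnn_predict_batch(model: GRNNModel, table: pd.DataFrame, target_col: str | None = None
                       ) -> pd.DataFrame:
    """Vectorised prediction over a descriptor table.

    Returns a frame of (id, actual, predicted) rows ready for parity
    plotting; ``actual`` is NaN when no target column is given.
    """
    missing = [c for c in model.scaling.columns if c not in table.columns]
    if missing:
        raise ValueError(f"prediction table lacks descriptor columns {missing}")
    pred = grnn_predict(model, table)
    actual = table[target_col].to_numpy(dtype=float) if target_col else np.full(len(table), np.nan)
    return pd.DataFrame({"actual": actual, "predicted": pred}, index=table.index)


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _loo_rmse(train_X: np.ndarray, train_y: np.ndarray, sigma: float) -> float:
    """Leave-one-out RMSE on the training set (self-weight removed)."""
    w = _kernel_weights(train_X, train_X, sigma)
    np.fill_diagonal(w, 0.0)
    row_sum = w.sum(axis=1, keepdims=True)
    row_sum[row_sum == 0] = 1.0
    pred = (w / row_sum) @ train_y
    return _rmse(pred, train_y)


_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def fit_grnn(
    train: pd.DataFrame,
    test: pd.DataFrame | None,
    target_col: str,
    feature_cols: list[str] | None = None,
    log_sigma_bounds: tuple[float, float] = (-3.0, 2.0),
    rel_tol: float = 1e-3,
    clip: bool = True,
) -> tuple[GRNNModel, SelectionTrace]:
    """Fit scaling on the training set and select σ on the test set.

    σ minimises test-set RMSE by golden-section search over log₁₀σ in
    ``log_sigma_bounds``; with no test set the criterion falls back to
    leave-one-out RMSE on the training data. Deterministic throughout.
    """
    if target_col not in train.columns:
        raise ValueError(f"target column {target_col!r} missing from training table")
    if feature_cols is None:
        feature_cols = [c for c in train.columns if c != target_col]
    if len(train) == 0:
        raise ValueError("training table is empty")
    scaling = fit_scaling(train, feature_cols)
    train_X = scaling.transform(train)
    train_y = train[target_col].to_numpy(dtype=float)

    use_loo = test is None or len(test) == 0
    if not use_loo:
        test_X = scaling.transform(test)
        test_y = test[target_col].to_numpy(dtype=float)

    trace = SelectionTrace()

    def objective(log_sigma: float) -> float:
        sigma = 10.0**log_sigma
        tr = _rmse(_predict_scaled(train_X, train_X, train_y, sigma), train_y)
        if use_loo:
            te = _loo_rmse(train_X, train_y, sigma)
        else:
            te = _rmse(_predict_scaled(test_X, train_X, train_y, sigma), test_y)
        trace.sigma.append(sigma)
        trace.train_rmse.append(tr)
        trace.test_rmse.append(te)
        return te

    a, b = log_sigma_bounds
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = objective(c), objective(d)
    while abs(b - a) > rel_tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = objective(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = objective(d)
    log_sigma = 0.5 * (a + b)
    sigma = 10.0**log_sigma
    objective(log_sigma)  # record the final point in the trace

    model = GRNNModel(train_X=train_X, train_y=train_y, sigma=sigma, scaling=scaling, clip=clip)
    return model, trace
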