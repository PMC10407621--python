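"""Fit statistics and leverage-based applicability-domain analysis."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import sqrt

import numpy as np
import pandas as pd

from .dataset import QsarDataset
from .exceptions import MetricsError, SingularityError

logger = logging.getLogger(__name__)


@dataclass
class FitMetrics:
    r2: float
    mse: float
    rmse: float
    mpe: float
    n: int
    scope: str = "total"

    def as_dict(self) -> dict:
        return {"scope": self.scope, "n": self.n, "r2": self.r2,
                "mse": self.mse, "rmse": self.rmse, "mpe": self.mpe}


def fit_metrics(y_exp, y_pred, scope: str = "total",
                r2_mode: str = "ss_ratio") -> FitMetrics:
    """R², MSE, RMSE and mean (absolute) percentage error.

    ``r2_mode='ss_ratio'`` (default) uses 1 - SS_res/SS_tot;
    ``'pearson_sq'`` uses the squared Pearson correlation instead.
    Zero-valued targets are excluded from the percentage error (logged).
    """
    y_exp = np.asarray(y_exp, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_exp.shape != y_pred.shape or y_exp.ndim != 1:
        raise MetricsError("y_exp and y_pred must be equal-length vectors")
    n = len(y_exp)
    if n < 2:
        raise MetricsError("need at least two samples")
    if not (y_exp != 0).any():
        raise MetricsError("all targets are zero; MPE undefined")
    residuals = y_exp - y_pred
    mse = float(residuals @ residuals) / n
    ss_tot = float(((y_exp - y_exp.mean()) ** 2).sum())
    if ss_tot == 0:
        raise MetricsError("all experimental values identical; R2 undefined")
    if r2_mode == "ss_ratio":
        r2 = 1.0 - float(residuals @ residuals) / ss_tot
    elif r2_mode == "pearson_sq":
        r2 = float(np.corrcoef(y_exp, y_pred)[0, 1]) ** 2
    else:
        raise ValueError(f"unknown r2_mode {r2_mode!r}")
    nonzero = y_exp != 0
    n_excluded = int((~nonzero).sum())
    if n_excluded:
        logger.info("MPE: excluding %d zero-valued target(s)", n_excluded)
    mpe = float(100.0 / nonzero.sum()
                * (np.abs(residuals[nonzero]) / y_exp[nonzero]).sum())
    return FitMetrics(r2=r2, mse=mse, rmse=sqrt(mse), mpe=mpe, n=n, scope=scope)


def metrics_by_split(y_exp: pd.Series, y_pred: pd.Series,
                     splits: pd.Series) -> dict[str, FitMetrics]:
    out = {"total": fit_metrics(y_exp, y_pred, scope="total")}
    for name in sorted(splits.unique()):
        mask = splits == name
        out[name] = fit_metrics(y_exp[mask], y_pred[mask], scope=name)
    return out


# ---------------------------------------------------------------------------
# applicability domain

def leverage(X_train: np.ndarray, X_query: np.ndarray | None = None) -> np.ndarray:
    """Hat-matrix diagonal h_i = x_i (X'X)^-1 x_i' (no intercept column).

    ``X_query`` defaults to the training matrix itself, in which case the
    leverages sum to the number of descriptors.
    """
    Xt = np.atleast_2d(np.asarray(X_train, dtype=float))
    n, m = Xt.shape
    if n < m:
        raise SingularityError(f"need rows >= columns, got {n} x {m}")
    gram = Xt.T @ Xt
    if np.linalg.matrix_rank(gram) < m:
        raise SingularityError("X'X is singular; remove dependent descriptors")
    Xq = Xt if X_query is None else np.atleast_2d(np.asarray(X_query, dtype=float))
    solved = np.linalg.solve(gram, Xq.T)
    return np.einsum("ij,ji->i", Xq, solved)


def critical_leverage(n_train: int, m: int) -> float:
    """h* = 3(m+1)/n for n training compounds and m descriptors."""
    if n_train <= 0:
        raise ValueError("n_train must be positive")
    return 3.0 * (m + 1) / n_train


@dataclass
class AdReport:
    leverages: pd.Series
    h_star: float
    std_residuals: pd.Series
    outliers: list[str] = field(default_factory=list)

    def as_frame(self, splits: pd.Series) -> pd.DataFrame:
        flags = []
        for name in self.leverages.index:
            reasons = []
            if self.leverages[name] > self.h_star:
                reasons.append("leverage")
            if abs(self.std_residuals[name]) > 3:
                reasons.append("residual")
            flags.append("+".join(reasons) if reasons else "ok")
        return pd.DataFrame({
            "compound": self.leverages.index,
            "split": splits.loc[self.leverages.index].values,
            "leverage": self.leverages.values,
            "std_residual": self.std_residuals.values,
            "flag": flags,
        })


def williams_report(y_pred: pd.Series, dataset: QsarDataset,
                    h_star: float | None = None) -> tuple[AdReport, pd.DataFrame]:
    """Leverages, standardized residuals and outlier flags for every compound.

    Leverage uses the training descriptor matrix; residuals are
    standardized by the training-residual standard deviation.  A compound
    is flagged when its leverage exceeds h* or |standardized residual| > 3.
    Returns the report and a plot-data table (Williams plot input).
    """
    y_pred = y_pred.loc[dataset.X.index]
    train_mask = dataset.splits == "training"
    X_train = dataset.X[train_mask].to_numpy(dtype=float)
    if h_star is None:
        h_star = critical_leverage(int(train_mask.sum()), dataset.X.shape[1])
    h = leverage(X_train, dataset.X.to_numpy(dtype=float))
    residuals = dataset.y - y_pred
    train_sd = float(residuals[train_mask].std(ddof=1))
    if train_sd == 0:
        raise MetricsError("zero training-residual spread; cannot standardize")
    std_res = residuals / train_sd
    leverages = pd.Series(h, index=dataset.X.index, name="leverage")
    outliers = [str(c) for c, h_i, r_i in zip(dataset.X.index, h, std_res)
                if h_i > h_star or abs(r_i) > 3]
    report = AdReport(
        leverages=leverages, h_star=h_star,
        std_residuals=std_res.rename("std_residual"),
        outliers=outliers,
    )
    return report, report.as_frame(dataset.splits)
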