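"""Descriptor filtering cascade.

Zero-variance removal, pairwise correlation pruning against a |r| > 0.90
threshold, forward stepwise regression ranking by p-value, and top-k
selection.  The cascade is fully deterministic given its inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import SelectionError

logger = logging.getLogger(__name__)


@dataclass
class SelectionReport:
    n_input: int
    zero_variance_removed: list[str]
    correlation_removed: list[str]
    stepwise_ranking: list[tuple[str, float]]
    selected: list[str] = field(default_factory=list)

    @property
    def n_zero_variance_removed(self) -> int:
        return len(self.zero_variance_removed)

    @property
    def n_correlation_removed(self) -> int:
        return len(self.correlation_removed)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "zero_variance_removed": self.zero_variance_removed,
            "correlation_removed": self.correlation_removed,
            "stepwise_ranking": [[n, p] for n, p in self.stepwise_ranking],
            "selected": self.selected,
        }


def drop_zero_variance(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove columns whose values are all identical (variance zero).

    Covers both all-zero columns and constant nonzero columns.
    """
    if X.shape[1] == 0:
        raise SelectionError("empty descriptor matrix")
    constant = [c for c in X.columns if X[c].nunique(dropna=False) <= 1]
    reduced = X.drop(columns=constant)
    if reduced.shape[1] == 0:
        raise SelectionError("all columns removed as zero-variance")
    return reduced, constant


def prune_correlated(X: pd.DataFrame, y: pd.Series,
                     threshold: float = 0.90) -> tuple[pd.DataFrame, list[str]]:
    """Iteratively drop one member of every column pair with |r| > threshold.

    From each offending pair the column with the smaller absolute
    correlation to the response is removed (ties broken by column name so
    the result is deterministic); iterated until no pair exceeds the
    threshold.  The comparison is strict: a pair at exactly the threshold
    is kept.
    """
    if X.shape[1] < 2:
        return X.copy(), []
    variances = X.var(axis=0, ddof=0)
    if (variances == 0).any():
        bad = list(variances.index[variances == 0])
        raise SelectionError(
            f"zero-variance columns {bad}; run drop_zero_variance first"
        )
    kept = X.copy()
    removed: list[str] = []
    response_corr = {c: abs(float(np.corrcoef(X[c], y)[0, 1])) for c in X.columns}
    while True:
        corr = kept.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pairs = [
            (corr.iloc[i, j], corr.index[i], corr.columns[j])
            for i in range(len(corr)) for j in range(i + 1, len(corr))
            if corr.iloc[i, j] > threshold
        ]
        if not pairs:
            break
        # resolve the worst pair first; recompute after each removal
        _, a, b = max(pairs, key=lambda t: (t[0], t[1], t[2]))
        drop = min((a, b), key=lambda c: (response_corr[c], c))
        kept = kept.drop(columns=drop)
        removed.append(drop)
    return kept, removed


def _forward_stepwise(X: pd.DataFrame, y: pd.Series, entry_alpha: float) -> list[str]:
    """Forward selection by partial-F p-value with entry threshold."""
    included: list[str] = []
    candidates = sorted(X.columns)
    yv = np.asarray(y, dtype=float)
    while candidates:
        if len(included) + 2 > len(X):
            logger.warning("stepwise stopped: no residual degrees of freedom")
            break
        best_name, best_p = None, np.inf
        for name in candidates:
            cols = included + [name]
            design = sm.add_constant(X[cols].to_numpy(dtype=float))
            fit = sm.OLS(yv, design).fit()
            p_val = float(fit.pvalues[-1])  # partial F == t-test for 1 df
            if p_val < best_p or (p_val == best_p and (best_name is None or name < best_name)):
                best_name, best_p = name, p_val
        if best_name is None or not best_p < entry_alpha:
            break
        included.append(best_name)
        candidates.remove(best_name)
    return included


def stepwise_rank(X: pd.DataFrame, y: pd.Series, entry_alpha: float = 0.05,
                  ranking: str = "final_model") -> SelectionReport:
    """Forward stepwise regression producing a p-value ranking.

    ``ranking='final_model'`` (default) ranks the entered descriptors by
    their coefficient p-values in the final stepwise model;
    ``ranking='marginal'`` ranks them by single-descriptor regression
    p-values instead.  Ties are broken by descriptor name.
    """
    if X.shape[1] == 0:
        raise SelectionError("empty descriptor matrix")
    included = _forward_stepwise(X, y, entry_alpha)
    if not included:
        logger.warning("no descriptor passed the entry threshold alpha=%g", entry_alpha)
        pairs: list[tuple[str, float]] = []
    elif ranking == "final_model":
        design = sm.add_constant(X[included].to_numpy(dtype=float))
        fit = sm.OLS(np.asarray(y, dtype=float), design).fit()
        pvals = {name: float(p) for name, p in zip(included, fit.pvalues[1:])}
        pairs = sorted(pvals.items(), key=lambda kv: (kv[1], kv[0]))
    elif ranking == "marginal":
        pvals = {}
        for name in included:
            design = sm.add_constant(X[[name]].to_numpy(dtype=float))
            fit = sm.OLS(np.asarray(y, dtype=float), design).fit()
            pvals[name] = float(fit.pvalues[1])
        pairs = sorted(pvals.items(), key=lambda kv: (kv[1], kv[0]))
    else:
        raise ValueError(f"unknown ranking mode {ranking!r}")
    return SelectionReport(
        n_input=X.shape[1],
        zero_variance_removed=[],
        correlation_removed=[],
        stepwise_ranking=pairs,
    )


def select_top_k(report: SelectionReport, k: int = 4) -> list[str]:
    """First k descriptor names of the ascending-p-value ranking."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k > len(report.stepwise_ranking):
        raise SelectionError(
            f"ranking has only {len(report.stepwise_ranking)} descriptors; "
            f"choose k <= that (got k={k})"
        )
    selected = [name for name, _ in report.stepwise_ranking[:k]]
    report.selected = selected
    return selected


def run_cascade(X: pd.DataFrame, y: pd.Series, k: int = 4,
                corr_threshold: float = 0.90, entry_alpha: float = 0.05,
                ranking: str = "final_model") -> tuple[SelectionReport, pd.DataFrame]:
    """Full filtering cascade; returns the report and the selected columns."""
    X1, zero_removed = drop_zero_variance(X)
    X2, corr_removed = prune_correlated(X1, y, threshold=corr_threshold)
    report = stepwise_rank(X2, y, entry_alpha=entry_alpha, ranking=ranking)
    report.n_input = X.shape[1]
    report.zero_variance_removed = zero_removed
    report.correlation_removed = corr_removed
    k_eff = min(k, len(report.stepwise_ranking))
    if k_eff < k:
        logger.warning("only %d descriptors ranked; selecting all of them", k_eff)
    selected = select_top_k(report, k_eff)
    return report, X2[selected]
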