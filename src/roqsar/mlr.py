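"""Multiple linear regression baseline and the published reference model."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .exceptions import SingularityError

#: published reference coefficients (normalised-variable scale)
_REFERENCE_INTERCEPT = 0.1632
_REFERENCE_COEFFS = {
    "SIC1": -0.1963528,
    "R2e": 0.4113547,
    "EEig03d": 0.1675084,
    "ESpm14u": 0.867939,
}


@dataclass
class MlrModel:
    intercept: float
    coefficients: dict[str, float]
    scale_note: str = "raw"  # descriptor scale the model applies to

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.coefficients)

    def as_dict(self) -> dict:
        return {"intercept": self.intercept, "coefficients": dict(self.coefficients),
                "scale_note": self.scale_note}

    @classmethod
    def from_dict(cls, d: dict) -> "MlrModel":
        return cls(intercept=float(d["intercept"]),
                   coefficients={k: float(v) for k, v in d["coefficients"].items()},
                   scale_note=d.get("scale_note", "raw"))


def _dependent_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    return sorted(names[i] for i in piv[rank:])


def fit_mlr(X: pd.DataFrame, y: pd.Series, scale_note: str = "raw") -> MlrModel:
    """Ordinary least squares with an intercept.

    Raises :class:`SingularityError` naming the dependent columns when the
    design matrix is rank deficient.
    """
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    if n <= p:
        raise SingularityError(f"need more rows ({n}) than columns ({p})")
    design = np.column_stack([np.ones(n), Xv])
    if np.linalg.matrix_rank(design) < p + 1:
        bad = _dependent_columns(Xv - Xv.mean(axis=0), names)
        raise SingularityError(f"rank-deficient design; dependent columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, np.asarray(y, dtype=float), rcond=None)
    return MlrModel(intercept=float(beta[0]),
                    coefficients={nm: float(b) for nm, b in zip(names, beta[1:])},
                    scale_note=scale_note)


def predict(model: MlrModel, X: pd.DataFrame) -> np.ndarray:
    """Affine evaluation of the model on matching descriptor columns."""
    missing = [c for c in model.descriptor_names if c not in X.columns]
    if missing:
        raise SingularityError(f"descriptor columns missing from input: {missing}")
    Xv = X[model.descriptor_names].to_numpy(dtype=float)
    beta = np.array([model.coefficients[c] for c in model.descriptor_names])
    return model.intercept + Xv @ beta


def eq8_reference() -> MlrModel:
    """The published linear rejection model.

    Its coefficient magnitudes imply normalised descriptor variables, so it
    is tagged ``scale_note='scaled'`` (interpretive; the source does not
    state the variable scale).
    """
    return MlrModel(intercept=_REFERENCE_INTERCEPT,
                    coefficients=dict(_REFERENCE_COEFFS),
                    scale_note="scaled")
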