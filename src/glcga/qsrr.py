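"""Retention-index calibration, QSRR regression, and the retention filter.

Retention indices (RI) put retention on a dimensionless, gradient-
independent scale via piecewise-linear interpolation between (RT, RI)
anchor points.  A QSRR (quantitative structure-retention relationship)
model is an ordinary least-squares regression from molecular descriptors
to RI; its cross-validated error sets the matching threshold.  Because a
glucosyl group always weakens reversed-phase retention, a Glc-GA elutes
earlier than its parent GA, so the one-sided filter

    RI(experimental, Glc-GAn) < RI(predicted, GAn-DMED) + threshold

retains a candidate (threshold default 69.5832, the model's cross-
validated RMS error).  Positive deviations of any size are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EQ1_THRESHOLD",
    "CalibrationSeries",
    "QSRRModel",
    "load_calibration",
    "rt_to_ri",
    "fit_qsrr",
    "loocv_rmse",
    "eq1_filter",
    "ri_differences",
]

#: Default retention-index matching threshold (cross-validated RMS error
#: of the 13-standard QSRR model).
EQ1_THRESHOLD = 69.5832


@dataclass(frozen=True)
class CalibrationSeries:
    """Ordered (RT, RI) anchors; both strictly increasing."""

    rt: np.ndarray
    ri: np.ndarray

    def __post_init__(self) -> None:
        rt = np.asarray(self.rt, dtype=float)
        ri = np.asarray(self.ri, dtype=float)
        if rt.size < 2:
            raise ValueError("calibration needs at least 2 anchor points")
        if not np.all(np.diff(rt) > 0):
            raise ValueError("anchor RTs must be strictly increasing")
        if not np.all(np.diff(ri) > 0):
            raise ValueError("anchor RIs must be strictly increasing")
        object.__setattr__(self, "rt", rt)
        object.__setattr__(self, "ri", ri)


def load_calibration(path) -> CalibrationSeries:
    """Read a calibration CSV with columns rt, ri."""
    frame = pd.read_csv(path)
    for col in ("rt", "ri"):
        if col not in frame.columns:
            raise ValueError(f"calibration {path}: missing column {col!r}")
    frame = frame.sort_values("rt")
    return CalibrationSeries(frame["rt"].to_numpy(), frame["ri"].to_numpy())


def rt_to_ri(rt: float, cal: CalibrationSeries) -> float:
    """Piecewise-linear RT -> RI; linear extrapolation (with warning) outside."""
    if rt < cal.rt[0]:
        warnings.warn(f"RT {rt:.3f} min below first anchor; extrapolating")
        slope = (cal.ri[1] - cal.ri[0]) / (cal.rt[1] - cal.rt[0])
        return float(cal.ri[0] + slope * (rt - cal.rt[0]))
    if rt > cal.rt[-1]:
        warnings.warn(f"RT {rt:.3f} min above last anchor; extrapolating")
        slope = (cal.ri[-1] - cal.ri[-2]) / (cal.rt[-1] - cal.rt[-2])
        return float(cal.ri[-1] + slope * (rt - cal.rt[-1]))
    return float(np.interp(rt, cal.rt, cal.ri))


@dataclass
class QSRRModel:
    """Linear QSRR: RI ~ intercept + descriptors . coefficients."""

    descriptor_names: List[str]
    coefficients: np.ndarray
    intercept: float
    training_rmse: float

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coefficients


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0]), X])


def fit_qsrr(X, y, descriptor_names: Sequence[str] | None = None) -> QSRRModel:
    """Ordinary least-squares fit of RI on a descriptor matrix.

    Requires n >= p + 2 rows and a full-rank design (else error).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} samples for {p} descriptors, got {n}")
    A = _design(X)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("rank-deficient descriptor matrix")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    rmse = float(np.sqrt(np.mean(resid**2)))
    names = list(descriptor_names) if descriptor_names else [f"x{i}" for i in range(p)]
    return QSRRModel(
        descriptor_names=names,
        coefficients=beta[1:],
        intercept=float(beta[0]),
        training_rmse=rmse,
    )


def loocv_rmse(X, y) -> float:
    """Leave-one-out cross-validated RMSE of the linear model.

    Computed through the PRESS identity e_i / (1 - h_ii), which is exact
    for ordinary least squares.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} samples for {p} descriptors, got {n}")
    A = _design(X)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("rank-deficient descriptor matrix")
    hat = A @ np.linalg.solve(A.T @ A, A.T)
    resid = y - hat @ y
    h = np.diag(hat)
    if np.any(h >= 1.0 - 1e-12):
        raise ValueError("leverage 1 point: leave-one-out undefined")
    loo = resid / (1.0 - h)
    return float(np.sqrt(np.mean(loo**2)))


def eq1_filter(ri_exp: float, ri_pred: float, threshold: float = EQ1_THRESHOLD) -> bool:
    """Retain a candidate iff experimental RI < predicted RI + threshold."""
    if not (np.isfinite(ri_exp) and np.isfinite(ri_pred)):
        raise ValueError("non-finite retention index")
    return bool(ri_exp < ri_pred + threshold)


def ri_differences(ri_pred: Sequence[float], ri_exp: float) -> List[float]:
    """Elementwise predicted - experimental RI, rounded to 2 decimals."""
    return [round(float(p) - float(ri_exp), 2) for p in ri_pred]
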