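"""Isocratic retention processing and chromatographic lipophilicity.

Reversed-phase retention of a neutral solute, measured as the retention
factor k = (t_R - t_0)/t_0, falls log-linearly with the volume fraction of
organic modifier in the mobile phase (Soczewinski-Wachtmeister relation):

    log k = log k_w - s * phi

Extrapolating to phi = 0 gives log k_w, the retention the solute would show
in pure aqueous buffer, which serves as a chromatographic lipophilicity
index; the slope s tracks lipophilicity closely for congeneric series.
This module fits that line per compound/column, and provides the two
calibration regressions used to compare stationary phases: log k_w of one
column against another, and log k_w against s within a column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .exceptions import (
    DegenerateDesignError,
    InconsistentInputError,
    InsufficientDataError,
    InvalidMeasurementError,
    PairingError,
)
from .regression import LinearModelFit, OLSModel

__all__ = [
    "IsocraticMeasurement",
    "RetentionPoint",
    "RetentionFit",
    "compute_log_k",
    "RetentionExtrapolator",
    "fit_soczewinski_wachtmeister",
    "cross_column_regression",
    "kw_vs_slope_regression",
]


@dataclass(frozen=True)
class IsocraticMeasurement:
    """One isocratic run: solute retention time t_r and dead time t_0
    (minutes) at organic-modifier volume fraction phi."""

    compound_id: str
    column_id: str
    phi: float
    t_r: float
    t_0: float

    def __post_init__(self):
        if not (0.0 < self.phi < 1.0):
            raise InvalidMeasurementError(
                f"phi must lie in (0, 1), got {self.phi}"
            )
        if self.t_0 <= 0:
            raise InvalidMeasurementError(
                f"dead time must be positive, got t_0={self.t_0}"
            )
        if self.t_r <= self.t_0:
            raise InvalidMeasurementError(
                f"retention time t_r={self.t_r} not later than dead time "
                f"t_0={self.t_0} (compound {self.compound_id})"
            )


@dataclass(frozen=True)
class RetentionPoint:
    """A (phi, log k) observation."""

    phi: float
    log_k: float

    def __post_init__(self):
        if not (math.isfinite(self.phi) and math.isfinite(self.log_k)):
            raise InvalidMeasurementError("phi and log_k must be finite")


@dataclass(frozen=True)
class RetentionFit:
    """Fitted Soczewinski-Wachtmeister line for one compound on one column.

    ``s`` is stored as the positive slope magnitude of log k = log_kw - s*phi
    (reversed-phase convention).  ``r2`` is 0 by convention when the
    response has zero variance (flagged via ``zero_variance_response``).
    """

    compound_id: str
    column_id: str
    log_kw: float
    s: float
    r2: float
    n_points: int
    residual_sd: float
    zero_variance_response: bool = False


def compute_log_k(m: IsocraticMeasurement) -> float:
    """Decadic log retention factor log10((t_r - t_0)/t_0)."""
    # invariants enforced at construction; guard for duck-typed inputs
    if m.t_0 <= 0 or m.t_r <= m.t_0:
        raise InvalidMeasurementError(
            f"invalid measurement: t_r={m.t_r}, t_0={m.t_0}"
        )
    return math.log10((m.t_r - m.t_0) / m.t_0)


class RetentionExtrapolator(BaseEstimator):
    """Least-squares extrapolation of isocratic retention to phi = 0.

    scikit-learn style: ``fit(phi, log_k)`` stores ``log_kw_``, ``s_``,
    ``r2_``, ``residual_sd_`` and ``n_points_``; ``predict(phi)`` evaluates
    the fitted line.
    """

    def __init__(self, min_points: int = 3):
        self.min_points = min_points

    def fit(self, phi, log_k):
        phi = np.asarray(phi, dtype=float).ravel()
        log_k = np.asarray(log_k, dtype=float).ravel()
        if phi.shape != log_k.shape:
            raise PairingError(
                f"phi and log_k differ in length: {phi.size} vs {log_k.size}"
            )
        if phi.size < self.min_points:
            raise InsufficientDataError(
                f"need at least {self.min_points} (phi, log k) points, "
                f"got {phi.size}"
            )
        if np.unique(phi).size < 2:
            raise DegenerateDesignError(
                "all phi values identical; slope is not estimable"
            )
        self.zero_variance_response_ = bool(np.ptp(log_k) == 0.0)
        if self.zero_variance_response_:
            # Horizontal data: slope 0, intercept the constant; r2 is 0/0,
            # reported as 0 by convention.
            self.log_kw_ = float(log_k[0])
            self.s_ = 0.0
            self.r2_ = 0.0
            self.residual_sd_ = 0.0
        else:
            model = OLSModel().fit(phi.reshape(-1, 1), log_k)
            self.log_kw_ = float(model.intercept_)
            self.s_ = float(-model.coef_[0])
            self.r2_ = float(model.r2_)
            self.residual_sd_ = float(model.residual_sd_)
        self.n_points_ = int(phi.size)
        return self

    def predict(self, phi) -> np.ndarray:
        if not hasattr(self, "log_kw_"):
            raise AttributeError("not fitted")
        phi = np.asarray(phi, dtype=float)
        return self.log_kw_ - self.s_ * phi

    def to_fit(self, compound_id: str, column_id: str) -> RetentionFit:
        return RetentionFit(
            compound_id=compound_id,
            column_id=column_id,
            log_kw=self.log_kw_,
            s=self.s_,
            r2=self.r2_,
            n_points=self.n_points_,
            residual_sd=self.residual_sd_,
            zero_variance_response=self.zero_variance_response_,
        )


def fit_soczewinski_wachtmeister(
    points: Iterable[RetentionPoint],
    compound_id: str = "",
    column_id: str = "",
) -> RetentionFit:
    """OLS of log k on phi; returns log_kw (intercept), the positive slope
    s, r2 and the residual standard deviation."""
    pts = list(points)
    phi = [p.phi for p in pts]
    log_k = [p.log_k for p in pts]
    return (
        RetentionExtrapolator()
        .fit(phi, log_k)
        .to_fit(compound_id=compound_id, column_id=column_id)
    )


def _simple_regression(
    x, y, x_name: str, y_name: str
) -> LinearModelFit:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise PairingError(
            f"paired vectors differ in length: {x.size} vs {y.size}"
        )
    if x.size < 3:
        raise InsufficientDataError(
            f"need at least 3 paired observations, got {x.size}"
        )
    return (
        OLSModel()
        .fit(x.reshape(-1, 1), y, predictor_names=[x_name])
        .summary(response_name=y_name)
    )


def cross_column_regression(
    x_values,
    y_values,
    x_name: str = "log_kw_x",
    y_name: str = "log_kw_y",
) -> LinearModelFit:
    """Inter-column calibration: OLS line relating log k_w measured on two
    stationary phases over the same compounds."""
    return _simple_regression(x_values, y_values, x_name, y_name)


def kw_vs_slope_regression(fits: Sequence[RetentionFit]) -> LinearModelFit:
    """Within-column OLS of log k_w on the slope s — the congenericity
    check; all fits must come from the same column."""
    fits = list(fits)
    if len(fits) < 3:
        raise InsufficientDataError(
            f"need at least 3 retention fits, got {len(fits)}"
        )
    columns = {f.column_id for f in fits}
    if len(columns) != 1:
        raise InconsistentInputError(
            "retention fits span multiple columns: "
            + ", ".join(sorted(columns))
        )
    col = fits[0].column_id
    return _simple_regression(
        [f.s for f in fits],
        [f.log_kw for f in fits],
        x_name=f"s_{col}",
        y_name=f"log_kw_{col}",
    )
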