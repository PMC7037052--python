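"""Ordinary-least-squares engine with the diagnostics QSAR practice relies on.

:class:`OLSModel` is a scikit-learn style estimator wrapping a statsmodels
OLS fit and exposing, as fitted attributes, the statistics a modelling
report quotes: coefficient standard errors, R² and adjusted R², the residual
standard error ("SD" in chromatographic QSAR papers), the global F test,
hat values and the leverage-based applicability-domain limit h* = 3m/n.

Module-level helpers (:func:`ols_fit`, :func:`vif`,
:func:`standardized_coefficients`, :func:`leverage`, :func:`pairwise_r2`)
are thin functional wrappers kept for script use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (
    CollinearityError,
    DegenerateDesignError,
    InsufficientDataError,
)

__all__ = [
    "LinearModelFit",
    "LeverageDiagnostics",
    "OLSModel",
    "ols_fit",
    "vif",
    "standardized_coefficients",
    "leverage",
    "pairwise_r2",
]


@dataclass(frozen=True)
class LinearModelFit:
    """Immutable summary of one fitted linear model.

    ``residual_sd`` is the residual standard error sqrt(SSE/(n-p-1)), the
    quantity QSAR reports print as "SD".  ``p_value`` belongs to the global
    F test with (p, n-p-1) degrees of freedom.
    """

    predictor_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    standard_errors: tuple[float, ...]
    intercept: float
    intercept_se: float
    n_obs: int
    n_predictors: int
    r2: float
    r2_adj: float
    residual_sd: float
    f_stat: float
    p_value: float
    response_name: str = "y"

    def equation_string(self, precision: int = 3) -> str:
        """Render the model the way journals print it:
        ``y = c(+/- se) + b1(+/- se) x1 + ...`` followed by the global
        statistics line ``N = ...; SD = ...; R2 = ...; F = ...``."""
        p = precision
        terms = [f"{self.intercept:.{p}f}(± {self.intercept_se:.{p}f})"]
        for name, b, se in zip(
            self.predictor_names, self.coefficients, self.standard_errors
        ):
            sign = "-" if b < 0 else "+"
            terms.append(f"{sign} {abs(b):.{p}f}(± {se:.{p}f}) {name}")
        eq = f"{self.response_name} = " + " ".join(terms)
        stats = (
            f"N = {self.n_obs}; SD = {self.residual_sd:.3f}; "
            f"R2 = {self.r2:.4f}; F = {self.f_stat:.0f}"
        )
        return eq + "\n" + stats

    def to_dict(self) -> dict:
        return {
            "response": self.response_name,
            "predictors": list(self.predictor_names),
            "coefficients": list(self.coefficients),
            "standard_errors": list(self.standard_errors),
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "n_obs": self.n_obs,
            "n_predictors": self.n_predictors,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "residual_sd": self.residual_sd,
            "f_stat": self.f_stat,
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class LeverageDiagnostics:
    """Hat-matrix diagonal and the warning-leverage limit h* = 3m/n.

    ``m`` counts descriptors (the intercept is excluded), the convention
    used with Williams-type residual/leverage plots in this workflow; note
    other software uses 3(p+1)/n.  ``standardized_residuals`` are
    internally studentized: e_i / (sd * sqrt(1 - h_ii)).
    """

    hat_values: tuple[float, ...]
    h_star: float
    standardized_residuals: tuple[float, ...] = field(default=())

    def outside_domain(self) -> tuple[int, ...]:
        """Indices of training observations with leverage above h*."""
        return tuple(
            i for i, h in enumerate(self.hat_values) if h > self.h_star
        )


def _as_design(X, names=None) -> tuple[np.ndarray, list[str]]:
    """Coerce a predictor table to a float ndarray plus column names."""
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr.reshape(-1, 1)
        if names is None:
            names = [f"x{j + 1}" for j in range(arr.shape[1])]
        names = list(names)
    if arr.ndim != 2:
        raise ValueError("design must be 2-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError("design contains non-finite values")
    return arr, names


def _check_rank(arr: np.ndarray, names: Sequence[str], include_intercept: bool):
    """Raise CollinearityError naming dependent columns if rank deficient."""
    full = sm.add_constant(arr, has_constant="add") if include_intercept else arr
    rank = np.linalg.matrix_rank(full)
    if rank >= full.shape[1]:
        return
    # Identify a minimal set of offending columns by greedy inclusion.
    dependent = []
    kept = np.ones((arr.shape[0], 1)) if include_intercept else np.empty((arr.shape[0], 0))
    for j in range(arr.shape[1]):
        cand = np.column_stack([kept, arr[:, j]])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            dependent.append(names[j])
        else:
            kept = cand
    raise CollinearityError(
        "design matrix is rank deficient; linearly dependent columns: "
        + (", ".join(dependent) if dependent else "<intercept-confounded>"),
        columns=dependent,
    )


class OLSModel(RegressorMixin, BaseEstimator):
    """Ordinary least squares with report-grade diagnostics.

    Parameters
    ----------
    include_intercept : bool, default True
        Whether to prepend a constant column to the design.

    Attributes (after :meth:`fit`)
    ------------------------------
    coef_, intercept_ : point estimates
    se_coef_, se_intercept_ : standard errors (n-p-1 residual df)
    r2_, r2_adj_, residual_sd_, f_stat_, f_pvalue_ : global statistics
    hat_values_ : hat-matrix diagonal of the training design
    n_obs_, n_predictors_, predictor_names_
    """

    def __init__(self, include_intercept: bool = True):
        self.include_intercept = include_intercept

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y, predictor_names=None):
        arr, names = _as_design(X, predictor_names)
        y = np.asarray(y, dtype=float).ravel()
        n, p = arr.shape
        if y.shape[0] != n:
            raise ValueError(
                f"response length {y.shape[0]} != design rows {n}"
            )
        n_params = p + (1 if self.include_intercept else 0)
        if n <= n_params:
            raise InsufficientDataError(
                f"need more than {n_params} observations for {p} predictors"
                f" (got n={n}); no residual degrees of freedom"
            )
        _check_rank(arr, names, self.include_intercept)

        design = (
            sm.add_constant(arr, has_constant="add")
            if self.include_intercept
            else arr
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            res = sm.OLS(y, design).fit()
            # force lazily computed statistics inside the errstate guard
            res.fvalue, res.f_pvalue, res.rsquared, res.rsquared_adj
        self._sm_result_ = res
        self._design_ = design
        self._response_ = y
        self.predictor_names_ = tuple(names)
        self.n_obs_ = int(n)
        self.n_predictors_ = int(p)
        params = np.asarray(res.params, dtype=float)
        bse = np.asarray(res.bse, dtype=float)
        if self.include_intercept:
            self.intercept_ = float(params[0])
            self.se_intercept_ = float(bse[0])
            self.coef_ = params[1:].copy()
            self.se_coef_ = bse[1:].copy()
        else:
            self.intercept_ = 0.0
            self.se_intercept_ = 0.0
            self.coef_ = params.copy()
            self.se_coef_ = bse.copy()
        self.r2_ = float(res.rsquared)
        self.r2_adj_ = float(res.rsquared_adj)
        self.residual_sd_ = float(np.sqrt(res.mse_resid))
        self.f_stat_ = float(res.fvalue)
        self.f_pvalue_ = float(res.f_pvalue)
        self.fitted_values_ = np.asarray(res.fittedvalues, dtype=float)
        self.residuals_ = np.asarray(res.resid, dtype=float)
        self.hat_values_ = np.asarray(
            res.get_influence().hat_matrix_diag, dtype=float
        )
        # Gram inverse for leverage of new points.
        self._xtx_inv_ = np.linalg.pinv(design.T @ design)
        return self

    # -- prediction --------------------------------------------------------

    def _require_fitted(self):
        if not hasattr(self, "coef_"):
            raise AttributeError("model is not fitted; call fit() first")

    def predict(self, X, coef_precision: int | None = None) -> np.ndarray:
        """Linear prediction.

        ``coef_precision`` rounds the intercept and coefficients to that
        many decimals before evaluating — the "equation as published" mode
        used when reproducing printed prediction tables, where the source
        equations carry three decimals.
        """
        self._require_fitted()
        arr, _ = _as_design(X, self.predictor_names_)
        if arr.shape[1] != self.n_predictors_:
            raise ValueError(
                f"expected {self.n_predictors_} predictors, got {arr.shape[1]}"
            )
        b0, b = self.intercept_, self.coef_
        if coef_precision is not None:
            b0 = float(np.round(b0, coef_precision))
            b = np.round(b, coef_precision)
        return b0 + arr @ b

    def leverage_of(self, X) -> np.ndarray:
        """Hat value x (X'X)^-1 x' of new points in the training design
        space; used for applicability-domain screening."""
        self._require_fitted()
        arr, _ = _as_design(X, self.predictor_names_)
        if self.include_intercept:
            arr = sm.add_constant(arr, has_constant="add")
        return np.einsum("ij,jk,ik->i", arr, self._xtx_inv_, arr)

    # -- diagnostics -------------------------------------------------------

    def summary(self, response_name: str = "y") -> LinearModelFit:
        self._require_fitted()
        return LinearModelFit(
            predictor_names=self.predictor_names_,
            coefficients=tuple(float(b) for b in self.coef_),
            standard_errors=tuple(float(s) for s in self.se_coef_),
            intercept=self.intercept_,
            intercept_se=self.se_intercept_,
            n_obs=self.n_obs_,
            n_predictors=self.n_predictors_,
            r2=self.r2_,
            r2_adj=self.r2_adj_,
            residual_sd=self.residual_sd_,
            f_stat=self.f_stat_,
            p_value=self.f_pvalue_,
            response_name=response_name,
        )

    def leverage(self, n_descriptors: int | None = None) -> LeverageDiagnostics:
        """Leverage diagnostics with warning limit h* = 3m/n, m defaulting
        to the number of descriptors in the model (intercept excluded)."""
        self._require_fitted()
        m = self.n_predictors_ if n_descriptors is None else int(n_descriptors)
        h = self.hat_values_
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = self.residual_sd_ * np.sqrt(np.clip(1.0 - h, 0.0, None))
            std_resid = np.where(denom > 0, self.residuals_ / denom, np.nan)
        return LeverageDiagnostics(
            hat_values=tuple(float(v) for v in h),
            h_star=3.0 * m / self.n_obs_,
            standardized_residuals=tuple(float(v) for v in std_resid),
        )

    def standardized_coefficients(self) -> np.ndarray:
        """Coefficients of the same OLS fit on z-scored predictors and
        response (ddof=1); dimensionless effect sizes whose signs rank the
        descriptors' contributions."""
        self._require_fitted()
        Xc = self._design_[:, 1:] if self.include_intercept else self._design_
        sx = Xc.std(axis=0, ddof=1)
        sy = self._response_.std(ddof=1)
        if np.any(sx == 0) or sy == 0:
            raise DegenerateDesignError(
                "zero-variance predictor or response; cannot standardize"
            )
        return self.coef_ * sx / sy

    def loo_press(self) -> float:
        """PRESS via the hat-value shortcut sum((e_i/(1-h_ii))^2)."""
        self._require_fitted()
        return float(np.sum((self.residuals_ / (1.0 - self.hat_values_)) ** 2))


# ---------------------------------------------------------------------------
# functional wrappers


def ols_fit(
    design,
    response,
    include_intercept: bool = True,
    predictor_names=None,
    response_name: str = "y",
) -> LinearModelFit:
    """Fit OLS and return the immutable :class:`LinearModelFit` summary."""
    model = OLSModel(include_intercept=include_intercept)
    model.fit(design, response, predictor_names=predictor_names)
    return model.summary(response_name=response_name)


def vif(design, predictor_names=None) -> pd.Series:
    """Variance inflation factors 1/(1-R²_j), one per predictor, from
    auxiliary regressions (with intercept) of each column on the others."""
    arr, names = _as_design(design, predictor_names)
    if arr.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    _check_rank(arr, names, include_intercept=True)
    out = {}
    for j, name in enumerate(names):
        others = np.delete(arr, j, axis=1)
        aux = sm.OLS(arr[:, j], sm.add_constant(others)).fit()
        r2j = aux.rsquared
        if r2j >= 1.0 - 1e-12:
            raise CollinearityError(
                f"predictor {name} is perfectly explained by the others",
                columns=[name],
            )
        out[name] = 1.0 / (1.0 - r2j)
    return pd.Series(out, name="VIF")


def standardized_coefficients(design, response, predictor_names=None) -> pd.Series:
    model = OLSModel().fit(design, response, predictor_names=predictor_names)
    return pd.Series(
        model.standardized_coefficients(), index=list(model.predictor_names_)
    )


def leverage(design, response=None, predictor_names=None, n_descriptors=None):
    """Leverage diagnostics of a design (response optional; defaults to a
    zero vector since hat values depend on the design only)."""
    arr, names = _as_design(design, predictor_names)
    y = np.zeros(arr.shape[0]) if response is None else response
    model = OLSModel().fit(arr, y, predictor_names=names)
    return model.leverage(n_descriptors=n_descriptors)


def pairwise_r2(table) -> pd.DataFrame:
    """Symmetric matrix of squared Pearson correlations between columns;
    the multicollinearity screen quoted alongside LFER fits.  Pairs
    involving a zero-variance column are NaN."""
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(np.asarray(table, dtype=float))
    if table.shape[1] < 2 or table.shape[0] < 3:
        raise ValueError("need >= 2 columns and >= 3 rows")
    r = table.corr(method="pearson")  # pandas yields NaN for zero variance
    return r**2
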