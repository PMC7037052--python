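"""Cross-validation for linear log BB models.

Two schemes, matching how such models are commonly validated:

* leave-one-out (:func:`loo_cv`) — deterministic; PRESS is computed via the
  exact hat-value shortcut PRESS = sum((e_i / (1 - h_ii))^2), which equals
  the explicit n-refit loop for OLS (the test suite asserts this).
* repeated leave-50%-out (:func:`leave_half_out_cv`) — seeded random
  half-splits; per-repeat held-out squared error is rescaled to the full
  sample size so PRESS values are comparable across schemes.

Q² is 1 - PRESS/SS_tot with SS_tot about the full-sample mean, so Q² <= R²
always holds for the same data.  Note that some published validation
tables print the full fit's adjusted R² under the label "Q²"; that
quantity is available as ``r2_adj`` on the fitted model and is not what
this module computes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .exceptions import FoldFailureError, InsufficientDataError
from .regression import OLSModel, _as_design

__all__ = ["CrossValidationResult", "loo_cv", "leave_half_out_cv"]


@dataclass(frozen=True)
class CrossValidationResult:
    """PRESS, Q² and MSEcv (= PRESS/n) for one model under one scheme."""

    model_id: str
    scheme: str  # "LOO" or "L50O"
    press: float
    q2: float
    mse_cv: float
    n_obs: int
    repeats: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        d = {
            "model_id": self.model_id,
            "scheme": self.scheme,
            "press": self.press,
            "q2": self.q2,
            "mse_cv": self.mse_cv,
            "n_obs": self.n_obs,
        }
        if self.scheme == "L50O":
            d["repeats"] = self.repeats
            d["seed"] = self.seed
        return d


def loo_cv(design, response, model_id: str = "model") -> CrossValidationResult:
    """Leave-one-out cross-validation of an OLS model (with intercept).

    Uses the exact hat-value shortcut; requires n > p + 2 so every
    fold remains estimable.
    """
    arr, names = _as_design(design)
    y = np.asarray(response, dtype=float).ravel()
    n, p = arr.shape
    if n <= p + 2:
        raise InsufficientDataError(
            f"LOO needs n > p + 2 (p={p}); got n={n}"
        )
    model = OLSModel().fit(arr, y, predictor_names=names)
    h = model.hat_values_
    if np.any(h >= 1.0 - 1e-12):
        # a fold whose removal makes the design singular
        idx = int(np.argmax(h))
        raise FoldFailureError(
            f"observation {idx} has leverage ~1; its LOO fold is rank "
            "deficient",
            fold=idx,
        )
    press = float(np.sum((model.residuals_ / (1.0 - h)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / ss_tot
    return CrossValidationResult(
        model_id=model_id,
        scheme="LOO",
        press=press,
        q2=q2,
        mse_cv=press / n,
        n_obs=n,
    )


def loo_cv_explicit(design, response, model_id: str = "model"):
    """Brute-force LOO by n explicit refits; the independent oracle for
    :func:`loo_cv` (kept in the library so scripts can double-check)."""
    arr, _ = _as_design(design)
    y = np.asarray(response, dtype=float).ravel()
    n = arr.shape[0]
    errors = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        Xi = sm.add_constant(arr[mask], has_constant="add")
        fit = sm.OLS(y[mask], Xi).fit()
        xi = np.concatenate([[1.0], arr[i]])
        errors[i] = y[i] - float(xi @ fit.params)
    press = float(np.sum(errors**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return CrossValidationResult(
        model_id=model_id,
        scheme="LOO",
        press=press,
        q2=1.0 - press / ss_tot,
        mse_cv=press / n,
        n_obs=n,
    )


def leave_half_out_cv(
    design,
    response,
    repeats: int = 200,
    seed: int | None = None,
    model_id: str = "model",
) -> CrossValidationResult:
    """Repeated random-half validation.

    Each repeat draws ceil(n/2) training rows uniformly without
    replacement, fits, and predicts the held-out remainder; the held-out
    squared-error sum is rescaled by n/n_test so the average over repeats
    (PRESS**) is on the same footing as LOO PRESS.  Rank-deficient repeats
    are skipped; more than 10% skipped is an error.
    """
    arr, _ = _as_design(design)
    y = np.asarray(response, dtype=float).ravel()
    n, p = arr.shape
    if n < 10:
        raise InsufficientDataError(f"leave-50%-out needs n >= 10, got n={n}")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    n_train = int(np.ceil(n / 2))
    press_values = []
    skipped = 0
    for _ in range(repeats):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        Xtr = sm.add_constant(arr[train], has_constant="add")
        if np.linalg.matrix_rank(Xtr) < p + 1:
            skipped += 1
            continue
        fit = sm.OLS(y[train], Xtr).fit()
        Xte = sm.add_constant(arr[test], has_constant="add")
        err = y[test] - Xte @ fit.params
        press_values.append(float(np.sum(err**2)) * n / test.size)
    if skipped > 0.1 * repeats:
        raise FoldFailureError(
            f"{skipped}/{repeats} random halves were rank deficient"
        )
    press = float(np.mean(press_values))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return CrossValidationResult(
        model_id=model_id,
        scheme="L50O",
        press=press,
        q2=1.0 - press / ss_tot,
        mse_cv=press / n,
        n_obs=n,
        repeats=repeats,
        seed=seed,
    )
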