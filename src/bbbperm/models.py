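"""Blood-brain-barrier permeability models.

Two layers:

1. :class:`AbrahamLFER` — the solvation-parameter linear free-energy
   relationship log BB = c + eE + sS + aA + bB + vV, calibrated on
   compounds with experimental brain/plasma distribution data.  Fitting
   also computes the descriptor pairwise-R² screen, VIFs and leverage
   diagnostics; prediction attaches the leverage of each new compound in
   the training descriptor space and an applicability-domain flag
   (leverage <= h* = 3m/n).

2. :class:`RetentionQSAR` — a per-column QSAR regressing log BB on an
   experimentally accessible lipophilicity measure (chromatographic
   log k_w, or a computed octanol-water log P) together with TPSA and
   molecular polarizability.

Both are scikit-learn style estimators over :class:`~bbbperm.regression.OLSModel`.
``predict(..., coef_precision=3)`` evaluates the equation at published
precision, which is how printed prediction tables are reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import IncompleteRecordError, InsufficientDataError
from .regression import (
    LeverageDiagnostics,
    LinearModelFit,
    OLSModel,
    pairwise_r2,
    vif,
)

__all__ = [
    "ABRAHAM_DESCRIPTORS",
    "AbrahamDescriptors",
    "BulkDescriptors",
    "CompoundRecord",
    "PredictionRecord",
    "AbrahamLFER",
    "RetentionQSAR",
    "fit_lfer",
    "predict_lfer",
    "fit_qsar",
    "predict_qsar",
]

ABRAHAM_DESCRIPTORS = ("E", "S", "A", "B", "V")


@dataclass(frozen=True)
class AbrahamDescriptors:
    """Abraham solute descriptors: excess molar refraction E,
    dipolarity/polarizability S, H-bond acidity A, H-bond basicity B and
    McGowan volume V in (cm3/mol)/100."""

    E: float
    S: float
    A: float
    B: float
    V: float

    def __post_init__(self):
        if self.V <= 0:
            raise ValueError(f"McGowan volume must be positive, got {self.V}")
        if self.A < 0 or self.B < 0:
            raise ValueError("hydrogen-bond acidity/basicity must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.E, self.S, self.A, self.B, self.V])


@dataclass(frozen=True)
class BulkDescriptors:
    """In-silico bulk descriptors: TPSA (A^2), polarizability alpha (A^3),
    molecular weight (g/mol) and optionally a computed log P."""

    TPSA: float
    alpha: float
    MW: float
    alogps: float | None = None

    def __post_init__(self):
        if self.TPSA < 0:
            raise ValueError(f"TPSA must be >= 0, got {self.TPSA}")
        if self.alpha <= 0 or self.MW <= 0:
            raise ValueError("polarizability and MW must be positive")


@dataclass(frozen=True)
class CompoundRecord:
    """One compound with whichever descriptor blocks are available."""

    compound_id: str
    group: str = ""
    abraham: AbrahamDescriptors | None = None
    bulk: BulkDescriptors | None = None
    log_kw: dict | None = None  # column_id -> extrapolated log k_w
    log_bb_experimental: float | None = None

    def __post_init__(self):
        if self.abraham is None and self.bulk is None and not self.log_kw:
            raise ValueError(
                f"compound {self.compound_id}: no descriptor block present"
            )


@dataclass(frozen=True)
class PredictionRecord:
    """A model prediction plus its applicability-domain diagnostics."""

    compound_id: str
    model_id: str
    log_bb_predicted: float
    leverage_new: float
    inside_domain: bool


class _LinearBBModel(RegressorMixin, BaseEstimator):
    """Shared fit/predict plumbing for the two log BB model layers."""

    _predictors: tuple[str, ...] = ()
    _model_id: str = "model"

    def _fit_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self._predictors if c not in X.columns]
            if missing:
                raise IncompleteRecordError(
                    "missing descriptor column(s): " + ", ".join(missing)
                )
            frame = X.loc[:, list(self._predictors)].astype(float)
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != len(self._predictors):
                raise IncompleteRecordError(
                    f"expected {len(self._predictors)} descriptor columns "
                    f"{self._predictors}, got shape {getattr(arr, 'shape', None)}"
                )
            frame = pd.DataFrame(arr, columns=list(self._predictors))
        bad = frame.index[frame.isna().any(axis=1)]
        if len(bad):
            raise IncompleteRecordError(
                "incomplete descriptor values for row(s): "
                + ", ".join(str(i) for i in bad)
            )
        return frame

    def fit(self, X, y):
        frame = self._fit_frame(X)
        y = np.asarray(y, dtype=float).ravel()
        self.model_ = OLSModel().fit(frame, y)
        self.coef_ = self.model_.coef_
        self.intercept_ = self.model_.intercept_
        self.r2_ = self.model_.r2_
        self.leverage_ = self.model_.leverage()
        self.h_star_ = self.leverage_.h_star
        self.vif_ = vif(frame)
        self.pairwise_r2_ = pairwise_r2(frame)
        return self

    def predict(self, X, coef_precision: int | None = None) -> np.ndarray:
        frame = self._fit_frame(X)
        return self.model_.predict(frame, coef_precision=coef_precision)

    def summary(self, response_name: str = "log BB") -> LinearModelFit:
        return self.model_.summary(response_name=response_name)

    def leverage_of(self, X) -> np.ndarray:
        return self.model_.leverage_of(self._fit_frame(X))

    def predict_records(
        self,
        X,
        compound_ids: Sequence | None = None,
        coef_precision: int | None = None,
    ) -> list[PredictionRecord]:
        """Predictions with leverage in the training design space and the
        h*-based applicability-domain flag."""
        frame = self._fit_frame(X)
        preds = self.model_.predict(frame, coef_precision=coef_precision)
        levs = self.model_.leverage_of(frame)
        if compound_ids is None:
            compound_ids = [str(i) for i in range(len(preds))]
        return [
            PredictionRecord(
                compound_id=str(cid),
                model_id=self._model_id,
                log_bb_predicted=float(p),
                leverage_new=float(h),
                inside_domain=bool(h <= self.h_star_),
            )
            for cid, p, h in zip(compound_ids, preds, levs)
        ]


class AbrahamLFER(_LinearBBModel):
    """Abraham solvation-parameter model for log BB.

    ``fit(X, y)`` takes a table with columns E, S, A, B, V and the
    experimental log BB response.  Requires n >= 7 so the five-descriptor
    fit keeps at least one residual degree of freedom.
    """

    _predictors = ABRAHAM_DESCRIPTORS
    _model_id = "lfer"

    def fit(self, X, y):
        n = len(X)
        if n < 7:
            raise InsufficientDataError(
                f"LFER calibration needs >= 7 compounds for 5 descriptors "
                f"+ intercept with df > 0; got {n}"
            )
        return super().fit(X, y)


class RetentionQSAR(_LinearBBModel):
    """Column-specific QSAR: log BB ~ lipophilicity + TPSA + alpha.

    Parameters
    ----------
    column_id : str
        Stationary-phase label ("ODS", "IAM", "Cholester", ...); metadata
        recorded in prediction records.
    lipophilicity_source : {"log_kw", "alogps"}
        Which lipophilicity measure the first predictor is.
    """

    def __init__(
        self, column_id: str = "ODS", lipophilicity_source: str = "log_kw"
    ):
        self.column_id = column_id
        self.lipophilicity_source = lipophilicity_source

    @property
    def _predictors(self) -> tuple[str, ...]:
        lipo = (
            f"log_kw_{self.column_id}"
            if self.lipophilicity_source == "log_kw"
            else "alogps"
        )
        return (lipo, "TPSA", "alpha")

    @property
    def _model_id(self) -> str:
        return (
            f"qsar_{self.column_id}"
            if self.lipophilicity_source == "log_kw"
            else "qsar_alogps"
        )


# ---------------------------------------------------------------------------
# record-oriented functional wrappers


def _records_to_lfer_frame(records: Iterable[CompoundRecord]):
    rows, y, ids = [], [], []
    for rec in records:
        if rec.abraham is None:
            raise IncompleteRecordError(
                f"compound {rec.compound_id} lacks Abraham descriptors"
            )
        if rec.log_bb_experimental is None:
            raise IncompleteRecordError(
                f"compound {rec.compound_id} lacks experimental log BB"
            )
        rows.append(rec.abraham.as_array())
        y.append(rec.log_bb_experimental)
        ids.append(rec.compound_id)
    X = pd.DataFrame(rows, columns=list(ABRAHAM_DESCRIPTORS), index=ids)
    return X, np.array(y)


def fit_lfer(records: Iterable[CompoundRecord]) -> AbrahamLFER:
    """Calibrate the LFER on compound records carrying Abraham descriptors
    and experimental log BB."""
    X, y = _records_to_lfer_frame(records)
    return AbrahamLFER().fit(X, y)


def predict_lfer(
    model: AbrahamLFER,
    compound: AbrahamDescriptors,
    compound_id: str = "",
    coef_precision: int | None = None,
) -> PredictionRecord:
    X = pd.DataFrame(
        [compound.as_array()], columns=list(ABRAHAM_DESCRIPTORS)
    )
    return model.predict_records(
        X, compound_ids=[compound_id], coef_precision=coef_precision
    )[0]


def fit_qsar(
    records: Iterable[CompoundRecord],
    column_id: str,
    response,
    lipophilicity_source: str = "log_kw",
) -> RetentionQSAR:
    """Fit a per-column QSAR from compound records; ``response`` is the
    log BB vector (typically LFER predictions for the same compounds)."""
    rows, ids = [], []
    for rec in records:
        if rec.bulk is None:
            raise IncompleteRecordError(
                f"compound {rec.compound_id} lacks bulk descriptors"
            )
        if lipophilicity_source == "log_kw":
            if not rec.log_kw or column_id not in rec.log_kw:
                raise IncompleteRecordError(
                    f"compound {rec.compound_id} lacks log k_w for column "
                    f"{column_id}"
                )
            lipo = rec.log_kw[column_id]
        else:
            if rec.bulk.alogps is None:
                raise IncompleteRecordError(
                    f"compound {rec.compound_id} lacks a computed log P"
                )
            lipo = rec.bulk.alogps
        rows.append((lipo, rec.bulk.TPSA, rec.bulk.alpha))
        ids.append(rec.compound_id)
    model = RetentionQSAR(
        column_id=column_id, lipophilicity_source=lipophilicity_source
    )
    X = pd.DataFrame(rows, columns=list(model._predictors), index=ids)
    return model.fit(X, np.asarray(response, dtype=float))


def predict_qsar(
    model: RetentionQSAR,
    compound: CompoundRecord,
    coef_precision: int | None = None,
) -> PredictionRecord:
    if compound.bulk is None:
        raise IncompleteRecordError(
            f"compound {compound.compound_id} lacks bulk descriptors"
        )
    if model.lipophilicity_source == "log_kw":
        if not compound.log_kw or model.column_id not in compound.log_kw:
            raise IncompleteRecordError(
                f"compound {compound.compound_id} lacks log k_w for column "
                f"{model.column_id}"
            )
        lipo = compound.log_kw[model.column_id]
    else:
        lipo = compound.bulk.alogps
    X = pd.DataFrame(
        [(lipo, compound.bulk.TPSA, compound.bulk.alpha)],
        columns=list(model._predictors),
    )
    return model.predict_records(
        X, compound_ids=[compound.compound_id], coef_precision=coef_precision
    )[0]
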