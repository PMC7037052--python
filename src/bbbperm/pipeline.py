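"""End-to-end modelling pipeline and report writer.

Stages, in the order the study design dictates:

1. (optional) fit Soczewinski-Wachtmeister lines to raw isocratic series,
   yielding per-compound (log k_w, s) for each stationary phase;
2. inter-column calibrations (log k_w of one phase vs another) and the
   within-column log k_w vs s regressions;
3. LFER calibration of log BB on Abraham descriptors, with descriptor
   pairwise-R², VIF and leverage diagnostics;
4. LFER prediction for the test compounds, at published equation precision
   (coefficients rounded to ``equation_precision`` decimals) and rounded to
   ``report_rounding`` decimals for the report table — the convention under
   which published prediction tables are reproducible;
5. per-column QSAR fits of the (rounded) LFER predictions on
   (log k_w, TPSA, alpha), plus predictions;
6. leave-one-out and seeded leave-50%-out cross-validation of every model.

``run_pipeline`` returns a plain dict (JSON-serializable apart from the
DataFrames) and ``write_report`` materializes CSV/JSON/text outputs.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .models import AbrahamLFER, RetentionQSAR
from .retention import RetentionExtrapolator, cross_column_regression
from .regression import OLSModel
from .validation import leave_half_out_cv, loo_cv

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]

logger = logging.getLogger("bbbperm")
if not logger.handlers:  # stderr logging, configurable by the host app
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass
class PipelineConfig:
    """Inputs and knobs of one pipeline run.

    ``None`` paths mean the packaged study fixtures.  ``equation_precision``
    is the decimal precision at which fitted equations are applied when
    building report tables (3, as published); ``response_rounding`` is the
    rounding applied to the LFER predictions before they become the QSAR
    response (2 dp reproduces the published workflow; None disables).
    """

    retention_path: str | None = None
    training_path: str | None = None
    prediction_path: str | None = None
    raw_retention_path: str | None = None
    columns: tuple[str, ...] = bio.COLUMNS
    cv_repeats: int = 200
    seed: int = 20200123
    equation_precision: int | None = 3
    response_rounding: int | None = 2
    report_rounding: int = 2
    out_dir: str = "bbbperm_out"

    def __post_init__(self):
        if self.cv_repeats < 1:
            raise ValueError("cv_repeats must be >= 1")


def _fit_raw_retention(raw: pd.DataFrame) -> pd.DataFrame:
    """Collapse long-format raw measurements to wide (log_kw, s) fits."""
    rows: dict[str, dict] = {}
    for (cid, col), grp in raw.groupby(["compound_id", "column_id"], sort=False):
        log_k = np.log10((grp["t_r"] - grp["t_0"]) / grp["t_0"])
        fit = RetentionExtrapolator().fit(grp["phi"].to_numpy(), log_k.to_numpy())
        rows.setdefault(cid, {"compound_id": cid})
        rows[cid][f"log_kw_{col}"] = fit.log_kw_
        rows[cid][f"s_{col}"] = fit.s_
    return pd.DataFrame(list(rows.values()))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; see the module docstring for stages."""
    results: dict = {"config": {
        "columns": list(config.columns),
        "cv_repeats": config.cv_repeats,
        "seed": config.seed,
        "equation_precision": config.equation_precision,
        "response_rounding": config.response_rounding,
        "provenance": "packaged study fixtures"
        if config.retention_path is None
        else str(config.retention_path),
    }}

    # -- stage 1: retention parameters ------------------------------------
    if config.raw_retention_path is not None:
        raw = bio.load_raw_retention(config.raw_retention_path)
        retention = _fit_raw_retention(raw)
        logger.info(
            "stage retention: fitted %d series from %d raw measurements",
            retention.shape[0], raw.shape[0],
        )
    else:
        retention = bio.load_retention_params(config.retention_path)
        logger.info(
            "stage retention: loaded %d pre-fitted compounds", len(retention)
        )
    training = bio.load_training_set(config.training_path)
    prediction = bio.load_test_compounds(config.prediction_path)
    logger.info(
        "stage load: training n=%d, prediction n=%d",
        len(training), len(prediction),
    )
    if not retention["compound_id"].tolist() == prediction["compound_id"].tolist():
        from .exceptions import InconsistentInputError

        raise InconsistentInputError(
            "retention and prediction tables list different compounds"
        )

    # -- stage 2: calibration regressions ----------------------------------
    cross = {}
    for xcol, ycol in (("IAM", "ODS"), ("Cholester", "ODS"), ("Cholester", "IAM")):
        fit = cross_column_regression(
            retention[f"log_kw_{xcol}"],
            retention[f"log_kw_{ycol}"],
            x_name=f"log_kw_{xcol}",
            y_name=f"log_kw_{ycol}",
        )
        cross[f"{ycol}_vs_{xcol}"] = fit.to_dict()
    kw_s = {}
    for col in config.columns:
        fit = (
            OLSModel()
            .fit(
                retention[[f"s_{col}"]].to_numpy(),
                retention[f"log_kw_{col}"].to_numpy(),
                predictor_names=[f"s_{col}"],
            )
            .summary(response_name=f"log_kw_{col}")
        )
        kw_s[col] = fit.to_dict()
    results["cross_column"] = cross
    results["kw_vs_slope"] = kw_s
    logger.info(
        "stage calibration: %d inter-column + %d within-column regressions",
        len(cross), len(kw_s),
    )

    # -- stage 3: LFER ------------------------------------------------------
    lfer = AbrahamLFER().fit(
        training[["E", "S", "A", "B", "V"]], training["log_bb_exp"]
    )
    results["lfer"] = {
        **lfer.summary(response_name="log_bb").to_dict(),
        "h_star": lfer.h_star_,
        "vif": lfer.vif_.to_dict(),
        "pairwise_r2": lfer.pairwise_r2_.round(6).to_dict(),
        "standardized_coefficients": dict(
            zip(lfer.model_.predictor_names_,
                lfer.model_.standardized_coefficients())
        ),
    }
    logger.info("stage lfer: n=%d R2=%.4f", lfer.model_.n_obs_, lfer.r2_)

    # -- stage 4: LFER predictions for the test compounds -------------------
    Xp = prediction[["E", "S", "A", "B", "V"]]
    pred_lfer = lfer.predict(Xp, coef_precision=config.equation_precision)
    lev_new = lfer.leverage_of(Xp)
    pred_table = pd.DataFrame(
        {
            "compound_id": prediction["compound_id"],
            "log_bb_lfer": bio.round_half_away(
                pred_lfer, config.report_rounding
            ),
            "leverage_lfer": lev_new,
            "inside_domain_lfer": lev_new <= lfer.h_star_,
        }
    )

    # -- stage 5: per-column QSARs ------------------------------------------
    response = (
        bio.round_half_away(pred_lfer, config.response_rounding)
        if config.response_rounding is not None
        else pred_lfer
    )
    results["qsar"] = {}
    for col in config.columns:
        X = pd.DataFrame(
            {
                f"log_kw_{col}": retention[f"log_kw_{col}"].to_numpy(),
                "TPSA": prediction["TPSA"].to_numpy(),
                "alpha": prediction["alpha"].to_numpy(),
            }
        )
        qsar = RetentionQSAR(column_id=col).fit(X, response)
        results["qsar"][col] = {
            **qsar.summary(response_name="log_bb").to_dict(),
            "h_star": qsar.h_star_,
            "vif": qsar.vif_.to_dict(),
            "max_vif": float(qsar.vif_.max()),
            "standardized_coefficients": dict(
                zip(qsar.model_.predictor_names_,
                    qsar.model_.standardized_coefficients())
            ),
        }
        pred_q = qsar.predict(X, coef_precision=config.equation_precision)
        pred_table[f"log_bb_qsar_{col}"] = bio.round_half_away(
            pred_q, config.report_rounding
        )
        results.setdefault("_qsar_models", {})[col] = (qsar, X)
    logger.info("stage qsar: fitted %d column models", len(config.columns))

    # -- stage 6: cross-validation ------------------------------------------
    cv_rows = []
    Xl = training[["E", "S", "A", "B", "V"]].to_numpy()
    yl = training["log_bb_exp"].to_numpy()
    cv_rows.append(loo_cv(Xl, yl, model_id="lfer").to_dict())
    cv_rows.append(
        leave_half_out_cv(
            Xl, yl, repeats=config.cv_repeats, seed=config.seed,
            model_id="lfer",
        ).to_dict()
    )
    for col in config.columns:
        qsar, X = results["_qsar_models"][col]
        Xq = X.to_numpy()
        cv_rows.append(loo_cv(Xq, response, model_id=f"qsar_{col}").to_dict())
        cv_rows.append(
            leave_half_out_cv(
                Xq, response, repeats=config.cv_repeats,
                seed=config.seed, model_id=f"qsar_{col}",
            ).to_dict()
        )
    del results["_qsar_models"]
    results["cv"] = cv_rows
    results["predictions"] = pred_table
    logger.info("stage cv: %d validation runs", len(cv_rows))
    return results


def _summary_lines(results: dict) -> str:
    """Human-readable model summaries in the journal line format."""
    out = []
    for label, d in (
        [("lfer", results["lfer"])]
        + [(f"qsar_{c}", results["qsar"][c]) for c in results["qsar"]]
    ):
        coefs = " ".join(
            f"{'-' if b < 0 else '+'} {abs(b):.3f}(± {se:.3f}) {nm}"
            for nm, b, se in zip(
                d["predictors"], d["coefficients"], d["standard_errors"]
            )
        )
        out.append(
            f"[{label}] log_bb = {d['intercept']:.3f}"
            f"(± {d['intercept_se']:.3f}) {coefs}"
        )
        out.append(
            f"  N = {d['n_obs']}; SD = {d['residual_sd']:.3f}; "
            f"R2 = {d['r2']:.4f}; F = {d['f_stat']:.0f}"
        )
    return "\n".join(out) + "\n"


def write_report(results: dict, out_dir) -> list[Path]:
    """Write predictions.csv, cv.csv, models.json and summary.txt."""
    if not results:
        logger.warning("empty results; nothing to write")
        return []
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    predictions: pd.DataFrame = results["predictions"]
    p = out / "predictions.csv"
    predictions.to_csv(p, index=False)
    written.append(p)

    cv = pd.DataFrame(results["cv"])
    p = out / "cv.csv"
    cv.to_csv(p, index=False)
    written.append(p)

    serializable = {
        k: v for k, v in results.items() if k != "predictions"
    }
    p = out / "models.json"
    with open(p, "w") as fh:
        json.dump(serializable, fh, indent=2, sort_keys=True, default=float)
    written.append(p)

    p = out / "summary.txt"
    p.write_text(_summary_lines(results))
    written.append(p)
    logger.info("wrote %d report files to %s", len(written), out)
    return written
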