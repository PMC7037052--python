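"""LFER calibration and per-column QSAR models."""

import numpy as np
import pandas as pd
import pytest

from bbbperm.exceptions import IncompleteRecordError, InsufficientDataError
from bbbperm.io import round_half_away
from bbbperm.models import (
    AbrahamDescriptors,
    AbrahamLFER,
    BulkDescriptors,
    CompoundRecord,
    RetentionQSAR,
    fit_lfer,
    fit_qsar,
    predict_lfer,
    predict_qsar,
)
from bbbperm.synthetic import ModelSimSpec, gen_training_table

DESC = ["E", "S", "A", "B", "V"]


class TestAbrahamLFER:
    def test_printed_calibration_statistics(self, lfer):
        s = lfer.summary()
        assert s.n_obs == 23
        assert s.r2 == pytest.approx(0.9039, abs=0.005)
        assert s.residual_sd == pytest.approx(0.134, abs=0.005)
        assert s.intercept == pytest.approx(0.934, abs=0.01)
        coef = dict(zip(s.predictor_names, s.coefficients))
        assert coef["V"] == pytest.approx(0.545, abs=0.01)
        assert coef["S"] == pytest.approx(-0.605, abs=0.01)
        assert s.f_stat == pytest.approx(32, abs=1)

    def test_standardized_signs(self, lfer):
        signs = np.sign(lfer.model_.standardized_coefficients())
        assert list(signs) == [1, -1, -1, -1, 1]  # E, S, A, B, V

    def test_exact_recovery_of_planted_lfer(self):
        spec = ModelSimSpec(n_compounds=40, noise_sd=0.0, seed=3)
        df = gen_training_table(spec)
        model = AbrahamLFER().fit(df[DESC], df["log_bb"])
        truth = spec.true_coefficients
        assert model.intercept_ == pytest.approx(truth["intercept"], abs=1e-10)
        for name, est in zip(DESC, model.coef_):
            assert est == pytest.approx(truth[name], abs=1e-10)
        assert model.r2_ == pytest.approx(1.0, abs=1e-12)

    def test_minimum_training_size_enforced(self):
        df = gen_training_table(ModelSimSpec(n_compounds=40, seed=0)).head(6)
        with pytest.raises(InsufficientDataError):
            AbrahamLFER().fit(df[DESC], df["log_bb"])

    def test_missing_descriptor_column(self, training_table):
        with pytest.raises(IncompleteRecordError):
            AbrahamLFER().fit(
                training_table[["E", "S", "A", "B"]],
                training_table["log_bb_exp"],
            )

    def test_all_zero_descriptors_predict_intercept(self, lfer):
        X = pd.DataFrame(
            [[0.0, 0.0, 0.0, 0.0, 0.0]], columns=DESC
        )
        assert lfer.predict(X)[0] == pytest.approx(lfer.intercept_)

    def test_prediction_is_linear_in_descriptors(self, lfer, rng):
        # predict(d1 + d2) - predict(d2) does not depend on d2
        d1 = rng.uniform(0, 2, size=5)
        for _ in range(5):
            d2 = rng.uniform(0, 2, size=5)
            d3 = rng.uniform(0, 2, size=5)
            X = pd.DataFrame([d1 + d2, d2, d1 + d3, d3], columns=DESC)
            p = lfer.predict(X)
            assert p[0] - p[1] == pytest.approx(p[2] - p[3], abs=1e-10)

    def test_worked_example_predictions(self, lfer):
        # first and last test compounds, at published equation precision
        X = pd.DataFrame(
            [
                [1.88, 1.73, 0.0, 1.34, 1.8144],
                [2.71, 2.38, 0.0, 1.35, 2.6670],
            ],
            columns=DESC,
        )
        pred = round_half_away(lfer.predict(X, coef_precision=3), 2)
        assert pred[0] == pytest.approx(0.21)
        assert pred[1] == pytest.approx(0.43)

    def test_record_interface_round_trip(self, training_table):
        records = [
            CompoundRecord(
                compound_id=row.compound_id,
                abraham=AbrahamDescriptors(
                    E=row.E, S=row.S, A=row.A, B=row.B, V=row.V
                ),
                log_bb_experimental=row.log_bb_exp,
            )
            for row in training_table.itertuples()
        ]
        model = fit_lfer(records)
        assert model.r2_ == pytest.approx(0.9039, abs=0.005)
        rec = predict_lfer(
            model,
            AbrahamDescriptors(E=1.88, S=1.73, A=0.0, B=1.34, V=1.8144),
            compound_id="1",
            coef_precision=3,
        )
        assert round_half_away(rec.log_bb_predicted, 2) == pytest.approx(0.21)
        assert rec.inside_domain == (rec.leverage_new <= model.h_star_)


class TestRetentionQSAR:
    def _qsar_design(self, retention_table, test_table, col):
        return pd.DataFrame(
            {
                f"log_kw_{col}": retention_table[f"log_kw_{col}"].to_numpy(),
                "TPSA": test_table["TPSA"].to_numpy(),
                "alpha": test_table["alpha"].to_numpy(),
            }
        )

    @pytest.fixture()
    def published_response(self, lfer, test_table):
        pred = lfer.predict(test_table[DESC], coef_precision=3)
        return round_half_away(pred, 2)

    @pytest.mark.parametrize(
        "col,r2_ref,vif_ref",
        [("ODS", 0.8474, 3.1), ("IAM", 0.8469, 2.7), ("Cholester", 0.8471, 3.7)],
    )
    def test_printed_qsar_statistics(
        self, retention_table, test_table, published_response, col, r2_ref, vif_ref
    ):
        X = self._qsar_design(retention_table, test_table, col)
        model = RetentionQSAR(column_id=col).fit(X, published_response)
        assert model.r2_ == pytest.approx(r2_ref, abs=0.01)
        assert model.vif_.max() <= vif_ref

    def test_standardized_signs_lipophilicity_positive_tpsa_negative(
        self, retention_table, test_table, published_response
    ):
        for col in ("ODS", "IAM", "Cholester"):
            X = self._qsar_design(retention_table, test_table, col)
            model = RetentionQSAR(column_id=col).fit(X, published_response)
            signs = np.sign(model.model_.standardized_coefficients())
            assert list(signs) == [1, -1, 1]

    def test_planted_model_ignores_lipophilicity(self, rng):
        n = 60
        X = pd.DataFrame(
            {
                "log_kw_ODS": rng.uniform(0.5, 4.5, n),
                "TPSA": rng.uniform(48, 84, n),
                "alpha": rng.uniform(27, 42, n),
            }
        )
        y = 0.6 - 0.013 * X["TPSA"] + 0.009 * X["alpha"]
        model = RetentionQSAR(column_id="ODS").fit(X, y)
        assert model.coef_[0] == pytest.approx(0.0, abs=1e-10)
        assert model.coef_[1] == pytest.approx(-0.013, abs=1e-10)
        assert model.coef_[2] == pytest.approx(0.009, abs=1e-10)
        assert model.intercept_ == pytest.approx(0.6, abs=1e-10)

    def test_intercept_prediction_at_origin(
        self, retention_table, test_table, published_response
    ):
        X = self._qsar_design(retention_table, test_table, "ODS")
        model = RetentionQSAR(column_id="ODS").fit(X, published_response)
        origin = pd.DataFrame(
            [[0.0, 0.0, 0.0]], columns=X.columns
        )
        assert model.predict(origin)[0] == pytest.approx(model.intercept_)

    def test_record_interface_and_worked_example(
        self, retention_table, test_table, published_response
    ):
        records = []
        for rrow, prow in zip(
            retention_table.itertuples(), test_table.itertuples()
        ):
            records.append(
                CompoundRecord(
                    compound_id=prow.compound_id,
                    bulk=BulkDescriptors(
                        TPSA=prow.TPSA, alpha=prow.alpha, MW=prow.MW
                    ),
                    log_kw={
                        "ODS": rrow.log_kw_ODS,
                        "Cholester": rrow.log_kw_Cholester,
                    },
                )
            )
        for col, expected in (("ODS", 0.19), ("Cholester", 0.22)):
            model = fit_qsar(records, col, published_response)
            rec = predict_qsar(model, records[0], coef_precision=3)
            assert round_half_away(rec.log_bb_predicted, 2) == pytest.approx(
                expected
            )

    def test_alogps_lipophilicity_variant(self, rng):
        # same model form with a computed log P as the lipophilicity axis
        n = 40
        X = pd.DataFrame(
            {
                "alogps": rng.uniform(0.5, 4.0, n),
                "TPSA": rng.uniform(48, 84, n),
                "alpha": rng.uniform(27, 42, n),
            }
        )
        y = 0.627 + 0.077 * X["alogps"] - 0.012 * X["TPSA"] + 0.001 * X["alpha"]
        model = RetentionQSAR(lipophilicity_source="alogps").fit(X, y)
        assert model.coef_ == pytest.approx((0.077, -0.012, 0.001), abs=1e-10)
        records = [
            CompoundRecord(
                compound_id="a",
                bulk=BulkDescriptors(TPSA=60.0, alpha=35.0, MW=300.0, alogps=2.0),
            )
        ]
        rec = predict_qsar(model, records[0])
        expected = 0.627 + 0.077 * 2.0 - 0.012 * 60.0 + 0.001 * 35.0
        assert rec.log_bb_predicted == pytest.approx(expected, abs=1e-9)
        assert rec.model_id == "qsar_alogps"

    def test_missing_column_retention_is_incomplete(self, published_response):
        records = [
            CompoundRecord(
                compound_id=str(i),
                bulk=BulkDescriptors(TPSA=50.0, alpha=30.0, MW=300.0),
                log_kw={"ODS": 1.0 + i * 0.1},
            )
            for i in range(10)
        ]
        with pytest.raises(IncompleteRecordError):
            fit_qsar(records, "IAM", published_response[:10])


class TestDescriptorValidation:
    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            AbrahamDescriptors(E=1.0, S=1.0, A=0.1, B=0.1, V=-1.0)

    def test_negative_acidity_rejected(self):
        with pytest.raises(ValueError):
            AbrahamDescriptors(E=1.0, S=1.0, A=-0.1, B=0.1, V=1.0)

    def test_bulk_invariants(self):
        with pytest.raises(ValueError):
            BulkDescriptors(TPSA=-5.0, alpha=30.0, MW=300.0)
        with pytest.raises(ValueError):
            BulkDescriptors(TPSA=50.0, alpha=0.0, MW=300.0)

    def test_record_requires_some_descriptors(self):
        with pytest.raises(ValueError):
            CompoundRecord(compound_id="x")
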