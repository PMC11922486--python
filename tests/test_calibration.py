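import numpy as np
import pytest

from qcucvp import (
    agreement_metrics,
    apply_trained_model,
    cmh2o_to_mmhg,
    fit_linear,
    hydrostatic_offset,
    jvp_to_mmhg,
    predict,
)
from qcucvp.study_data import JvpStatus, StudyTable, SubjectRecord, Vein


class TestConversions:
    @pytest.mark.parametrize("theta,expected", [(30.0, 5.0), (0.0, 0.0), (90.0, 10.0)])
    def test_hydrostatic_offset(self, theta, expected):
        assert hydrostatic_offset(theta) == pytest.approx(expected)

    @pytest.mark.parametrize("theta", [-1.0, 90.5])
    def test_hydrostatic_offset_range(self, theta):
        with pytest.raises(ValueError):
            hydrostatic_offset(theta)

    @pytest.mark.parametrize("p,expected", [(5.0, 3.678), (0.0, 0.0), (1.0, 0.7356)])
    def test_cmh2o_to_mmhg(self, p, expected):
        assert cmh2o_to_mmhg(p) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "h,theta,expected", [(10.0, 30.0, 3.678), (0.0, 45.0, 0.0), (1.0, 90.0, 0.7356)]
    )
    def test_jvp_conversion(self, h, theta, expected):
        assert jvp_to_mmhg(h, theta) == pytest.approx(expected)

    def test_negative_height_rejected(self):
        with pytest.raises(ValueError):
            jvp_to_mmhg(-1.0, 30.0)


class TestStudyFit:
    def test_cf_only_regression_coefficients(self, study_table):
        fit = fit_linear(study_table, ("CF",))
        assert fit.coefficients["CF"] == pytest.approx(1.05, abs=0.005)
        assert fit.intercept == pytest.approx(-0.053, abs=0.0005)
        assert fit.n == 11

    def test_cf_only_fit_metrics(self, study_table):
        fit = fit_linear(study_table, ("CF",))
        assert round(fit.r_squared, 2) == 0.82
        assert round(fit.mae, 2) == 1.08
        assert round(fit.sd_error, 2) == 1.24
        assert fit.p_values["CF"] == pytest.approx(1.3e-4, rel=0.05)

    def test_multilinear_fit(self, study_table):
        fit = fit_linear(study_table, ("CF", "HO_mmHg"))
        assert round(fit.r_squared, 2) == 0.83
        assert fit.p_values["HO_mmHg"] > 0.05  # hydrostatic term not significant

    def test_residuals_mean_zero(self, study_table):
        fit = fit_linear(study_table, ("CF", "HO_mmHg"))
        assert np.mean(fit.residuals) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("sid,expected", [(1, 10.14), (6, 2.28)])
    def test_predicted_cvp_matches_published_column(self, study_table, sid, expected):
        fit = fit_linear(study_table, ("CF",))
        assert predict(fit, study_table.subject(sid)) == pytest.approx(expected, abs=0.005)

    def test_zero_coefficient_fit_returns_intercept(self, study_table):
        from dataclasses import replace

        fit = fit_linear(study_table, ("CF",))
        flat = replace(fit, coefficients={"CF": 0.0})
        assert predict(flat, study_table.subject(1)) == pytest.approx(flat.intercept)

    def test_collinear_predictors_rejected(self, study_table):
        # HO and JVP collinear by construction in a 2-record table
        recs = [
            SubjectRecord(1, 4.0, Vein.LIJ, collapse_force=3.0, ho_cmh2o=2.0,
                          jvp_status=JvpStatus.MEASURED, jvp_mmhg=2.0),
            SubjectRecord(2, 5.0, Vein.LIJ, collapse_force=4.0, ho_cmh2o=2.0,
                          jvp_status=JvpStatus.MEASURED, jvp_mmhg=2.0),
            SubjectRecord(3, 6.0, Vein.LIJ, collapse_force=5.0, ho_cmh2o=2.0,
                          jvp_status=JvpStatus.MEASURED, jvp_mmhg=2.0),
            SubjectRecord(4, 7.0, Vein.LIJ, collapse_force=6.0, ho_cmh2o=2.0,
                          jvp_status=JvpStatus.MEASURED, jvp_mmhg=2.0),
        ]
        with pytest.raises(ValueError, match="singular"):
            fit_linear(StudyTable(recs), ("HO_mmHg", "JVP"))

    def test_insufficient_records(self):
        recs = [SubjectRecord(1, 4.0, Vein.LIJ, collapse_force=3.0)]
        with pytest.raises(ValueError, match="insufficient"):
            fit_linear(StudyTable(recs), ("CF",))

    def test_two_points_interpolate(self):
        recs = [
            SubjectRecord(1, 4.0, Vein.LIJ, collapse_force=3.0),
            SubjectRecord(2, 5.0, Vein.LIJ, collapse_force=4.0),
        ]
        fit = fit_linear(StudyTable(recs), ("CF",))
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.coefficients["CF"] == pytest.approx(1.0)

    def test_unknown_predictor(self, study_table):
        with pytest.raises(ValueError, match="unknown predictor"):
            fit_linear(study_table, ("CF", "AGE"))


class TestOlsOracle:
    def test_matches_normal_equations_on_random_tables(self):
        """OLS through the module surface agrees with a hand-rolled
        normal-equations solve on small random cohorts."""
        rng = np.random.default_rng(123)
        for _ in range(20):
            n = int(rng.integers(5, 13))
            cf = rng.uniform(1, 10, n)
            ho = rng.uniform(0, 8, n)
            y = 0.9 * cf + 0.2 * ho + rng.normal(0, 1, n)
            recs = [
                SubjectRecord(i + 1, float(y[i]), Vein.LIJ,
                              collapse_force=float(cf[i]), ho_cmh2o=float(ho[i]))
                for i in range(n)
            ]
            fit = fit_linear(StudyTable(recs), ("CF", "HO_mmHg"))
            X = np.column_stack([np.ones(n), cf, ho * 0.7356])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert fit.intercept == pytest.approx(beta[0], abs=1e-9)
            assert fit.coefficients["CF"] == pytest.approx(beta[1], abs=1e-9)
            assert fit.coefficients["HO_mmHg"] == pytest.approx(beta[2], abs=1e-9)


class TestTrainedModel:
    @pytest.mark.parametrize(
        "sid,expected,tol",
        [(6, 0.98, 0.02), (11, 3.55, 0.03)],
    )
    def test_published_cells_reproduced(self, study_table, sid, expected, tol):
        assert apply_trained_model(study_table.subject(sid)) == pytest.approx(expected, abs=tol)

    def test_zero_inputs_give_intercept(self):
        rec = SubjectRecord(1, 5.0, Vein.LIJ, collapse_force=1e-12, ho_cmh2o=0.0)
        assert apply_trained_model(rec) == pytest.approx(0.054)

    def test_missing_inputs_rejected(self):
        rec = SubjectRecord(1, 5.0, Vein.LIJ)
        with pytest.raises(ValueError, match="missing CF or HO"):
            apply_trained_model(rec)


class TestAgreementMetrics:
    def test_perfect_agreement(self):
        m = agreement_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m["r_squared"] == pytest.approx(1.0)
        assert m["mae"] == 0.0
        assert m["sd_error"] == 0.0

    def test_jvp_column_agreement(self, study_table):
        jvp = [r.jvp_mmhg for r in study_table if r.jvp_status is JvpStatus.MEASURED]
        cvp = [r.avg_invasive_cvp for r in study_table if r.jvp_status is JvpStatus.MEASURED]
        m = agreement_metrics(jvp, cvp)
        assert round(m["r_squared"], 2) == 0.45
        assert round(m["sd_error"], 2) == 1.88
        assert m["mae"] == pytest.approx(1.39, abs=0.01)

    def test_trained_model_column_agreement(self, study_table):
        pred = [r.trained_model_cvp for r in study_table]
        cvp = [r.avg_invasive_cvp for r in study_table]
        m = agreement_metrics(pred, cvp)
        assert round(m["mae"], 2) == 1.60
        assert round(m["r_squared"], 2) == 0.46
        assert round(m["sd_error"], 2) == 2.17

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            agreement_metrics([1.0], [1.0, 2.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            agreement_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
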