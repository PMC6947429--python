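"""Tests of recalibration, LOO internal-external CV and multibiomarker
calibration."""

import numpy as np
import pandas as pd
import pytest

from pkrrf.calibration import (MultibiomarkerCalibrator,
                               loo_internal_external_cv, recalibrate)
from pkrrf.evaluation import roc_auc
from pkrrf.rrf_models import fit_pkrrf


@pytest.fixture(scope="module")
def basic_model(small_cohort):
    return fit_pkrrf(small_cohort, "basic", "logistic")


@pytest.fixture(scope="module")
def continuous_model(small_cohort):
    return fit_pkrrf(small_cohort, "basic", "continuous")


def _logit(p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


class TestRecalibrate:
    def test_self_calibration_is_near_identity(self, basic_model,
                                               validation_fixture):
        """Outcomes simulated from the model's own predictive distribution
        recalibrate to intercept ~0, slope ~1."""
        rng = np.random.default_rng(0)
        fx = validation_fixture.copy()
        p = basic_model.predict(fx)
        y = (rng.random(len(fx)) < p).astype(float)
        # encode the simulated outcome through the urea-clearance column
        fx["urcl_measured"] = np.where(y == 1, 5.0, 0.5)
        cal = recalibrate(basic_model, fx, "linear")
        # SE of the slope in a logistic fit at n~120 is roughly 0.2
        assert cal.intercept == pytest.approx(0.0, abs=0.6)
        assert cal.slope == pytest.approx(1.0, abs=0.5)

    def test_injected_logit_offset_recovered(self, basic_model,
                                             validation_fixture):
        rng = np.random.default_rng(1)
        fx = validation_fixture.copy()
        p = basic_model.predict(fx)
        p_shift = 1 / (1 + np.exp(-(_logit(p) + 0.9)))
        y = (rng.random(len(fx)) < p_shift).astype(float)
        fx["urcl_measured"] = np.where(y == 1, 5.0, 0.5)
        cal = recalibrate(basic_model, fx, "intercept")
        assert cal.intercept == pytest.approx(0.9, abs=0.6)
        assert cal.slope == 1.0

    def test_linear_recalibration_preserves_auc(self, basic_model,
                                                validation_fixture):
        fx = validation_fixture
        y = (fx.urcl_measured >= 2.0).astype(int)
        before = roc_auc(basic_model.predict(fx), y)
        cal = recalibrate(basic_model, fx, "linear")
        after = roc_auc(cal.predict(fx), y)
        assert after == pytest.approx(before, abs=1e-12)

    def test_continuous_intercept_update_fixes_mean_bias(self,
                                                         continuous_model,
                                                         validation_fixture):
        fx = validation_fixture
        cal = recalibrate(continuous_model, fx, "intercept")
        resid = (cal.intercept
                 + continuous_model.predict(fx, scale="urcl")
                 - fx.urcl_measured.to_numpy())
        assert resid.mean() == pytest.approx(0.0, abs=1e-10)

    def test_too_few_rows_error(self, basic_model, validation_fixture):
        with pytest.raises(ValueError, match="10 validation rows"):
            recalibrate(basic_model, validation_fixture.iloc[:5])


class TestLooCv:
    def test_equals_brute_force_refit_loop(self, basic_model,
                                           validation_fixture):
        """The LOO driver must match an explicit n-refit loop exactly."""
        fx = validation_fixture.iloc[:30].reset_index(drop=True)
        loo = loo_internal_external_cv(basic_model, fx, "linear")
        for i in range(len(fx)):
            rest = fx.drop(index=i)
            cal = recalibrate(basic_model, rest, "linear")
            expected = cal.predict(fx.iloc[[i]])[0]
            assert loo["predictions"][i] == pytest.approx(expected, abs=1e-10)

    def test_left_out_record_does_not_see_its_own_outcome(self, basic_model,
                                                          validation_fixture):
        fx = validation_fixture.iloc[:40].reset_index(drop=True)
        base = loo_internal_external_cv(basic_model, fx, "linear")
        perturbed = fx.copy()
        # flip record 7's outcome across the clearance cutoff
        perturbed.loc[7, "urcl_measured"] = (
            0.2 if fx.loc[7, "urcl_measured"] >= 2.0 else 6.0)
        new = loo_internal_external_cv(basic_model, perturbed, "linear")
        assert new["predictions"][7] == pytest.approx(base["predictions"][7])
        assert not np.allclose(np.delete(new["predictions"], 7),
                               np.delete(base["predictions"], 7))

    def test_strong_signal_fixture_has_high_oof_auc(self, basic_model,
                                                    validation_fixture):
        loo = loo_internal_external_cv(basic_model, validation_fixture,
                                       "linear")
        assert len(loo["predictions"]) == len(validation_fixture)
        assert loo["auc"] > 0.8

    def test_too_few_rows_error(self, basic_model, validation_fixture):
        with pytest.raises(ValueError, match="20 validation rows"):
            loo_internal_external_cv(basic_model, validation_fixture.iloc[:15])


class TestMultibiomarker:
    def test_unsupported_biomarker_rejected(self, basic_model):
        with pytest.raises(ValueError, match="troponin"):
            MultibiomarkerCalibrator(basic_model, ("troponin",))

    def test_missing_biomarker_column_reported(self, basic_model,
                                               validation_fixture):
        cal = MultibiomarkerCalibrator(basic_model, ("cystatin_c",))
        with pytest.raises(ValueError, match="cystatin_c"):
            cal.fit(validation_fixture.drop(columns=["cystatin_c"]))

    def test_zero_amplitude_reduces_to_linear_recalibration(
            self, basic_model, validation_fixture):
        fx = validation_fixture
        lin = recalibrate(basic_model, fx, "linear")
        mb = MultibiomarkerCalibrator(basic_model, ("cystatin_c",),
                                      amplitude=0.0).fit(fx)
        assert np.allclose(mb.predict(fx), lin.predict(fx))

    def test_planted_cystatin_signal_improves_cv_auc(self, basic_model,
                                                     validation_fixture):
        """Cystatin C carries residual RRF information in the fixture, so
        the GP calibration must beat plain linear recalibration."""
        fx = validation_fixture
        lin = loo_internal_external_cv(basic_model, fx, "linear")
        mb = MultibiomarkerCalibrator(basic_model, ("cystatin_c",)).fit(fx)
        cv = mb.loo_cv(fx)
        assert cv["auc"] >= lin["auc"] + 0.02

    def test_pure_noise_biomarker_changes_little(self, basic_model,
                                                 validation_fixture):
        rng = np.random.default_rng(0)
        fx = validation_fixture.copy()
        fx["urea"] = rng.normal(100.0, 15.0, len(fx))  # no RRF signal
        lin = loo_internal_external_cv(basic_model, fx, "linear")
        mb = MultibiomarkerCalibrator(basic_model, ("urea",)).fit(fx)
        cv = mb.loo_cv(fx)
        assert abs(cv["auc"] - lin["auc"]) < 0.03

    @pytest.mark.parametrize("combo", [
        (), ("creatinine",), ("urea",), ("cystatin_c",),
        ("cystatin_c", "urea"), ("creatinine", "urea"),
        ("cystatin_c", "creatinine"), ("cystatin_c", "creatinine", "urea")])
    def test_all_biomarker_combinations_supported(self, combo, basic_model,
                                                  validation_fixture):
        fx = validation_fixture.iloc[:60]
        if not combo:
            cal = recalibrate(basic_model, fx, "linear")
        else:
            cal = MultibiomarkerCalibrator(basic_model, combo).fit(fx)
        p = cal.predict(fx)
        assert np.all((p >= 0) & (p <= 1))
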