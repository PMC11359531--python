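import numpy as np
import pytest

from ivivckit.ivivc import (IVIVCCorrelation, predict_plasma,
                            prediction_error, select_ivivc, validate)
from ivivckit.pk import UnitImpulseResponse, nca

from .conftest import PK_GRID_MIN, make_dissolution

H = 1.0 / 60.0

DISS = make_dissolution("hill", finf=0.79, mdt=1.07, b=2.93)
UIR = UnitImpulseResponse.from_params([(0.36, 0.48 * H), (0.076, 0.015 * H)])


class TestCorrelationFitting:
    def test_identity_mapping_recovered_by_simplest_form(self):
        y = DISS.predict_minutes(PK_GRID_MIN)
        m = IVIVCCorrelation("F1", dissolution_model=DISS).fit(PK_GRID_MIN, y)
        assert m.abs_scale_ == pytest.approx(1.0, rel=1e-6)
        assert m.r_adj_ == pytest.approx(1.0, abs=1e-6)
        assert (m.t_scale_, m.t_shift_, m.abs_base_) == (1.0, 0.0, 0.0)

    def test_time_scaled_form_recovers_both_parameters(self):
        y = 1.30 * DISS.predict_minutes(1.11 * PK_GRID_MIN)
        m = IVIVCCorrelation("F2", dissolution_model=DISS).fit(PK_GRID_MIN, y)
        assert m.abs_scale_ == pytest.approx(1.30, rel=1e-3)
        assert m.t_scale_ == pytest.approx(1.11, rel=1e-3)

    def test_baseline_form_absorbs_offset(self):
        y = 1.2 * (DISS.predict_minutes(PK_GRID_MIN) - 0.05)
        m4 = IVIVCCorrelation("F4", dissolution_model=DISS).fit(PK_GRID_MIN, y)
        m1 = IVIVCCorrelation("F1", dissolution_model=DISS).fit(PK_GRID_MIN, y)
        assert m4.abs_base_ == pytest.approx(0.05, abs=1e-3)
        assert m1.rss_ > m4.rss_ * 10

    def test_nested_forms_rss_monotone(self):
        # shifted, scaled, offset data: each added parameter can only help
        t = PK_GRID_MIN
        y = 1.4 * (DISS.predict_minutes(1.2 * t - 18.0) - 0.02)
        rss = []
        for form in ("F1", "F2", "F3", "F4"):
            m = IVIVCCorrelation(form, dissolution_model=DISS).fit(t, y)
            rss.append(m.rss_)
        for lo, hi in zip(rss[1:], rss[:-1]):
            assert lo <= hi * (1 + 1e-9)

    def test_negative_argument_evaluates_to_zero(self):
        m = IVIVCCorrelation("F3", dissolution_model=DISS)
        m.abs_scale_, m.t_scale_, m.t_shift_, m.abs_base_ = 1.0, 1.0, 120.0, 0.0
        assert np.all(m.predict([0.0, 60.0, 119.0]) == 0.0)
        assert m.predict([240.0])[0] > 0

    def test_selection_prefers_higher_adjusted_r(self):
        t = PK_GRID_MIN
        y = 1.30 * DISS.predict_minutes(1.11 * t)
        fits = [IVIVCCorrelation(f, dissolution_model=DISS).fit(t, y)
                for f in ("F1", "F2")]
        assert select_ivivc(fits).form == "F2"


class TestPredictionError:
    @pytest.mark.parametrize("pred, obs, expected", [
        (3754.39, 3268.72, 14.86),    # external validation, AUC
        (3725.00, 3596.97, 3.56),
        (2143.49, 2060.36, 4.03),
        (3033.97, 6096.27, -50.23),   # inter-brand comparison
        (8763.84, 6096.27, 43.76),
        (33.82, 34.62, -2.31),
    ])
    def test_reference_pairs(self, pred, obs, expected):
        assert round(prediction_error(pred, obs), 2) == pytest.approx(
            expected, abs=0.005)

    def test_exact_prediction_is_zero(self):
        assert prediction_error(5.0, 5.0) == 0.0

    def test_zero_observed_rejected(self):
        with pytest.raises(ValueError):
            prediction_error(1.0, 0.0)


class TestPrediction:
    def _model(self, abs_scale=1.0 / 0.79):
        m = IVIVCCorrelation("F1", dissolution_model=DISS)
        m.abs_scale_, m.t_scale_, m.t_shift_, m.abs_base_ = \
            abs_scale, 1.0, 0.0, 0.0
        return m

    def test_zero_dose_gives_zero_profile(self):
        prof = predict_plasma(self._model(), UIR, 0.0, 0.5, t_end=720)
        assert np.all(prof.values == 0.0)

    def test_linearity_in_dose(self):
        p1 = predict_plasma(self._model(), UIR, 100.0, 0.5, t_end=720)
        p2 = predict_plasma(self._model(), UIR, 200.0, 0.5, t_end=720)
        np.testing.assert_allclose(p2.values, 2 * p1.values, rtol=1e-12)

    def test_mass_balance_when_input_completes(self):
        # absorbed fraction reaches 1, so AUC = dose * f * sum(A/alpha)
        prof = predict_plasma(self._model(), UIR, 100.0, 0.5,
                              t_end=80000.0, grid_step=5.0)
        auc = np.trapezoid(prof.values, prof.times)
        assert auc == pytest.approx(100.0 * 0.5 * UIR.auc_inf(), rel=5e-3)

    def test_internal_validation_round_trip(self):
        # data generated by the model itself must validate (near) exactly
        model = self._model()
        dose, f = 1000.0, 0.3
        prof = predict_plasma(model, UIR, dose, f, t_end=1440.0)
        observed = nca(prof, dose=dose)
        report = validate(model, UIR, observed, dose, f)
        assert report.verdict
        assert all(abs(v) < 1.0 for v in report.pe_pct.values())

    def test_threshold_is_inclusive(self):
        model = self._model()
        dose, f = 1000.0, 0.3
        prof = predict_plasma(model, UIR, dose, f, t_end=1440.0)
        idx = np.searchsorted(prof.times, PK_GRID_MIN)
        observed = nca(type(prof)(PK_GRID_MIN, prof.values[idx]), dose=dose)
        report = validate(model, UIR, observed, dose, f)
        worst = max(abs(v) for v in report.pe_pct.values())
        at_bound = validate(model, UIR, observed, dose, f, threshold=worst)
        assert at_bound.verdict  # |PE| == threshold still passes
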