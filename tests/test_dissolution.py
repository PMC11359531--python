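import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ivivckit.core import TimeProfile
from ivivckit.dissolution import (DissolutionModel, cumulative_dissolution,
                                  evaluate_model, fit_dissolution_model,
                                  hill, makoid_banakar,
                                  select_dissolution_model, weibull)

from .conftest import DISS_GRID_MIN, make_dissolution


class TestCumulativeDissolution:
    def test_single_point_no_replacement(self):
        prof = cumulative_dissolution([15.0], [0.1], 900.0, 0.0, 100.0)
        assert prof.values[0] == pytest.approx(0.90)

    def test_zero_sample_volume_is_plain_ratio(self):
        c = np.array([0.01, 0.02, 0.03])
        prof = cumulative_dissolution([15, 30, 45], c, 900.0, 0.0, 50.0)
        np.testing.assert_allclose(prof.values, c * 900.0 / 50.0)

    def test_replacement_correction_hand_expanded(self):
        # constant concentration c over 3 samples:
        # D3 = (c*V1 + V2*(c + c)) / M
        c, v1, v2, m = 0.05, 900.0, 3.0, 60.0
        prof = cumulative_dissolution([15, 30, 45], [c, c, c], v1, v2, m)
        assert prof.values[2] == pytest.approx((c * v1 + 2 * v2 * c) / m)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            cumulative_dissolution([15, 30], [0.1, -0.1], 900, 3, 100)

    def test_overshoot_warns(self):
        with pytest.warns(UserWarning):
            cumulative_dissolution([15.0], [0.2], 900.0, 0.0, 100.0)

    @given(st.lists(st.floats(0, 0.01), min_size=2, max_size=9))
    def test_non_decreasing_for_nonnegative_concs(self, concs):
        # the replacement term makes cumulative dissolution monotone even
        # when sampled concentrations dip
        times = np.arange(1, len(concs) + 1) * 15.0
        prof = cumulative_dissolution(times, np.sort(concs), 900.0, 3.0,
                                      20.0)
        assert np.all(np.diff(prof.values) >= -1e-12)


class TestModelShapes:
    def test_hill_half_maximum_at_mdt(self):
        assert hill(1.7, 0.8, 1.7, 2.5) == pytest.approx(0.4)

    def test_makoid_banakar_plateau(self):
        assert makoid_banakar(2.0, 0.75, 2.0, 3.1) == pytest.approx(0.75)
        assert makoid_banakar(5.0, 0.75, 2.0, 3.1) == pytest.approx(0.75)

    @pytest.mark.parametrize("model, params", [
        ("hill", {"finf": 0.8, "mdt": 1.2, "b": 2.0}),
        ("weibull", {"finf": 0.8, "mdt": 1.2, "b": 2.0, "tlag": 0.3}),
        ("makoid_banakar", {"fmax": 0.8, "tmax": 1.5, "b": 2.0}),
    ])
    def test_zero_at_origin_and_bounded_by_plateau(self, model, params):
        t = np.linspace(0, 12, 400)
        y = evaluate_model(model, t, params)
        assert y[0] == 0.0
        assert np.all(y <= 0.8 + 1e-12)
        assert np.all(y >= 0.0)


class TestFitting:
    @pytest.mark.parametrize("model, truth", [
        ("weibull", {"finf": 0.70, "mdt": 1.10, "b": 2.06}),
        ("hill", {"finf": 0.78, "mdt": 1.10, "b": 2.71}),
        ("makoid_banakar", {"fmax": 0.75, "tmax": 2.2, "b": 1.6}),
    ])
    def test_noise_free_parameter_recovery(self, model, truth):
        gen = make_dissolution(model, **truth)
        t_h = DISS_GRID_MIN / 60.0
        fit = DissolutionModel(model).fit(t_h, gen.predict(t_h))
        for name, val in truth.items():
            assert fit.params_[name] == pytest.approx(val, rel=1e-4)
        assert fit.r_ > 0.999999

    def test_finf_fixed_constrains_plateau(self):
        t_h = DISS_GRID_MIN / 60.0
        y = weibull(t_h, 1.0, 1.5, 1.8)
        fit = DissolutionModel("weibull", finf_fixed=True).fit(t_h, y)
        assert fit.params_["finf"] == 1.0
        assert fit.params_["mdt"] == pytest.approx(1.5, rel=1e-4)

    def test_profile_wrapper_honours_time_unit(self):
        prof = TimeProfile(DISS_GRID_MIN,
                           hill(DISS_GRID_MIN / 60.0, 0.8, 1.2, 2.4),
                           kind="fraction")
        fit = fit_dissolution_model(prof, "hill")
        assert fit.params_["mdt"] == pytest.approx(1.2, rel=1e-4)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            DissolutionModel("hill").fit([0.5, 1.0, 2.0], [0.1, 0.3, 0.5])


class TestSelection:
    def _fake(self, r, aic):
        m = make_dissolution("hill", finf=1, mdt=1, b=1)
        m.r_, m.aic_ = r, aic
        return m

    def test_highest_r_wins(self):
        a, b = self._fake(0.9909, -25.65), self._fake(0.9981, -39.54)
        assert select_dissolution_model([a, b]) is b

    def test_single_candidate_returned(self):
        a = self._fake(0.99, -10)
        assert select_dissolution_model([a]) is a

    def test_tie_broken_by_aic(self):
        a, b = self._fake(0.995, -25.0), self._fake(0.995, -40.0)
        assert select_dissolution_model([a, b]) is b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_dissolution_model([])
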