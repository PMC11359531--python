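import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ivivckit.core import TimeProfile, trapezoid_auc
from ivivckit.integration import (integrate_concentrations,
                                  integrate_dissolution, weight_coefficients)

from .conftest import DISS_GRID_MIN, make_dissolution

#: per-tablet contents (mg) of the five-component reference formulation
CONTENTS = {"protopine": 0.1742, "alpha-allocryptopine": 1.1042,
            "byakangelicin": 0.0975, "tetrahydropalmatine": 0.3017,
            "corydaline": 0.2871}


class TestWeights:
    def test_reference_contents(self):
        w = weight_coefficients(CONTENTS)
        assert w["protopine"] == pytest.approx(0.1742 / 1.9647, rel=1e-6)
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)

    def test_single_component_weight_is_one(self):
        assert weight_coefficients({"x": 3.7}) == {"x": 1.0}

    def test_equal_contents_give_equal_weights(self):
        w = weight_coefficients({f"c{i}": 2.0 for i in range(5)})
        assert all(v == pytest.approx(0.2) for v in w.values())

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            weight_coefficients({})

    @given(st.dictionaries(st.text("abc", min_size=1, max_size=3),
                           st.floats(1e-3, 1e3), min_size=1, max_size=8))
    def test_weights_always_sum_to_one(self, contents):
        assert sum(weight_coefficients(contents).values()) == pytest.approx(
            1.0, abs=1e-12)


def _const(value):
    return TimeProfile(DISS_GRID_MIN, np.full(DISS_GRID_MIN.size, value),
                       kind="fraction")


class TestIntegrateDissolution:
    def test_identical_profiles_unchanged(self):
        p = _const(0.5)
        out = integrate_dissolution({"a": p, "b": p}, {"a": 0.4, "b": 0.6})
        np.testing.assert_allclose(out.profile.values, p.values)

    def test_two_constants(self):
        out = integrate_dissolution({"a": _const(0.0), "b": _const(1.0)},
                                    {"a": 0.3, "b": 0.7})
        np.testing.assert_allclose(out.profile.values, 0.7)

    def test_plateau_combines_linearly(self):
        # five sigmoid release curves: the integrated plateau is the
        # weight-combined plateau of the members
        models = {
            "tetrahydropalmatine": make_dissolution("hill", finf=0.79,
                                                    mdt=1.07, b=2.93),
            "corydaline": make_dissolution("weibull", finf=0.71, mdt=1.23,
                                           b=2.04, tlag=0.0),
            "protopine": make_dissolution("hill", finf=0.78, mdt=1.10,
                                          b=2.71),
            "alpha-allocryptopine": make_dissolution("weibull", finf=0.86,
                                                     mdt=1.26, b=1.97,
                                                     tlag=0.0),
            "byakangelicin": make_dissolution("hill", finf=0.35, mdt=1.12,
                                              b=2.79),
        }
        weights = weight_coefficients(CONTENTS)
        t_late = np.array([1e5, 2e5])  # effectively infinite time, minutes
        profiles = {n: TimeProfile(t_late, m.predict_minutes(t_late),
                                   kind="fraction")
                    for n, m in models.items()}
        out = integrate_dissolution(profiles, weights)
        expected = sum(weights[n] * m.plateau_ for n, m in models.items())
        assert out.profile.values[-1] == pytest.approx(expected, rel=1e-3)

    def test_convex_bound(self):
        lo, hi = _const(0.2), _const(0.8)
        out = integrate_dissolution({"a": lo, "b": hi},
                                    {"a": 0.25, "b": 0.75})
        assert np.all(out.profile.values >= lo.values - 1e-12)
        assert np.all(out.profile.values <= hi.values + 1e-12)

    def test_grid_mismatch_names_offender(self):
        other = TimeProfile(DISS_GRID_MIN[:-1], np.zeros(8), kind="fraction")
        with pytest.raises(ValueError, match="b"):
            integrate_dissolution({"a": _const(0.1), "b": other},
                                  {"a": 0.5, "b": 0.5})

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            integrate_dissolution({"a": _const(0.1)}, {"a": 0.9})


class TestIntegrateConcentrations:
    def _conc(self, scale):
        t = np.array([15, 60, 240, 720], float)
        return TimeProfile(t, scale * np.exp(-0.003 * t))

    def test_equal_profiles_double(self):
        p = self._conc(10.0)
        out = integrate_concentrations({"a": p, "b": p})
        np.testing.assert_allclose(out.values, 2 * p.values)

    def test_zero_member_is_identity(self):
        p = self._conc(10.0)
        z = TimeProfile(p.times, np.zeros_like(p.values))
        out = integrate_concentrations({"a": p, "b": z})
        np.testing.assert_allclose(out.values, p.values)

    def test_auc_additive(self):
        a, b = self._conc(10.0), self._conc(3.0)
        total = integrate_concentrations({"a": a, "b": b})
        assert trapezoid_auc(total) == pytest.approx(
            trapezoid_auc(a) + trapezoid_auc(b), rel=1e-12)
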