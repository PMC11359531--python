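"""Cumulative dissolution and dissolution-kinetics model fitting.

Cumulative dissolution corrects sampled concentrations for the medium
withdrawn and replaced at each sampling time:

    D_n = (C_n * V1 + V2 * sum_{i=1..n-1} C_i) / M

with V1 the vessel volume, V2 the sample volume and M the total drug content.

Three empirical release models are supported, parameterised in hours:

    Hill            F(t) = Finf * t^b / (MDT^b + t^b)
    Weibull         F(t) = Finf * (1 - exp[-((t - tlag)/MDT)^b])
    Makoid-Banakar  F(t) = Fmax * (t/Tmax)^b * exp[b*(1 - t/Tmax)]  (t <= Tmax)
                    F(t) = Fmax                                      (t >  Tmax)

Model selection follows the highest correlation coefficient, ties broken by
the smaller AIC (least-squares form n*ln(SSR/n) + 2k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .core import (FRACTION_OVERSHOOT_TOL, MediumSpec, TimeProfile,
                   convert_time_units)

MODEL_FAMILIES = ("hill", "weibull", "makoid_banakar")

#: standard sampling grid (minutes); HCl runs truncate at 180 min
STANDARD_GRID_MIN = (15, 30, 45, 60, 90, 120, 180, 240, 360)

#: correlation-coefficient tie tolerance for model selection
R_TIE_TOL = 1e-4


def cumulative_dissolution(times_min, concs, v1: float, v2: float,
                           m: float, label: str = "") -> TimeProfile:
    """Cumulative dissolved fraction from sampled concentrations.

    times_min: sampling times (minutes); concs: concentrations (mg/mL) at
    those times; v1: medium volume (mL); v2: sample volume replaced (mL);
    m: total drug content (mg). Returns a fraction-kind profile (the x100%
    of the reported percentage is applied only at report time).
    """
    c = np.asarray(concs, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative concentration in dissolution samples")
    if m <= 0:
        raise ValueError("drug content m must be positive")
    if v2 < 0 or v1 <= 0:
        raise ValueError("require v1 > 0 and v2 >= 0")
    removed = v2 * np.concatenate(([0.0], np.cumsum(c)[:-1]))
    frac = (c * v1 + removed) / m
    if np.any(frac > FRACTION_OVERSHOOT_TOL):
        warnings.warn(f"cumulative dissolution exceeds {FRACTION_OVERSHOOT_TOL}; "
                      "check content or assay", stacklevel=2)
    return TimeProfile(times_min, frac, kind="fraction", label=label)


# ---------------------------------------------------------------------------
# model families (t in hours)

def hill(t, finf, mdt, b):
    t = np.asarray(t, dtype=float)
    tp = np.clip(t, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = finf * tp**b / (mdt**b + tp**b)
    return np.where(t > 0, out, 0.0)


def weibull(t, finf, mdt, b, tlag=0.0):
    t = np.asarray(t, dtype=float)
    s = np.clip(t - tlag, 0.0, None)
    return finf * (1.0 - np.exp(-((s / mdt) ** b)))


def makoid_banakar(t, fmax, tmax, b):
    t = np.asarray(t, dtype=float)
    tp = np.clip(t, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        rising = fmax * (tp / tmax) ** b * np.exp(b * (1.0 - tp / tmax))
    out = np.where(tp > tmax, fmax, np.where(t > 0, rising, 0.0))
    return out


_EVALUATORS = {
    "hill": lambda t, p: hill(t, p["finf"], p["mdt"], p["b"]),
    "weibull": lambda t, p: weibull(t, p["finf"], p["mdt"], p["b"],
                                    p.get("tlag", 0.0)),
    "makoid_banakar": lambda t, p: makoid_banakar(t, p["fmax"], p["tmax"],
                                                  p["b"]),
}


def evaluate_model(model: str, t_hours, params: dict) -> np.ndarray:
    """Evaluate a named model family at t (hours) with a parameter dict."""
    if model not in MODEL_FAMILIES:
        raise ValueError(f"unknown dissolution model {model!r}")
    return _EVALUATORS[model](t_hours, params)


class FitError(RuntimeError):
    """Fit failed to converge; carries the best-so-far parameters."""

    def __init__(self, msg, best_params=None, residual_norm=None):
        super().__init__(msg)
        self.best_params = best_params
        self.residual_norm = residual_norm


def _as_1d_times(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 0:
        X = X[None]
    elif X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError("times must be a 1-D array or a single-column matrix")
    return X


def _quantile_times(t, y):
    """Times at which y first reaches 25/50/75% of its maximum."""
    ymax = float(np.max(y))
    if ymax <= 0:
        return [float(np.median(t))] * 3
    ymono = np.maximum.accumulate(y)
    return [float(np.interp(q * ymax, ymono, t)) for q in (0.25, 0.5, 0.75)]


def aic_least_squares(n: int, ssr: float, k: int) -> float:
    """AIC for an unweighted least-squares fit: n*ln(SSR/n) + 2k."""
    return float(n * np.log(max(ssr, 1e-300) / n) + 2 * k)


def sbc_least_squares(n: int, ssr: float, k: int) -> float:
    """Schwarz Bayes criterion for a least-squares fit: n*ln(SSR/n) + k*ln(n)."""
    return float(n * np.log(max(ssr, 1e-300) / n) + k * np.log(n))


def correlation_coefficient(observed, fitted, method: str = "pearson") -> float:
    """Goodness-of-fit R: Pearson of fitted vs observed (default) or
    sqrt(1 - SSR/SST)."""
    observed = np.asarray(observed, float)
    fitted = np.asarray(fitted, float)
    if method == "pearson":
        if np.std(fitted) == 0 or np.std(observed) == 0:
            return 0.0
        return float(np.corrcoef(observed, fitted)[0, 1])
    if method == "rsq":
        sst = float(np.sum((observed - observed.mean()) ** 2))
        ssr = float(np.sum((observed - fitted) ** 2))
        return float(np.sqrt(max(0.0, 1.0 - ssr / sst))) if sst > 0 else 0.0
    raise ValueError(f"unknown correlation method {method!r}")


class DissolutionModel(BaseEstimator, RegressorMixin):
    """Least-squares fit of a dissolution-kinetics model.

    Parameters
    ----------
    model : {'hill', 'weibull', 'makoid_banakar'}
    finf_fixed : bool
        Fix the plateau at 1 instead of estimating it. Estimation is the
        default: observed tablet release commonly plateaus well below 100%.
    fit_tlag : bool
        Estimate a Weibull lag time (otherwise fixed at 0). Ignored for the
        other families (the Hill form has no lag; Makoid-Banakar peaks at
        Tmax by construction).
    r_method : {'pearson', 'rsq'}
        Definition of the reported correlation coefficient.

    Fitted attributes: ``params_`` (dict), ``r_``, ``aic_``, ``n_obs_``,
    ``ssr_``. Times are in hours throughout.
    """

    def __init__(self, model: str = "weibull", finf_fixed: bool = False,
                 fit_tlag: bool = False, r_method: str = "pearson"):
        self.model = model
        self.finf_fixed = finf_fixed
        self.fit_tlag = fit_tlag
        self.r_method = r_method

    # -- parameter scaffolding -------------------------------------------
    def _make_params(self, mdt0, b0, plateau0, tmax_hi):
        p = lmfit.Parameters()
        if self.model in ("hill", "weibull"):
            p.add("finf", value=1.0 if self.finf_fixed else plateau0,
                  min=1e-6, max=1.2, vary=not self.finf_fixed)
            p.add("mdt", value=mdt0, min=1e-4, max=1e3)
            p.add("b", value=b0, min=0.05, max=25.0)
            if self.model == "weibull":
                p.add("tlag", value=0.0, min=0.0, max=tmax_hi,
                      vary=self.fit_tlag)
        else:
            p.add("fmax", value=plateau0, min=1e-6, max=1.2)
            p.add("tmax", value=mdt0, min=1e-4, max=10 * tmax_hi)
            p.add("b", value=b0, min=0.05, max=25.0)
        return p

    def fit(self, X, y):
        """Fit to (times in hours, dissolved fraction)."""
        if self.model not in MODEL_FAMILIES:
            raise ValueError(f"unknown dissolution model {self.model!r}")
        t = _as_1d_times(X)
        y = np.asarray(y, dtype=float)
        if t.size < 4:
            raise ValueError("need at least 4 points to fit a dissolution model")
        plateau0 = float(np.clip(np.max(y), 1e-3, 1.2))
        tmax_hi = float(np.max(t))
        evaluator = _EVALUATORS[self.model]

        def residual(params):
            pd_ = params.valuesdict()
            return evaluator(t, pd_) - y

        best = None
        for mdt0 in _quantile_times(t, y):
            for b0 in (0.5, 1.0, 2.0, 4.0):
                params = self._make_params(max(mdt0, 1e-3), b0, plateau0,
                                           tmax_hi)
                try:
                    res = lmfit.minimize(residual, params, method="leastsq")
                except Exception:  # singular start; try next
                    continue
                ssr = float(np.sum(res.residual**2))
                if best is None or ssr < best[0] - 1e-15:
                    best = (ssr, res)
        if best is None:
            raise FitError(f"{self.model} fit failed from every start")
        ssr, res = best
        if not res.success and ssr > 1e-6 * max(1.0, float(np.sum(y**2))):
            raise FitError(f"{self.model} fit did not converge",
                           best_params=res.params.valuesdict(),
                           residual_norm=np.sqrt(ssr))
        self.params_ = dict(res.params.valuesdict())
        self.n_obs_ = int(t.size)
        self.ssr_ = ssr
        k = int(res.nvarys)
        self.aic_ = aic_least_squares(self.n_obs_, ssr, k)
        fitted = evaluator(t, self.params_)
        self.r_ = correlation_coefficient(y, fitted, self.r_method)
        return self

    def predict(self, X) -> np.ndarray:
        """Evaluate the fitted model at times in hours (0 for t <= 0)."""
        t = _as_1d_times(X)
        return _EVALUATORS[self.model](t, self.params_)

    def predict_minutes(self, t_min) -> np.ndarray:
        """Evaluate at times in minutes (internal canonical unit)."""
        return self.predict(np.asarray(t_min, dtype=float) / 60.0)

    @property
    def plateau_(self) -> float:
        """Asymptotic (Hill/Weibull) or maximum (Makoid-Banakar) fraction."""
        return self.params_.get("finf", self.params_.get("fmax"))


def fit_dissolution_model(profile: TimeProfile, model: str = "weibull",
                          finf_fixed: bool = False,
                          fit_tlag: bool = False) -> DissolutionModel:
    """Fit one model family to a cumulative-dissolution profile.

    The profile's time unit is honoured; parameters are reported in hours.
    """
    prof_h = convert_time_units(profile, "hours")
    return DissolutionModel(model=model, finf_fixed=finf_fixed,
                            fit_tlag=fit_tlag).fit(prof_h.times, prof_h.values)


def select_dissolution_model(fits) -> DissolutionModel:
    """Pick the winner by highest R; ties (|dR| < 1e-4) by smaller AIC."""
    fits = list(fits)
    if not fits:
        raise ValueError("no candidate fits to select from")
    r_best = max(f.r_ for f in fits)
    contenders = [f for f in fits if abs(f.r_ - r_best) < R_TIE_TOL]
    return min(contenders, key=lambda f: f.aic_)


@dataclass
class DissolutionRun:
    """One dissolution experiment: n parallel vessels in one medium."""

    medium: MediumSpec
    component: str
    vessels: list = field(default_factory=list)  # per-vessel fraction profiles
    mean_profile: TimeProfile | None = None

    def __post_init__(self) -> None:
        if self.vessels:
            grid = self.vessels[0].times
            for v in self.vessels[1:]:
                if not np.array_equal(v.times, grid):
                    raise ValueError("all vessels must share the sampling grid")
            if self.mean_profile is None:
                mean = np.mean([v.values for v in self.vessels], axis=0)
                self.mean_profile = TimeProfile(
                    grid, mean, kind="fraction",
                    label=f"{self.component} mean ({self.medium.name})")
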