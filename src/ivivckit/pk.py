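"""Non-compartmental analysis and unit-impulse-response (UIR) estimation.

NCA is model-free: Cmax/Tmax read off the observed points, AUC by linear
trapezoid, terminal slope lambda_z by log-linear regression over the
best-adjusted-R^2 terminal window, t1/2 = ln2/lambda_z. Absolute
bioavailability is the dose-corrected AUC(0-t) ratio of the oral and IV
routes.

The UIR is the dose-normalised disposition kernel estimated from an IV
reference profile as a polyexponential with optional lag,

    UIR(t) = sum_i A_i * exp(-alpha_i * (t - tlag)),  t >= tlag  (else 0),

fitted by weighted least squares. Candidate weightings (uniform, 1/Y, 1/Y^2
and the iteratively-reweighted 1/Yhat, 1/Yhat^2) are scanned and the winner
chosen by AIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import lmfit
import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .core import TimeProfile
from .dissolution import (_as_1d_times, aic_least_squares,
                          correlation_coefficient, sbc_least_squares)

WEIGHTING_SCHEMES = ("1", "1/Y", "1/Y2", "1/Yhat", "1/Yhat2")

#: alphas closer than this (1/min) are treated as collapsed to one term
ALPHA_COLLAPSE_TOL = 1e-6


@dataclass(frozen=True)
class NCAResult:
    """Model-free PK summary of one concentration-time profile."""

    cmax: float
    tmax: float
    auc_0_t: float
    auc_0_inf: float  # nan when lambda_z is not estimable
    t_half: float
    lambda_z: float
    n_lambda_points: int
    dose: float = float("nan")
    route: str = ""


def _lambda_z(times, concs):
    """Terminal log-linear slope: best adjusted R^2 over >=3-point windows
    after (and excluding) Cmax. Returns (lambda_z, n_points) or (nan, 0)."""
    i_max = int(np.argmax(concs))
    t_tail = times[i_max + 1:]
    c_tail = concs[i_max + 1:]
    pos = c_tail > 0
    t_tail, c_tail = t_tail[pos], c_tail[pos]
    n = t_tail.size
    best = (np.nan, 0, -np.inf)
    for k in range(3, n + 1):
        t_w, c_w = t_tail[-k:], np.log(c_tail[-k:])
        slope, intercept = np.polyfit(t_w, c_w, 1)
        if slope >= 0:
            continue
        fitted = slope * t_w + intercept
        sst = np.sum((c_w - c_w.mean()) ** 2)
        if sst <= 0:
            continue
        r2 = 1.0 - np.sum((c_w - fitted) ** 2) / sst
        r2_adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        if r2_adj > best[2]:
            best = (-slope, k, r2_adj)
    return best[0], best[1]


def nca(profile: TimeProfile, dose: float = float("nan"),
        route: str = "oral") -> NCAResult:
    """Non-compartmental analysis of a plasma concentration-time profile.

    Times in minutes, concentrations in ng/mL. AUCs in ng*min/mL. When the
    terminal slope cannot be estimated (fewer than 3 declining points),
    AUC(0-inf), t1/2 and lambda_z are reported as nan rather than guessed.
    """
    t, c = profile.times, profile.values
    if np.sum(c > 0) < 3:
        raise ValueError("need at least 3 positive concentrations for NCA")
    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    auc_t = float(np.trapezoid(c, t))
    lam, k = _lambda_z(t, c)
    if np.isfinite(lam):
        c_last = float(c[c > 0][-1])
        auc_inf = auc_t + c_last / lam
        t_half = math.log(2) / lam
    else:
        auc_inf = float("nan")
        t_half = float("nan")
    return NCAResult(cmax=cmax, tmax=tmax, auc_0_t=auc_t, auc_0_inf=auc_inf,
                     t_half=t_half, lambda_z=lam, n_lambda_points=k,
                     dose=dose, route=route)


def bioavailability(auc_po: float, dose_po: float, auc_iv: float,
                    dose_iv: float) -> float:
    """Absolute bioavailability in percent: dose-corrected AUC(0-t) ratio.

    F% = 100 * (AUC_po/dose_po) / (AUC_iv/dose_iv). The AUC(0-t) variant is
    the validated default; pass AUC(0-inf) values to obtain that variant.
    """
    for name, v in (("auc_po", auc_po), ("dose_po", dose_po),
                    ("auc_iv", auc_iv), ("dose_iv", dose_iv)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    return 100.0 * (auc_po / dose_po) / (auc_iv / dose_iv)


class UnitImpulseResponse(BaseEstimator, RegressorMixin):
    """Polyexponential disposition kernel fitted from IV reference data.

    Parameters
    ----------
    n_terms : {1, 2}
        Number of exponential terms.
    weighting : str
        One of '1', '1/Y', '1/Y2', '1/Yhat', '1/Yhat2', or 'auto' to scan
        the candidates and keep the AIC winner. Yhat weightings use two
        iteratively-reweighted passes.
    fit_tlag : bool
        Estimate a lag time (default 0: an IV bolus has no lag).

    Fitted attributes: ``terms_`` (list of (A_i, alpha_i) per unit dose,
    alpha in 1/min, sorted by alpha descending), ``tlag_``, ``weighting_``,
    ``r_``, ``aic_``, ``sbc_``, ``collapsed_``.
    """

    def __init__(self, n_terms: int = 2, weighting: str = "auto",
                 fit_tlag: bool = False):
        self.n_terms = n_terms
        self.weighting = weighting
        self.fit_tlag = fit_tlag

    # -- construction without fitting (synthetic kernels, oracles) --------
    @classmethod
    def from_params(cls, terms, tlag: float = 0.0) -> "UnitImpulseResponse":
        """Build a ready-to-evaluate UIR from known (A_i, alpha_i) pairs."""
        uir = cls(n_terms=len(terms))
        uir.terms_ = sorted(((float(a), float(al)) for a, al in terms),
                            key=lambda p: -p[1])
        uir.tlag_ = float(tlag)
        uir.weighting_ = "1"
        uir.collapsed_ = False
        return uir

    # -- kernel evaluation -------------------------------------------------
    def evaluate(self, t_min) -> np.ndarray:
        """UIR(t) per unit dose; zero before the lag."""
        t = np.asarray(t_min, dtype=float)
        s = t - self.tlag_
        out = np.zeros_like(s)
        live = s >= 0
        for a, al in self.terms_:
            out[live] += a * np.exp(-al * s[live])
        return out

    def cumulative_integral(self, t_min) -> np.ndarray:
        """Exact integral of the kernel from 0 to t (elementwise)."""
        t = np.asarray(t_min, dtype=float)
        s = np.clip(t - self.tlag_, 0.0, None)
        out = np.zeros_like(s)
        for a, al in self.terms_:
            out += (a / al) * (1.0 - np.exp(-al * s))
        return out

    def auc_inf(self) -> float:
        """Analytic integral over [0, inf): sum A_i/alpha_i."""
        return float(sum(a / al for a, al in self.terms_))

    # -- fitting ------------------------------------------------------------
    def _model(self, t, params):
        p = params.valuesdict()
        s = t - p.get("tlag", 0.0)
        out = np.zeros_like(s)
        live = s >= 0
        for i in range(self._n_fit_terms):
            out[live] += p[f"a{i}"] * np.exp(-p[f"alpha{i}"] * s[live])
        return out

    def _fit_once(self, t, y, weights, n_terms, lam0, tmax):
        self._n_fit_terms = n_terms
        sw = np.sqrt(weights)

        def residual(params):
            return (self._model(t, params) - y) * sw

        best = None
        ratios = [(1.0,)] if n_terms == 1 else [(8.0,), (30.0,), (3.0,)]
        for (ratio,) in ratios:
            params = lmfit.Parameters()
            alphas0 = [lam0 * ratio, lam0][:n_terms] if n_terms == 2 \
                else [lam0]
            # amplitude starts from a linear solve on the exponential basis
            basis = np.stack([np.exp(-al * t) for al in alphas0], axis=1)
            amps0, *_ = np.linalg.lstsq(basis * sw[:, None], y * sw,
                                        rcond=None)
            amps0 = np.clip(amps0, 1e-9 * max(y.max(), 1e-12), None)
            for i in range(n_terms):
                params.add(f"a{i}", value=float(amps0[i]), min=0.0)
                params.add(f"alpha{i}", value=float(alphas0[i]),
                           min=1e-8, max=10.0)
            params.add("tlag", value=0.0, min=0.0, max=tmax / 2,
                       vary=self.fit_tlag)
            try:
                res = lmfit.minimize(residual, params, method="leastsq")
            except Exception:
                continue
            ssr = float(np.sum(res.residual**2))
            if best is None or ssr < best[0] - 1e-15:
                best = (ssr, res)
        if best is None:
            raise RuntimeError("UIR fit failed from every start")
        return best

    def fit(self, X, y, dose: float = 1.0):
        """Fit to (times in minutes, IV concentrations); amplitudes are
        normalised by ``dose`` so the kernel is per unit dose."""
        t = _as_1d_times(X)
        y = np.asarray(y, dtype=float)
        if t.size < 2 * self.n_terms + 1:
            raise ValueError(
                f"need at least {2 * self.n_terms + 1} points for "
                f"{self.n_terms} exponential terms")
        if self.n_terms not in (1, 2):
            raise ValueError("n_terms must be 1 or 2")
        lam0, _ = _lambda_z(t, y)
        if not np.isfinite(lam0):
            slope = np.polyfit(t[y > 0], np.log(y[y > 0]), 1)[0]
            lam0 = max(-slope, 1e-5)
        tmax = float(t.max())
        eps = max(float(y[y > 0].min()), 1e-12) * 1e-3

        schemes = (WEIGHTING_SCHEMES if self.weighting == "auto"
                   else (self.weighting,))
        best = None
        for scheme in schemes:
            if scheme == "1":
                w = np.ones_like(y)
                ssr, res = self._fit_once(t, y, w / w.mean(), self.n_terms,
                                          lam0, tmax)
            elif scheme in ("1/Y", "1/Y2"):
                p = 1 if scheme == "1/Y" else 2
                w = 1.0 / np.maximum(y, eps) ** p
                ssr, res = self._fit_once(t, y, w / w.mean(), self.n_terms,
                                          lam0, tmax)
            elif scheme in ("1/Yhat", "1/Yhat2"):
                p = 1 if scheme == "1/Yhat" else 2
                w = np.ones_like(y)
                for _ in range(2):  # two reweighting passes
                    ssr, res = self._fit_once(t, y, w / w.mean(),
                                              self.n_terms, lam0, tmax)
                    yhat = self._model(t, res.params)
                    w = 1.0 / np.maximum(yhat, eps) ** p
            else:
                raise ValueError(f"unknown weighting scheme {scheme!r}")
            n, k = t.size, int(res.nvarys)
            aic = aic_least_squares(n, ssr, k)
            if best is None or aic < best[0]:
                best = (aic, scheme, ssr, res)

        aic, scheme, ssr, res = best
        p = res.params.valuesdict()
        terms = [(p[f"a{i}"] / dose, p[f"alpha{i}"])
                 for i in range(self.n_terms)]
        self.collapsed_ = False
        if (self.n_terms == 2
                and abs(terms[0][1] - terms[1][1]) < ALPHA_COLLAPSE_TOL):
            # degenerate second term: refit with one exponential
            sub = UnitImpulseResponse(n_terms=1, weighting=scheme,
                                      fit_tlag=self.fit_tlag).fit(t, y, dose)
            terms = sub.terms_
            p = {"tlag": sub.tlag_}
            ssr, aic = sub.ssr_, sub.aic_
            res = None
            self.collapsed_ = True
        self.terms_ = sorted(terms, key=lambda q: -q[1])
        self.tlag_ = float(p.get("tlag", 0.0))
        self.dose_ = float(dose)
        self.weighting_ = scheme
        self.ssr_ = ssr
        n = t.size
        k = (res.nvarys if res is not None else 2 * len(self.terms_))
        self.aic_ = aic_least_squares(n, ssr, k)
        self.sbc_ = sbc_least_squares(n, ssr, k)
        self.r_ = correlation_coefficient(y, self.evaluate(t) * dose)
        return self

    def predict(self, X) -> np.ndarray:
        """Concentration at times X for the fitted dose."""
        return self.evaluate(_as_1d_times(X)) * self.dose_


def fit_uir(iv_profile: TimeProfile, iv_dose: float, n_terms: int = 2,
            weighting: str = "auto") -> UnitImpulseResponse:
    """Fit the dose-normalised UIR from an IV reference profile."""
    return UnitImpulseResponse(n_terms=n_terms, weighting=weighting).fit(
        iv_profile.times, iv_profile.values, dose=iv_dose)
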