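"""Synthetic multi-component dissolution and PK data with known ground truth.

The generator emulates the structure of a paddle-method dissolution study
(six vessels, 900 mL medium, 3 mL samples replaced at each time point, the
standard 15-360 min grid truncated at 180 min in 0.1 M HCl) and a crossover
beagle PK study (oral tablets vs IV reference, the standard 15-1440 min
sampling grid), for five tablet components at realistic concentration
scales (plasma Cmax of order 1-100 ng/mL, mean dissolution times of 1-3 h).

Noise is proportional log-normal (a CV on the natural scale; assay precision
for this kind of LC-MS/MS method is of order 1-11%, motivating the 10%
default) plus an optional additive floor. Everything is reproducible from
the scenario seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .core import MediumSpec, TimeProfile
from .dissolution import (STANDARD_GRID_MIN, DissolutionRun,
                          cumulative_dissolution, evaluate_model)
from .pk import UnitImpulseResponse

#: standard PK sampling grid (minutes after dosing)
PK_GRID_MIN = (15, 30, 45, 60, 90, 120, 150, 180, 240, 360, 480, 720, 1440)

DEFAULT_MEDIA = {
    "HCl_0.1M": MediumSpec("HCl_0.1M", ph=1.2),
    "acetate_pH4.5": MediumSpec("acetate_pH4.5", ph=4.5),
    "phosphate_pH6.8": MediumSpec("phosphate_pH6.8", ph=6.8),
    "water": MediumSpec("water", ph=6.9),
    "FaSSGF": MediumSpec("FaSSGF", ph=1.6),
    "FaSSIF-V2": MediumSpec("FaSSIF-V2", ph=6.5),
}


@dataclass(frozen=True)
class ComponentScenario:
    """Ground truth for one tablet component.

    dissolution maps medium name -> (model family, params dict, hours);
    disposition is the true UIR, (A_i per unit IV dose, alpha_i per min);
    ka (1/min) and tlag (min) drive the first-order oral input; f is the
    absolute bioavailability fraction; doses in ug; content in mg/tablet.
    """

    name: str
    dissolution: dict
    disposition: tuple
    ka: float = 0.03
    tlag: float = 25.0
    f: float = 0.08
    oral_dose: float = 2500.0
    iv_dose: float = 20.0
    content_per_tablet: float = 0.3

    def uir(self) -> UnitImpulseResponse:
        return UnitImpulseResponse.from_params(self.disposition)


@dataclass(frozen=True)
class SyntheticScenario:
    """A full study configuration: components, noise model, sizes, seed."""

    components: tuple
    cv: float = 0.10
    noise_floor: float = 0.0
    n_vessels: int = 6
    n_subjects: int = 6
    seed: int = 0
    drug_content_mg: float = 10.0  # per-component content of the 6 tablets

    def __post_init__(self):
        if self.cv < 0 or self.noise_floor < 0:
            raise ValueError("cv and noise_floor must be non-negative")
        for c in self.components:
            if c.ka <= 0 or any(al <= 0 for _, al in c.disposition):
                raise ValueError("all rate constants must be positive")

    def component(self, name: str) -> ComponentScenario:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def rng(self, *salt) -> np.random.Generator:
        return np.random.default_rng([self.seed, *salt])


def _noisy(rng, values, cv, floor):
    out = np.asarray(values, dtype=float).copy()
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        out = out * np.exp(rng.normal(0.0, sigma, out.shape)
                           - 0.5 * sigma**2)
    if floor > 0:
        out = out + rng.normal(0.0, floor, out.shape)
    return np.clip(out, 0.0, None)


def invert_cumulative(fracs, v1: float, v2: float, m: float) -> np.ndarray:
    """Concentrations whose replacement-corrected cumulative dissolution
    reproduces ``fracs`` exactly (inverse of the sampling correction)."""
    fracs = np.asarray(fracs, dtype=float)
    concs = np.zeros_like(fracs)
    removed = 0.0
    for n, d in enumerate(fracs):
        concs[n] = (d * m - v2 * removed) / v1
        removed += concs[n]
    return np.clip(concs, 0.0, None)


def dissolution_grid(medium: MediumSpec) -> np.ndarray:
    """Sampling grid in minutes; gastric media truncate at 180 min
    (gastric emptying)."""
    grid = np.asarray(STANDARD_GRID_MIN, dtype=float)
    if medium.name == "HCl_0.1M":
        grid = grid[grid <= 180]
    return grid


def true_dissolution_curve(component: ComponentScenario, medium: str,
                           t_min) -> np.ndarray:
    family, params = component.dissolution[medium]
    return evaluate_model(family, np.asarray(t_min, dtype=float) / 60.0,
                          params)


def simulate_dissolution(scenario: SyntheticScenario,
                         component_name: str,
                         medium: MediumSpec) -> DissolutionRun:
    """Per-vessel noisy dissolution samples on the standard grid.

    The sampled concentrations are back-computed from the generating curve
    so that the replacement correction (V1=900, V2=3) inverts exactly in
    the noise-free limit.
    """
    comp = scenario.component(component_name)
    grid = dissolution_grid(medium)
    fracs = true_dissolution_curve(comp, medium.name, grid)
    m = scenario.drug_content_mg
    concs_true = invert_cumulative(fracs, medium.volume,
                                   medium.sample_volume, m)
    rng = scenario.rng(zlib.crc32(component_name.encode()),
                       zlib.crc32(medium.name.encode()), 1)
    vessels = []
    for v in range(scenario.n_vessels):
        concs = _noisy(rng, concs_true, scenario.cv, scenario.noise_floor)
        cum = cumulative_dissolution(grid, concs, medium.volume,
                                     medium.sample_volume, m,
                                     label=f"{component_name} vessel {v}")
        vessels.append(cum)
    return DissolutionRun(medium=medium, component=component_name,
                          vessels=vessels)


def _oral_first_order(comp: ComponentScenario, t_min) -> np.ndarray:
    """Analytic first-order-absorption profile over the polyexponential
    disposition (superposition of Bateman terms)."""
    t = np.asarray(t_min, dtype=float)
    s = np.clip(t - comp.tlag, 0.0, None)
    out = np.zeros_like(s)
    ka = comp.ka
    for a, al in comp.disposition:
        if abs(ka - al) < 1e-12:
            out += a * ka * s * np.exp(-ka * s)
        else:
            out += a * ka / (ka - al) * (np.exp(-al * s) - np.exp(-ka * s))
    return comp.f * comp.oral_dose * out * (t >= comp.tlag)


def _oral_dissolution_limited(comp: ComponentScenario, medium: str,
                              t_min, step: float = 1.0) -> np.ndarray:
    """Oral profile whose input rate follows the in vitro dissolution curve
    (staircase increments of the normalised curve, exact convolution)."""
    from .deconvolution import convolve_input

    t = np.asarray(t_min, dtype=float)
    n = int(np.ceil(t.max() / step))
    grid = np.linspace(0.0, n * step, n + 1)
    diss = true_dissolution_curve(comp, medium, grid)
    plateau = diss[-1]
    rate = comp.f * comp.oral_dose * np.diff(diss / plateau) / step
    return convolve_input(grid, rate, comp.uir(), eval_times=t)


@dataclass
class PKStudy:
    """Simulated PK arm: per-subject profiles plus the mean profile."""

    route: str
    component: str
    dose: float
    subjects: list = field(default_factory=list)
    mean_profile: TimeProfile | None = None

    def __post_init__(self):
        if self.subjects and self.mean_profile is None:
            grid = self.subjects[0].times
            mean = np.mean([s.values for s in self.subjects], axis=0)
            self.mean_profile = TimeProfile(
                grid, mean, kind="concentration",
                label=f"{self.component} mean ({self.route})")


def simulate_pk(scenario: SyntheticScenario, component_name: str,
                route: str = "oral", input_kind: str = "first_order",
                input_medium: str | None = None,
                times=PK_GRID_MIN) -> PKStudy:
    """Simulate one PK arm.

    route='iv' samples the polyexponential disposition scaled by the IV
    dose; route='oral' convolves a first-order (default) or
    dissolution-limited input with the disposition.
    """
    comp = scenario.component(component_name)
    t = np.asarray(times, dtype=float)
    if route == "iv":
        clean = comp.iv_dose * comp.uir().evaluate(t)
        dose = comp.iv_dose
    elif route == "oral":
        if input_kind == "first_order":
            clean = _oral_first_order(comp, t)
        elif input_kind == "dissolution":
            if input_medium is None:
                raise ValueError("dissolution-limited input needs a medium")
            clean = _oral_dissolution_limited(comp, input_medium, t)
        else:
            raise ValueError(f"unknown input_kind {input_kind!r}")
        dose = comp.oral_dose
    else:
        raise ValueError(f"unknown route {route!r}")
    rng = scenario.rng(zlib.crc32(component_name.encode()),
                       0 if route == "iv" else 1, 2)
    subjects = [
        TimeProfile(t, _noisy(rng, clean, scenario.cv, scenario.noise_floor),
                    kind="concentration",
                    label=f"{component_name} subject {s}")
        for s in range(scenario.n_subjects)
    ]
    return PKStudy(route=route, component=component_name, dose=dose,
                   subjects=subjects)


# ---------------------------------------------------------------------------
# default study-like scenario

_BASE_DISSOLUTION = {
    # per-medium (family, params-in-hours); shapes span the observed range
    "HCl_0.1M": ("weibull", {"finf": 0.70, "mdt": 1.10, "b": 2.06,
                             "tlag": 0.0}),
    "acetate_pH4.5": ("hill", {"finf": 0.78, "mdt": 1.10, "b": 2.71}),
    "phosphate_pH6.8": ("weibull", {"finf": 0.62, "mdt": 1.50, "b": 1.63,
                                    "tlag": 0.0}),
    "water": ("hill", {"finf": 0.77, "mdt": 1.04, "b": 4.39}),
    "FaSSGF": ("weibull", {"finf": 0.82, "mdt": 1.00, "b": 1.01,
                           "tlag": 0.0}),
    "FaSSIF-V2": ("hill", {"finf": 0.60, "mdt": 1.09, "b": 4.44}),
}


def _vary(base: dict, mdt_factor: float, plateau_factor: float) -> dict:
    out = {}
    for medium, (family, params) in base.items():
        p = dict(params)
        p["mdt"] = p["mdt"] * mdt_factor
        key = "finf" if "finf" in p else "fmax"
        p[key] = min(p[key] * plateau_factor, 1.0)
        out[medium] = (family, p)
    return out


def default_scenario(seed: int = 0, cv: float = 0.10) -> SyntheticScenario:
    """Five-component scenario at the scales of the modelled study: contents
    of 0.1-1.1 mg/tablet, oral doses of a 12-tablet administration, IV
    reference doses of tens-to-hundreds of ug, biexponential disposition
    with half-lives of roughly 1.5 h and 2 days, Cmax of order 1-100 ng/mL."""
    h = 1.0 / 60.0  # per-hour -> per-minute
    components = (
        ComponentScenario(
            name="tetrahydropalmatine",
            dissolution=_vary(_BASE_DISSOLUTION, 1.0, 1.0),
            disposition=((0.50, 0.48 * h), (0.075, 0.015 * h)),
            ka=0.015, tlag=25.0, f=0.108,
            oral_dose=2500.0, iv_dose=19.75, content_per_tablet=0.3017),
        ComponentScenario(
            name="corydaline",
            dissolution=_vary(_BASE_DISSOLUTION, 1.1, 0.95),
            disposition=((0.95, 0.52 * h), (0.14, 0.012 * h)),
            ka=0.028, tlag=26.0, f=0.054,
            oral_dose=963.0, iv_dose=4.54, content_per_tablet=0.2871),
        ComponentScenario(
            name="protopine",
            dissolution=_vary(_BASE_DISSOLUTION, 0.9, 0.9),
            disposition=((0.060, 0.55 * h), (0.009, 0.010 * h)),
            ka=0.022, tlag=26.0, f=0.0135,
            oral_dose=1896.0, iv_dose=168.062, content_per_tablet=0.1742),
        ComponentScenario(
            name="alpha-allocryptopine",
            dissolution=_vary(_BASE_DISSOLUTION, 1.15, 1.05),
            disposition=((0.090, 0.45 * h), (0.013, 0.009 * h)),
            ka=0.035, tlag=40.0, f=0.075,
            oral_dose=917.0, iv_dose=297.16, content_per_tablet=1.1042),
        ComponentScenario(
            name="byakangelicin",
            dissolution=_vary(_BASE_DISSOLUTION, 0.95, 0.85),
            disposition=((0.13, 0.90 * h), (0.022, 0.020 * h)),
            ka=0.026, tlag=27.0, f=0.11,
            oral_dose=2783.0, iv_dose=78.68, content_per_tablet=0.0975),
    )
    return SyntheticScenario(components=components, cv=cv, seed=seed)


def with_seed(scenario: SyntheticScenario, seed: int) -> SyntheticScenario:
    return replace(scenario, seed=seed)
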