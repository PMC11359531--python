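"""Shared data model: time profiles, component/medium metadata, grid utilities.

The canonical internal time unit is minutes; hours appear only at I/O and in
reported dissolution-model parameters (MDT, Tmax, tlag are conventionally
quoted in hours). Value kinds distinguish unitless cumulative fractions,
plasma concentrations (ng/mL) and amounts (ug).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

VALUE_KINDS = ("fraction", "concentration", "amount")
TIME_UNITS = ("minutes", "hours")

#: fraction profiles may overshoot 1 slightly from assay noise; above this we flag
FRACTION_OVERSHOOT_TOL = 1.05

#: registered dissolution media names
MEDIA_REGISTRY = (
    "HCl_0.1M",
    "acetate_pH4.5",
    "phosphate_pH6.8",
    "water",
    "FaSSGF",
    "FaSSIF-V2",
)


class ProfileError(ValueError):
    """Raised for structurally invalid time profiles or grid requests."""


@dataclass(frozen=True)
class TimeProfile:
    """An ordered (time, value) series.

    Parameters
    ----------
    times : array-like
        Sampling times, strictly increasing, non-negative.
    values : array-like
        Observed values, finite. For ``kind='fraction'`` values are expected
        in [0, 1.05]; larger values trigger a warning (flagged, not rejected).
    kind : str
        One of ``fraction``, ``concentration``, ``amount``.
    label : str
        Free-text label (component, medium, subject ...).
    time_unit : str
        ``minutes`` (canonical) or ``hours``.
    """

    times: np.ndarray
    values: np.ndarray
    kind: str = "concentration"
    label: str = ""
    time_unit: str = "minutes"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise ProfileError("times and values must be 1-D arrays of equal length")
        if t.size == 0:
            raise ProfileError("empty profile")
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(v)):
            raise ProfileError("times and values must be finite")
        if np.any(t < 0):
            raise ProfileError("times must be non-negative")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ProfileError("times must be strictly increasing")
        if self.kind not in VALUE_KINDS:
            raise ProfileError(f"unknown value kind {self.kind!r}")
        if self.time_unit not in TIME_UNITS:
            raise ProfileError(f"unknown time unit {self.time_unit!r}")
        if self.kind == "fraction" and np.any(v > FRACTION_OVERSHOOT_TOL):
            warnings.warn(
                f"fraction profile {self.label!r} exceeds "
                f"{FRACTION_OVERSHOOT_TOL} (max {v.max():.4f})",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "value": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind: str = "concentration", label: str = "",
                 time_unit: str = "minutes") -> "TimeProfile":
        df = pd.read_csv(path)
        tcol, vcol = df.columns[:2]
        return cls(df[tcol].to_numpy(), df[vcol].to_numpy(),
                   kind=kind, label=label, time_unit=time_unit)


@dataclass(frozen=True)
class MediumSpec:
    """A dissolution medium and vessel configuration.

    ``volume`` is the medium volume in the vessel (V1 of the cumulative
    dissolution correction); ``sample_volume`` is the volume withdrawn and
    replaced at each sampling time (V2).
    """

    name: str
    ph: float
    volume: float = 900.0
    sample_volume: float = 3.0
    paddle_rpm: int = 75

    def __post_init__(self) -> None:
        if self.name not in MEDIA_REGISTRY:
            raise ValueError(f"unknown medium {self.name!r}; "
                             f"registered: {MEDIA_REGISTRY}")
        if self.volume <= 0:
            raise ValueError("medium volume must be positive")
        if not 0 <= self.sample_volume < self.volume:
            raise ValueError("sample_volume must be in [0, volume)")
        if self.paddle_rpm not in (50, 75, 100):
            raise ValueError("paddle_rpm must be one of 50, 75, 100")


@dataclass(frozen=True)
class ComponentSpec:
    """Per-component formulation and biopharmaceutic metadata.

    content_per_tablet in mg; oral_dose and iv_dose in ug; solubilities in
    mg/mL keyed by medium name; peff in cm/s. ``m0_over_v0`` is the maximum
    administered dose divided by the reference gastric volume (mg/mL); if not
    given it is derived as content_per_tablet * tablets_per_dose / v0.
    ``censored_solubilities`` flags media whose solubility is a lower bound
    (assay saturated), e.g. reported as ">2.385".
    """

    name: str
    content_per_tablet: float
    oral_dose: float = float("nan")
    iv_dose: float = float("nan")
    solubilities: dict = field(default_factory=dict)
    peff: float = float("nan")
    m0_over_v0: float = float("nan")
    tablets_per_dose: int = 6
    censored_solubilities: frozenset = frozenset()

    def __post_init__(self) -> None:
        for attr in ("content_per_tablet", "oral_dose", "iv_dose", "peff",
                     "m0_over_v0"):
            val = getattr(self, attr)
            if np.isfinite(val) and val < 0:
                raise ValueError(f"{attr} must be non-negative")
        unknown = set(self.solubilities) - set(MEDIA_REGISTRY)
        if unknown:
            raise ValueError(f"solubilities for unregistered media: {sorted(unknown)}")
        object.__setattr__(self, "censored_solubilities",
                           frozenset(self.censored_solubilities))

    def dose_concentration(self, v0: float = 250.0) -> float:
        """M0/V0 in mg/mL: maximum administered dose over gastric volume."""
        if np.isfinite(self.m0_over_v0):
            return self.m0_over_v0
        return self.content_per_tablet * self.tablets_per_dose / v0


def resample(profile: TimeProfile, grid, method: str = "linear") -> TimeProfile:
    """Interpolate ``profile`` onto ``grid`` (same time unit).

    ``pchip`` is monotone-preserving and is the right choice for cumulative
    quantities (dissolution, absorption); ``linear`` suits concentrations.
    Extrapolation is refused.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if len(profile) < 2:
        raise ProfileError("resample requires at least 2 points")
    lo, hi = profile.times[0], profile.times[-1]
    out = grid[(grid < lo) | (grid > hi)]
    if out.size:
        raise ProfileError(
            f"grid time {out[0]:g} outside observed range [{lo:g}, {hi:g}]")
    if method == "linear":
        vals = np.interp(grid, profile.times, profile.values)
    elif method == "pchip":
        vals = PchipInterpolator(profile.times, profile.values)(grid)
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    # endpoints (and any grid point coinciding with a knot) are exact
    return replace(profile, times=grid, values=np.asarray(vals, dtype=float))


def convert_time_units(profile: TimeProfile, to: str) -> TimeProfile:
    """Rescale the time axis between minutes and hours. Values untouched."""
    if to not in TIME_UNITS:
        raise ValueError(f"unknown time unit {to!r}")
    if profile.time_unit == to:
        return profile
    factor = 1.0 / 60.0 if to == "hours" else 60.0
    return replace(profile, times=profile.times * factor, time_unit=to)


def trapezoid_auc(profile: TimeProfile) -> float:
    """Linear-trapezoid area under the profile over its observed range."""
    return float(np.trapezoid(profile.values, profile.times))
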