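"""Biopharmaceutics classification: dose number, apparent permeability, BCS.

The dose number D0 = (M0/V0)/Cs compares the concentration of the maximum
administered dose dissolved in a reference gastric volume (250 mL) with the
minimum aqueous solubility across physiological pH; D0 <= 1 means highly
soluble. Apparent permeability Peff = (dQ/dt)/(A*C0) from a transwell
monolayer transport assay; Peff > 1e-6 cm/s counts as highly permeable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ComponentSpec

#: default gastric reference volume (mL) for the dose number
DEFAULT_V0 = 250.0

#: transwell membrane area (cm^2) of the 24-well plate used in the assay
DEFAULT_TRANSWELL_AREA = 0.33

#: high-permeability threshold (cm/s)
PEFF_THRESHOLD = 1e-6

#: media whose solubilities enter the BCS solubility class (pH 1.2, 4.5, 6.8)
BCS_MEDIA = ("HCl_0.1M", "acetate_pH4.5", "phosphate_pH6.8")

_BCS_TABLE = {
    ("high", "high"): "I",
    ("low", "high"): "II",
    ("high", "low"): "III",
    ("low", "low"): "IV",
}


@dataclass(frozen=True)
class BCSResult:
    """Per-medium dose numbers, permeability and the resulting BCS class."""

    d0_by_medium: dict
    d0_censored: frozenset
    peff: float
    solubility_class: str
    permeability_class: str
    bcs_class: str


def dose_number(m0: float, v0: float, cs: float) -> float:
    """Dose number D0 = (m0/v0)/cs.

    m0: maximum administered dose (mg); v0: reference volume (mL);
    cs: solubility (mg/mL). All must be positive.
    """
    if m0 <= 0 or v0 <= 0:
        raise ValueError("m0 and v0 must be positive")
    if cs <= 0:
        raise ValueError("solubility cs must be positive (insoluble input)")
    return (m0 / v0) / cs


def transport_rate(times_min, amounts) -> float:
    """Least-squares slope of cumulative transported amount vs time.

    times_min in minutes, amounts in the assay's amount unit. Returns the
    rate per *second* (replacement-corrected cumulative amounts expected).
    """
    t = np.asarray(times_min, dtype=float)
    q = np.asarray(amounts, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 receiver time points")
    slope_per_min = np.polyfit(t, q, 1)[0]
    return float(slope_per_min / 60.0)


def apparent_permeability(dq_dt: float, area: float = DEFAULT_TRANSWELL_AREA,
                          c0: float = 1.0) -> float:
    """Apparent permeability Peff = (dQ/dt)/(A*C0).

    dq_dt: transport rate in amount per second (use :func:`transport_rate`
    to estimate it from per-minute receiver sampling); area in cm^2; c0 the
    initial donor concentration in the same amount unit per mL. Returns cm/s.
    """
    if area <= 0 or c0 <= 0:
        raise ValueError("area and c0 must be positive")
    return dq_dt / (area * c0)


def permeability_class(peff: float, threshold: float = PEFF_THRESHOLD) -> str:
    return "high" if peff > threshold else "low"


def classify_bcs(spec: ComponentSpec, v0: float = DEFAULT_V0,
                 peff_threshold: float = PEFF_THRESHOLD) -> BCSResult:
    """Assign a BCS class from solubilities at pH 1.2/4.5/6.8 and Peff.

    D0 is reported per medium (each medium's own solubility) and the
    solubility class is decided by the minimum solubility across the three
    media (equivalently the maximum D0). Censored (lower-bound) solubilities
    propagate to upper-bound D0 values, flagged in ``d0_censored``.
    """
    missing = [m for m in BCS_MEDIA if m not in spec.solubilities]
    if missing:
        raise ValueError(f"missing solubilities for media: {missing}")
    if not np.isfinite(spec.peff):
        raise ValueError("component peff is not set")
    m0v0 = spec.dose_concentration(v0)
    d0 = {m: m0v0 / spec.solubilities[m] for m in BCS_MEDIA}
    censored = frozenset(m for m in BCS_MEDIA
                         if m in spec.censored_solubilities)
    d0_max = max(d0.values())  # minimum-solubility rule
    sol_class = "high" if d0_max <= 1.0 else "low"
    perm_class = permeability_class(spec.peff, peff_threshold)
    return BCSResult(
        d0_by_medium=d0,
        d0_censored=censored,
        peff=spec.peff,
        solubility_class=sol_class,
        permeability_class=perm_class,
        bcs_class=_BCS_TABLE[(sol_class, perm_class)],
    )
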