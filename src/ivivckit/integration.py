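"""Content-weighted integration of multi-component profiles.

Components sharing a BCS class have similar dissolution and absorption
behaviour, so their individual dissolution profiles are combined into one
class-level profile using content weights

    Wi = Ni / sum(N),     Ct = sum_i Wi * Ci(t),

while class-level plasma concentration is the plain sum of the member
concentrations at each time point, CT = sum_j Cj(t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TimeProfile


@dataclass(frozen=True)
class IntegratedProfile:
    """A class-level profile with its member weights."""

    profile: TimeProfile
    weights: dict
    bcs_class: str = ""

    def __post_init__(self):
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"weights sum to {total!r}, expected 1")


def weight_coefficients(contents: dict) -> dict:
    """Content weights Wi = Ni / sum(N) from per-component contents (mg)."""
    if not contents:
        raise ValueError("empty contents map")
    if any(v <= 0 for v in contents.values()):
        raise ValueError("all contents must be positive")
    total = sum(contents.values())
    return {name: v / total for name, v in contents.items()}


def _check_common_grid(profiles: dict) -> np.ndarray:
    items = iter(profiles.items())
    first_name, first = next(items)
    grid = first.times
    for name, p in items:
        if not np.array_equal(p.times, grid):
            raise ValueError(
                f"profile {name!r} is not on the common grid of "
                f"{first_name!r}; resample first")
    return grid


def integrate_dissolution(profiles: dict, weights: dict,
                          bcs_class: str = "") -> IntegratedProfile:
    """Pointwise convex combination of dissolution profiles: sum Wi*Ci."""
    missing = set(profiles) ^ set(weights)
    if missing:
        raise ValueError(f"profiles/weights key mismatch: {sorted(missing)}")
    grid = _check_common_grid(profiles)
    ct = np.zeros(grid.size)
    for name, p in profiles.items():
        ct += weights[name] * p.values
    prof = TimeProfile(grid, ct, kind="fraction", label="integrated")
    return IntegratedProfile(prof, dict(weights), bcs_class=bcs_class)


def integrate_concentrations(profiles: dict, weights: dict | None = None) \
        -> TimeProfile:
    """Pointwise sum of plasma concentrations, CT = sum Cj (unweighted by
    default; optional weights expose per-component scaling)."""
    if not profiles:
        raise ValueError("empty profiles map")
    grid = _check_common_grid(profiles)
    ct = np.zeros(grid.size)
    for name, p in profiles.items():
        w = 1.0 if weights is None else weights[name]
        ct += w * p.values
    return TimeProfile(grid, ct, kind="concentration", label="integrated")
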