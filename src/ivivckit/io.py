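"""Config schema, file formats and report writers.

Delimited files use '.' decimal, ',' separator, UTF-8. Model files are JSON
with named parameters. The run config is schema-validated (unknown keys are
rejected) and a single seed drives all randomness.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .core import MEDIA_REGISTRY, ComponentSpec, TimeProfile
from .dissolution import MODEL_FAMILIES, DissolutionModel, DissolutionRun
from .ivivc import FORMS, IVIVCCorrelation
from .pk import UnitImpulseResponse


class ComponentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    content_per_tablet: float = Field(gt=0)  # mg
    oral_dose: float = Field(gt=0)           # ug
    iv_dose: float = Field(gt=0)             # ug
    solubilities: dict[str, float] = Field(default_factory=dict)  # mg/mL
    censored: list[str] = Field(default_factory=list)
    peff: float = Field(gt=0)                # cm/s
    tablets_per_dose: int = 6

    def to_spec(self) -> ComponentSpec:
        return ComponentSpec(
            name=self.name, content_per_tablet=self.content_per_tablet,
            oral_dose=self.oral_dose, iv_dose=self.iv_dose,
            solubilities=dict(self.solubilities), peff=self.peff,
            tablets_per_dose=self.tablets_per_dose,
            censored_solubilities=frozenset(self.censored))


class FittingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    finf_fixed: bool = False
    dissolution_models: list[str] = Field(
        default_factory=lambda: list(MODEL_FAMILIES))
    uir_terms: int = 2
    uir_weighting: str = "auto"
    forms: list[str] = Field(default_factory=lambda: list(FORMS))


class RunConfig(BaseModel):
    """Study-level configuration for the full pipeline."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    cv: float = Field(default=0.10, ge=0)
    media: list[str] = Field(default_factory=lambda: list(MEDIA_REGISTRY))
    components: list[ComponentConfig] = Field(default_factory=list)
    grid_step: float = Field(default=5.0, gt=0)
    pe_threshold: float = 15.0
    v0_ml: float = Field(default=250.0, gt=0)
    fitting: FittingConfig = Field(default_factory=FittingConfig)

    def digest(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = (yaml.safe_load(text) if str(path).endswith((".yml", ".yaml"))
                else json.loads(text))
        return cls.model_validate(data)


def default_components() -> list[ComponentConfig]:
    """The five-component registry at study-like magnitudes (contents in
    mg/tablet, solubilities in mg/mL, doses in ug)."""
    rows = [
        ("tetrahydropalmatine", 0.3017, 2500.0, 19.75,
         {"phosphate_pH6.8": 0.0197, "acetate_pH4.5": 2.666,
          "HCl_0.1M": 0.655}, [], 3.76e-6),
        ("corydaline", 0.2871, 963.0, 4.54,
         {"phosphate_pH6.8": 2.385, "acetate_pH4.5": 2.385,
          "HCl_0.1M": 2.385}, ["acetate_pH4.5", "HCl_0.1M"], 3.94e-6),
        ("protopine", 0.1742, 1896.0, 168.062,
         {"phosphate_pH6.8": 0.535, "acetate_pH4.5": 5.403,
          "HCl_0.1M": 4.700}, [], 7.49e-6),
        ("alpha-allocryptopine", 1.1042, 917.0, 297.16,
         {"phosphate_pH6.8": 0.0447, "acetate_pH4.5": 0.0458,
          "HCl_0.1M": 0.0487}, [], 1.34e-5),
        ("byakangelicin", 0.0975, 2783.0, 78.68,
         {"phosphate_pH6.8": 0.00763, "acetate_pH4.5": 1.291,
          "HCl_0.1M": 2.662}, [], 8.95e-6),
    ]
    return [ComponentConfig(name=n, content_per_tablet=c, oral_dose=od,
                            iv_dose=ivd, solubilities=sol, censored=cen,
                            peff=p)
            for n, c, od, ivd, sol, cen, p in rows]


# ---------------------------------------------------------------------------
# profile and run readers/writers

def read_profile_csv(path, kind: str = "concentration",
                     label: str = "") -> TimeProfile:
    return TimeProfile.from_csv(path, kind=kind, label=label)


def write_profile_csv(profile: TimeProfile, path) -> None:
    profile.to_csv(path)


def read_dissolution_runs(path, medium, content_mg: float) -> dict:
    """Read a long-format dissolution CSV (columns time_min, vessel,
    component, concentration_mg_per_ml) into per-component runs."""
    from .dissolution import cumulative_dissolution

    df = pd.read_csv(path)
    runs = {}
    for comp, cdf in df.groupby("component"):
        vessels = []
        for _, vdf in cdf.groupby("vessel"):
            vdf = vdf.sort_values("time_min")
            vessels.append(cumulative_dissolution(
                vdf["time_min"].to_numpy(),
                vdf["concentration_mg_per_ml"].to_numpy(),
                medium.volume, medium.sample_volume, content_mg,
                label=str(comp)))
        runs[comp] = DissolutionRun(medium=medium, component=str(comp),
                                    vessels=vessels)
    return runs


def read_pk_profiles(path) -> dict:
    """Read a long-format PK CSV (time_min, subject, component,
    conc_ng_per_ml) into per-component mean profiles."""
    df = pd.read_csv(path)
    out = {}
    for comp, cdf in df.groupby("component"):
        wide = cdf.pivot_table(index="time_min", values="conc_ng_per_ml",
                               aggfunc="mean").sort_index()
        out[comp] = TimeProfile(wide.index.to_numpy(),
                                wide["conc_ng_per_ml"].to_numpy(),
                                kind="concentration", label=str(comp))
    return out


# ---------------------------------------------------------------------------
# model serialisation

def uir_to_dict(uir: UnitImpulseResponse) -> dict:
    return {"terms": [[a, al] for a, al in uir.terms_],
            "tlag_min": uir.tlag_,
            "weighting": getattr(uir, "weighting_", "1")}


def uir_from_dict(d: dict) -> UnitImpulseResponse:
    return UnitImpulseResponse.from_params(d["terms"],
                                           tlag=d.get("tlag_min", 0.0))


def dissolution_to_dict(fit: DissolutionModel) -> dict:
    return {"model": fit.model, "params": dict(fit.params_),
            "r": getattr(fit, "r_", None), "aic": getattr(fit, "aic_", None)}


def dissolution_from_dict(d: dict) -> DissolutionModel:
    fit = DissolutionModel(model=d["model"])
    fit.params_ = dict(d["params"])
    if d.get("r") is not None:
        fit.r_ = d["r"]
    if d.get("aic") is not None:
        fit.aic_ = d["aic"]
    return fit


def ivivc_to_dict(model: IVIVCCorrelation) -> dict:
    return {"form": model.form,
            "abs_scale": model.abs_scale_, "t_scale": model.t_scale_,
            "t_shift_min": model.t_shift_, "abs_base": model.abs_base_,
            "r_adj": model.r_adj_, "aic": model.aic_, "sbc": model.sbc_,
            "dissolution": dissolution_to_dict(model.dissolution_model)}


def ivivc_from_dict(d: dict) -> IVIVCCorrelation:
    model = IVIVCCorrelation(form=d["form"],
                             dissolution_model=dissolution_from_dict(
                                 d["dissolution"]))
    model.abs_scale_ = d["abs_scale"]
    model.t_scale_ = d["t_scale"]
    model.t_shift_ = d["t_shift_min"]
    model.abs_base_ = d["abs_base"]
    model.r_adj_ = d.get("r_adj", float("nan"))
    model.aic_ = d.get("aic", float("nan"))
    model.sbc_ = d.get("sbc", float("nan"))
    model.identifiable_ = True
    return model


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serialisable: {type(o)}")
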