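"""Full-study orchestration: classification, dissolution-model fitting,
UIR estimation, deconvolution, correlation screening, integration and
internal validation, with table-shaped CSV/JSON reports.

The runner operates on a synthetic scenario (the package ships no study
data); real-data analyses compose the same library calls through the
individual CLI subcommands.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biopharm import classify_bcs
from .core import convert_time_units
from .deconvolution import deconvolve
from .dissolution import DissolutionModel, select_dissolution_model
from .integration import (integrate_concentrations, integrate_dissolution,
                          weight_coefficients)
from .io import RunConfig, default_components, uir_to_dict, write_json
from .ivivc import fit_ivivc, select_ivivc, validate
from .pk import bioavailability, fit_uir, nca
from .synthetic import (DEFAULT_MEDIA, SyntheticScenario, default_scenario,
                        simulate_dissolution, simulate_pk)

log = logging.getLogger("ivivckit.study")


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and offending input."""


def _fit_and_select(profile, component, medium_name, families, finf_fixed):
    profile_h = convert_time_units(profile, "hours")
    fits = []
    for family in families:
        try:
            fits.append(DissolutionModel(model=family,
                                         finf_fixed=finf_fixed)
                        .fit(profile_h.times, profile_h.values))
        except Exception as exc:  # family may be inadequate for the shape
            log.warning("dissolution fit %s/%s/%s failed: %s",
                        component, medium_name, family, exc)
    if not fits:
        raise StageError(f"dissolution fitting failed for {component} "
                         f"in {medium_name}")
    winner = select_dissolution_model(fits)
    log.info("dissolution %s/%s: selected %s (r=%.4f, aic=%.2f)",
             component, medium_name, winner.model, winner.r_, winner.aic_)
    return fits, winner


def run_full_study(config: RunConfig | None = None,
                   out_dir=None,
                   scenario: SyntheticScenario | None = None) -> dict:
    """Execute the end-to-end workflow and return the report bundle.

    Stages: BCS classification -> dissolution fitting in every configured
    medium -> IV NCA/UIR -> deconvolution of the oral profile ->
    correlation screening across media/forms -> internal validation ->
    BCS-class-weighted integration re-running the same stack.
    """
    config = config or RunConfig(components=default_components())
    if not config.components:
        raise StageError("config lists no components")
    if scenario is None:
        scenario = default_scenario(seed=config.seed, cv=config.cv)
    names = [c.name for c in config.components]
    for c in config.components:
        try:
            scenario.component(c.name)
        except KeyError:
            raise StageError(f"scenario has no kinetics for component "
                             f"{c.name!r}") from None
    media = {m: DEFAULT_MEDIA[m] for m in config.media}

    reports: dict = {"version": __version__, "config_hash": config.digest()}

    # --- stage 1: biopharmaceutic classification --------------------------
    bcs_rows, bcs_by_name = [], {}
    for comp in config.components:
        res = classify_bcs(comp.to_spec(), v0=config.v0_ml)
        bcs_by_name[comp.name] = res
        row = {"component": comp.name, "peff_cm_s": res.peff,
               "solubility_class": res.solubility_class,
               "permeability_class": res.permeability_class,
               "bcs_class": res.bcs_class}
        row.update({f"d0_{m}": v for m, v in res.d0_by_medium.items()})
        bcs_rows.append(row)
    reports["bcs"] = pd.DataFrame(bcs_rows)

    # --- stage 2: dissolution fitting per component x medium --------------
    diss_rows, selected_diss = [], {}
    for name in names:
        for mname, medium in media.items():
            run = simulate_dissolution(scenario, name, medium)
            _, winner = _fit_and_select(run.mean_profile, name, mname,
                                        config.fitting.dissolution_models,
                                        config.fitting.finf_fixed)
            selected_diss[(name, mname)] = winner
            diss_rows.append({"component": name, "medium": mname,
                              "model": winner.model, "r": winner.r_,
                              "aic": winner.aic_, **{f"param_{k}": v
                                                     for k, v in
                                                     winner.params_.items()}})
    reports["dissolution_models"] = pd.DataFrame(diss_rows)

    # --- stage 3: PK, NCA, UIR, deconvolution ------------------------------
    pk_rows, uirs, fabs_curves, oral_means, iv_means, oral_ncas = \
        [], {}, {}, {}, {}, {}
    for comp in config.components:
        iv = simulate_pk(scenario, comp.name, route="iv")
        oral = simulate_pk(scenario, comp.name, route="oral")
        iv_means[comp.name] = iv.mean_profile
        oral_means[comp.name] = oral.mean_profile
        nca_iv = nca(iv.mean_profile, dose=comp.iv_dose, route="iv")
        nca_po = nca(oral.mean_profile, dose=comp.oral_dose, route="oral")
        oral_ncas[comp.name] = nca_po
        f_pct = bioavailability(nca_po.auc_0_t, comp.oral_dose,
                                nca_iv.auc_0_t, comp.iv_dose)
        try:
            uir = fit_uir(iv.mean_profile, comp.iv_dose,
                          n_terms=config.fitting.uir_terms,
                          weighting=config.fitting.uir_weighting)
        except Exception as exc:
            raise StageError(f"UIR fitting failed for {comp.name}: {exc}")
        uirs[comp.name] = uir
        log.info("UIR %s: weighting %s, r=%.4f", comp.name, uir.weighting_,
                 uir.r_)
        fabs_curves[comp.name] = deconvolve(oral.mean_profile, uir,
                                            grid_step=config.grid_step)
        pk_rows.append({"component": comp.name,
                        "cmax_po": nca_po.cmax, "tmax_po": nca_po.tmax,
                        "auc0t_po": nca_po.auc_0_t,
                        "cmax_iv": nca_iv.cmax, "auc0t_iv": nca_iv.auc_0_t,
                        "bioavailability_pct": f_pct,
                        "uir_weighting": uir.weighting_, "uir_r": uir.r_})
    reports["pk_nca"] = pd.DataFrame(pk_rows)
    reports["uir"] = {name: uir_to_dict(u) for name, u in uirs.items()}

    # --- stage 4: correlation screening + internal validation --------------
    ivivc_rows, best_models = [], {}
    for comp in config.components:
        fabs = fabs_curves[comp.name]
        f_total = min(
            reports["pk_nca"].set_index("component")
            .loc[comp.name, "bioavailability_pct"] / 100.0, 1.0)
        per_medium = {}
        for mname in media:
            diss = selected_diss[(comp.name, mname)]
            fits = [fit_ivivc(fabs, diss, form)
                    for form in config.fitting.forms]
            winner = select_ivivc(fits)
            report = validate(winner, uirs[comp.name],
                              oral_ncas[comp.name], comp.oral_dose,
                              f_total, threshold=config.pe_threshold)
            per_medium[mname] = (winner, report)
            ivivc_rows.append({
                "component": comp.name, "medium": mname,
                "form": winner.form, "abs_scale": winner.abs_scale_,
                "t_scale": winner.t_scale_, "t_shift": winner.t_shift_,
                "abs_base": winner.abs_base_, "r_adj": winner.r_adj_,
                "aic": winner.aic_, "sbc": winner.sbc_,
                "pe_auc": round(report.pe_pct["auc"], 2),
                "pe_cmax": round(report.pe_pct["cmax"], 2),
                "internal_pass": report.verdict})
        passing = {m: mw for m, mw in per_medium.items() if mw[1].verdict}
        pool = passing or per_medium
        best_medium = max(pool, key=lambda m: pool[m][0].r_adj_)
        best_models[comp.name] = (best_medium, *per_medium[best_medium])
        log.info("IVIVC %s: selected medium %s (form %s, r_adj=%.4f, "
                 "internal %s)", comp.name, best_medium,
                 per_medium[best_medium][0].form,
                 per_medium[best_medium][0].r_adj_,
                 "pass" if per_medium[best_medium][1].verdict else "FAIL")
    reports["ivivc"] = pd.DataFrame(ivivc_rows)
    reports["selected"] = pd.DataFrame(
        [{"component": n, "medium": m, "form": w.form,
          "internal_pass": rep.verdict}
         for n, (m, w, rep) in best_models.items()])

    # --- stage 5: BCS-class integration ------------------------------------
    groups: dict = {}
    for comp in config.components:
        groups.setdefault(bcs_by_name[comp.name].bcs_class, []).append(comp)
    integrated_rows = []
    for bcs_class, members in sorted(groups.items()):
        contents = {c.name: c.content_per_tablet for c in members}
        weights = weight_coefficients(contents)
        for mname, medium in media.items():
            runs = {c.name: simulate_dissolution(scenario, c.name, medium)
                    for c in members}
            profiles = {n: r.mean_profile for n, r in runs.items()}
            integ = integrate_dissolution(profiles, weights,
                                          bcs_class=bcs_class)
            _, winner = _fit_and_select(
                integ.profile, f"BCS {bcs_class}", mname,
                config.fitting.dissolution_models,
                config.fitting.finf_fixed)
            integrated_rows.append({"bcs_class": bcs_class, "medium": mname,
                                    "model": winner.model, "r": winner.r_,
                                    **{f"param_{k}": v for k, v in
                                       winner.params_.items()}})
        iv_sum = integrate_concentrations(
            {c.name: iv_means[c.name] for c in members})
        oral_sum = integrate_concentrations(
            {c.name: oral_means[c.name] for c in members})
        dose_iv = sum(c.iv_dose for c in members)
        dose_po = sum(c.oral_dose for c in members)
        uir_g = fit_uir(iv_sum, dose_iv, n_terms=config.fitting.uir_terms,
                        weighting=config.fitting.uir_weighting)
        fabs_g = deconvolve(oral_sum, uir_g, grid_step=config.grid_step)
        nca_g = nca(oral_sum, dose=dose_po, route="oral")
        f_g = min(bioavailability(nca_g.auc_0_t, dose_po,
                                  nca(iv_sum, dose=dose_iv).auc_0_t,
                                  dose_iv) / 100.0, 1.0)
        reports[f"integrated_group_{bcs_class}"] = {
            "members": [c.name for c in members], "weights": weights,
            "uir": uir_to_dict(uir_g), "f_abs_total": f_g,
            "fabs_plateau_time_min": float(fabs_g.times[-1])}
    reports["integrated_dissolution"] = pd.DataFrame(integrated_rows)

    if out_dir is not None:
        _write_reports(reports, Path(out_dir))
    return reports


def _write_reports(reports: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"version": reports["version"],
            "config_hash": reports["config_hash"]}
    for key, value in reports.items():
        if isinstance(value, pd.DataFrame):
            value.to_csv(out_dir / f"{key}.csv", index=False)
        elif key not in ("version", "config_hash"):
            meta[key] = value
    write_json(meta, out_dir / "run.json")
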