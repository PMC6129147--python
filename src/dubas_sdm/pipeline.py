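"""Configuration and the end-to-end driver.

The pipeline wires the stages in the workflow order: synthetic (or file)
inputs -> variable selection -> replicated ensemble fit -> held-out
evaluation and suitability classification -> scenario projection -> annual
hotspot surfaces -> station-climate OLS/GWR. Every stage's inputs and
outputs are plain files (ASCII grids, CSV, JSON), a resolved copy of the
configuration is written into the run directory, and all randomness derives
from a single master seed by a documented per-stage scheme
(``SeedSequence([seed, stage_index])``), so runs are replayable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import ensemble as ens
from . import interpolate, project, sdm, spatialreg, synthdata, varselect
from .errors import ConfigurationError
from .geodata import (
    OccurrenceTable,
    read_occurrences,
    read_raster,
    read_stack,
    split_by_longitude,
    write_raster,
    write_stack,
)

logger = logging.getLogger(__name__)

#: Longitude bands of the geographic calibration/validation split
#: (56 deg 30' - 59 deg 00' E trains; flanking half-degree bands test).
DEFAULT_TRAIN_BAND = (56.5, 59.0)
DEFAULT_TEST_BANDS = ((56.0, 56.5), (59.0, 59.5))

_SCHEMA: dict[str, dict[str, Any]] = {
    "seed": None,
    "inputs": {"occurrences": None, "stack_dir": None},
    "synth": {f.name: None for f in dataclasses.fields(synthdata.SynthConfig)},
    "split": {"train_band": None, "test_bands": None},
    "select": {"enabled": None, "r_max": None},
    "ensemble": {"models": None, "replicates": None, "n_background": None,
                 "quadratic": None, "kernel_sd": None, "consensus_rule": None,
                 "model_params": None},
    "classify": {"marginal_fraction": None},
    "scenarios": None,
    "hotspot": {"enabled": None, "years": None, "high_quantile": None,
                "variogram_slope": None, "variogram_nugget": None},
    "gwr": {"enabled": None, "n_stations": None, "n_days": None, "year": None,
            "vif_max": None, "bandwidth": None, "kernel": None},
}


class PipelineConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    def __init__(self, raw: dict | None = None):
        raw = dict(raw or {})
        for key, sub in raw.items():
            if key not in _SCHEMA:
                raise ConfigurationError(f"unknown config key {key!r}")
            schema = _SCHEMA[key]
            if isinstance(schema, dict) and isinstance(sub, dict):
                for k in sub:
                    if k not in schema:
                        raise ConfigurationError(f"unknown config key {key}.{k}")
        self.raw = raw

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def section(self, name: str) -> dict:
        v = self.raw.get(name) or {}
        return dict(v) if isinstance(v, dict) else v

    def resolved(self, seed: int) -> dict:
        out = json.loads(json.dumps(self.raw, default=str))
        out["seed"] = seed
        return out


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % 2**31)


def _default_trainer(X, labels, weights):
    """Plain (non-stepwise) logistic scorer used by the jackknife."""
    Xd = np.column_stack([np.ones(len(X)), X])
    w = np.ones(len(X)) if weights is None else weights
    beta, _, _ = sdm._irls_logistic(Xd, np.asarray(labels, float), w)
    return Xd @ beta


def run_pipeline(config: PipelineConfig, outdir, seed: int | None = None) -> dict:
    """Execute the full workflow; returns a summary dict (also written as JSON).

    Partial failure leaves completed-stage outputs in place plus a
    machine-readable ``failure.json`` naming the stage and cause.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.raw.get("seed", 0) if seed is None else seed)
    (outdir / "resolved_config.json").write_text(json.dumps(config.resolved(seed), indent=2))
    summary: dict[str, Any] = {"seed": seed, "stages": {}}
    stage = "init"
    t_all = time.time()
    try:
        # ---- inputs ------------------------------------------------------
        stage = "inputs"
        t0 = time.time()
        scfg_over = config.section("synth")
        scfg_over.pop("seed", None)
        scfg = synthdata.SynthConfig(seed=_stage_seed(seed, 0), **scfg_over)
        inputs = config.section("inputs")
        truth = None
        if inputs.get("occurrences"):
            occ = read_occurrences(inputs["occurrences"])
            stack_dir = Path(inputs["stack_dir"])
            stack = read_stack({p.stem: p for p in sorted(stack_dir.glob("*.asc"))})
        else:
            stack = synthdata.gen_climate_stack(scfg)
            truth = synthdata.gen_true_suitability(stack, scfg)
            occ = synthdata.sample_occurrences(truth, scfg)
            write_raster(truth, outdir / "true_suitability.asc")
        occ.to_csv(outdir / "occurrences.csv")
        summary["stages"]["inputs"] = {"n_records": len(occ), "seconds": time.time() - t0}

        # ---- split -------------------------------------------------------
        stage = "split"
        sp = config.section("split")
        train_band = tuple(sp.get("train_band", DEFAULT_TRAIN_BAND))
        test_bands = [tuple(b) for b in sp.get("test_bands", DEFAULT_TEST_BANDS)]
        train, test = split_by_longitude(occ, train_band, test_bands)
        split_kind = "longitude_bands"
        if len(test) < 10:
            logger.warning("geographic split left %d validation records; "
                           "falling back to a random 25%% holdout", len(test))
            from .geodata import holdout_split

            train, test = holdout_split(occ, 0.25, _stage_seed(seed, 9))
            split_kind = "random_holdout"
        summary["stages"]["split"] = {"n_train": len(train), "n_test": len(test),
                                      "kind": split_kind}

        # ---- variable selection -----------------------------------------
        stage = "select"
        t0 = time.time()
        sel = config.section("select")
        selected = stack.names
        if sel.get("enabled", True):
            rng = np.random.default_rng(_stage_seed(seed, 1))
            density = sdm.record_density(train, stack.geometry)
            bg = sdm.sample_background(density, min(500, 4 * len(train)), rng)
            corr = varselect.pearson_matrix(stack)
            ft = sdm.build_feature_table(stack, np.column_stack([train.lon, train.lat]),
                                         bg, quadratic=False)
            imp = varselect.jackknife_importance(
                _default_trainer, ft.X, ft.layer_names, ft.labels, ft.weights)
            selected = varselect.select_uncorrelated(corr, imp, sel.get("r_max", 0.7))
            imp.table.to_csv(outdir / "importance.csv", index=False)
        stack = stack.subset(selected)
        summary["stages"]["select"] = {"selected": selected, "seconds": time.time() - t0}

        # ---- ensemble fit ------------------------------------------------
        stage = "ensemble"
        t0 = time.time()
        ecfg = config.section("ensemble")
        result = ens.run_ensemble(
            stack, train,
            models=tuple(ecfg.get("models", ens.DEFAULT_MODELS)),
            replicates=int(ecfg.get("replicates", ens.DEFAULT_REPLICATES)),
            seed=_stage_seed(seed, 2),
            n_background=int(ecfg.get("n_background", 1000)),
            quadratic=bool(ecfg.get("quadratic", True)),
            kernel_sd=ecfg.get("kernel_sd"),
            consensus_rule=ecfg.get("consensus_rule", "tss_weighted"),
            model_params=ecfg.get("model_params"),
        )
        write_raster(result.consensus, outdir / "consensus.asc")
        write_raster(result.weight_surface, outdir / "weight_surface.asc")
        result.member_table().to_csv(outdir / "members.csv", index=False)
        (outdir / "members.json").write_text(json.dumps(
            [{"kind": m.kind, "replicate": m.replicate, "tss": m.report.tss,
              "fit": json.loads(sdm.fit_to_json(m.fit))} for m in result.members]))
        summary["stages"]["ensemble"] = {
            "n_members": len(result.members), "seconds": time.time() - t0}

        # ---- evaluation & classification --------------------------------
        stage = "evaluate"
        rng = np.random.default_rng(_stage_seed(seed, 3))
        density = sdm.record_density(train, stack.geometry)
        eval_bg = sdm.sample_background(density, 1000, rng)
        report = ens.evaluate_on_split(result.consensus, test, eval_bg)
        result.consensus_report = report
        classes, areas = ens.classify_suitability(
            result.consensus, report.threshold,
            config.section("classify").get("marginal_fraction", 0.5))
        write_raster(classes, outdir / "classes.asc")
        areas.to_csv(outdir / "class_areas.csv", index=False)
        test_scores = sdm.predict_at(result.members[0].fit, stack,
                                     np.column_stack([test.lon, test.lat]))
        cons_test = ens._grid_scores_at(result.consensus,
                                        np.column_stack([test.lon, test.lat]))
        pct_high = 100.0 * float(np.nanmean(cons_test >= report.threshold))
        eval_out = report.to_dict() | {"pct_test_records_high_class": pct_high}
        if truth is not None:
            from scipy.stats import spearmanr

            ok = ~truth.nodata_mask & ~result.consensus.nodata_mask
            rho = float(spearmanr(truth.values[ok], result.consensus.values[ok]).statistic)
            eval_out["spearman_vs_truth"] = rho
        (outdir / "evaluation.json").write_text(json.dumps(eval_out, indent=2))
        summary["stages"]["evaluate"] = eval_out

        # ---- scenario projection ----------------------------------------
        stage = "project"
        scen_rows = []
        for scn in config.raw.get("scenarios") or []:
            scenario = project.Scenario(
                name=scn["name"],
                stack=project.perturb_stack(stack, scn.get("offsets", {})),
                horizon=int(scn.get("horizon", 2050)),
                rcp=float(scn.get("rcp", 4.5)),
            )
            cgrid, cls, area = project.project_scenario(
                result, scenario, report.threshold,
                config.section("classify").get("marginal_fraction", 0.5))
            write_raster(cgrid, outdir / f"scenario_{scenario.name}.asc")
            trans, gained, lost = project.change_summary(classes, cls)
            trans.to_csv(outdir / f"transition_{scenario.name}.csv")
            scen_rows.append(area)
        if scen_rows:
            pd.concat(scen_rows).to_csv(outdir / "scenario_areas.csv", index=False)
        summary["stages"]["project"] = {"n_scenarios": len(scen_rows)}

        # ---- hotspots ----------------------------------------------------
        stage = "hotspot"
        hcfg = config.section("hotspot")
        if hcfg.get("enabled", True):
            vg = interpolate.Variogram(slope=hcfg.get("variogram_slope", 1.0),
                                       nugget=hcfg.get("variogram_nugget", 0.0))
            years = hcfg.get("years") or sorted(occ.records.year.unique().tolist())
            surfaces = {}
            for yr in years:
                surf = interpolate.hotspot_surface(occ, int(yr), stack.geometry, vg)
                surfaces[int(yr)] = surf
                if not surf.nodata_mask.all():
                    write_raster(surf, outdir / f"hotspot_{yr}.asc")
            yrs = [y for y in sorted(surfaces) if not surfaces[y].nodata_mask.all()]
            for a, b in zip(yrs, yrs[1:]):
                change = interpolate.hotspot_change(
                    surfaces[a], surfaces[b], hcfg.get("high_quantile", 0.9))
                write_raster(change, outdir / f"hotspot_change_{a}_{b}.asc")
            summary["stages"]["hotspot"] = {"years": yrs}

        # ---- station OLS/GWR --------------------------------------------
        stage = "gwr"
        gcfg = config.section("gwr")
        if gcfg.get("enabled", True):
            gseed = _stage_seed(seed, 4)
            g_scfg = dataclasses.replace(scfg, seed=gseed)
            year = int(gcfg.get("year", 2009))
            stations, infest = synthdata.gen_station_series(
                g_scfg, int(gcfg.get("n_stations", 150)),
                int(gcfg.get("n_days", 365)), year=year)
            locs = infest[["longitude", "latitude"]].to_numpy()
            dm = spatialreg.climate_to_locations(
                stations, locs, year, response=infest["infestation"].to_numpy())
            dm, removed = spatialreg.screen_vif(dm, gcfg.get("vif_max", spatialreg.DEFAULT_VIF_MAX))
            ols = spatialreg.fit_ols(dm)
            gwr = spatialreg.fit_gwr(dm, bandwidth=gcfg.get("bandwidth"),
                                     kernel=gcfg.get("kernel", "gaussian"))
            table = spatialreg.gwr_summary_table({year: (ols, gwr)})
            table.to_csv(outdir / "gwr_summary.csv", index=False)
            pd.DataFrame({
                "longitude": dm.coords[:, 0], "latitude": dm.coords[:, 1],
                "local_r2": gwr.local_r2,
            }).to_csv(outdir / "gwr_local_r2.csv", index=False)
            summary["stages"]["gwr"] = {
                "factors_removed": removed, "ols_r2": ols.r_squared,
                "gwr_r2": gwr.r_squared}
    except Exception as e:
        (outdir / "failure.json").write_text(json.dumps(
            {"stage": stage, "error": type(e).__name__, "message": str(e)}, indent=2))
        raise
    summary["seconds_total"] = time.time() - t_all
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
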