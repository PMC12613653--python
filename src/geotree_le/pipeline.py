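"""End-to-end pipeline driver.

Runs the full chain — inputs (generated or loaded) -> population-weighted
exposure -> stratification -> q-statistics -> Geotree -> multilevel fit ->
scenario projection — writing every stage's artifact plus a checksum
manifest. A run is a pure function of (config, seed): identical inputs
give byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .exposure import exposure_table
from .geodetector import q_table
from .geotree import build_geotree, summarize_tree, tree_to_newick, write_tree_json
from .grids import read_ascii_grid, read_zone_map, write_ascii_grid, write_zone_map
from .mlm import DEFAULT_MODEL, cross_validate, fit_mlm, stepwise_select
from .panel import read_panel, validate_panel, write_panel
from .project import decadal_change, inequality_metrics, national_le, project_regions
from .stratify import assign_strata
from . import synthetic

logger = logging.getLogger(__name__)

_CSV_FMT = "%.12g"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause

    def record(self) -> dict:
        return {"stage": self.stage, "error": type(self.cause).__name__,
                "message": str(self.cause)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(path: Path, df: pd.DataFrame, index=False) -> None:
    df.to_csv(path, index=index, float_format=_CSV_FMT)


def _write_json(path: Path, doc) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and return the manifest (also written
    to ``<out_dir>/manifest.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }

    def register(stage: str, *paths: Path):
        manifest["stages"].setdefault(stage, {})
        for p in paths:
            manifest["stages"][stage][p.name] = _sha256(p)

    # ---- stage: inputs -------------------------------------------------
    stage = "inputs"
    try:
        if config.synthetic:
            elev, pop, zones = synthetic.make_grids(
                config.n_regions, tuple(config.grid_shape),
                tuple(config.type_mix), seed=config.seed,
            )
            truth = synthetic.SyntheticTruth(seed=config.seed)
            # exposures measured on the generated rasters drive the panel,
            # so rasters and panel describe one world
            from .exposure import weighted_zonal_mean

            wdem = weighted_zonal_mean(elev, pop, zones)
            panel = synthetic.make_panel(
                truth, config.n_regions, config.years, wdem_by_region=wdem,
            )
            scenario = synthetic.make_scenario(panel, config.target_year)
            write_ascii_grid(out / "elevation.asc", elev)
            write_ascii_grid(out / "population.asc", pop)
            write_zone_map(out / "zones.asc", zones)
            synthetic.write_truth(out / "truth.json", truth)
            write_panel(out / "panel.csv", panel)
            _write_csv(out / "scenario.csv", scenario)
            register(stage, out / "elevation.asc", out / "population.asc",
                     out / "zones.asc", out / "truth.json", out / "panel.csv",
                     out / "scenario.csv")
        else:
            elev = read_ascii_grid(config.elevation_path)
            pop = read_ascii_grid(config.population_path)
            zones = read_zone_map(config.zones_path)
            panel = read_panel(config.panel_path)
            scenario = (pd.read_csv(config.scenario_path)
                        if config.scenario_path else None)
            register(stage, *(Path(p) for p in [
                config.elevation_path, config.population_path,
                config.zones_path, config.panel_path,
            ]))
    except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
        raise StageError(stage, exc) from exc

    # ---- stage: exposure -----------------------------------------------
    stage = "exposure"
    try:
        expo = exposure_table({"wdem": elev}, pop, zones)
        _write_csv(out / "exposure.csv", expo, index=True)
        register(stage, out / "exposure.csv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: stratify -----------------------------------------------
    stage = "stratify"
    try:
        strata = assign_strata(
            panel, expo["wdem"], mode=config.stratify_mode,
            env_thresholds=tuple(config.env_thresholds),
            stage_thresholds=tuple(config.stage_thresholds),
        )
        _write_csv(out / "strata.csv", strata)
        register(stage, out / "strata.csv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    work = panel.drop(columns=["env_type", "stage"], errors="ignore").merge(
        strata, on=["region", "year"], validate="one_to_one"
    )

    # ---- stage: geodetector ---------------------------------------------
    stage = "geodetector"
    try:
        qvals = q_table(work, "le", ["env_type", "stage"], config.years)
        _write_csv(out / "qvalues.csv", qvals, index=True)
        register(stage, out / "qvalues.csv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: geotree --------------------------------------------------
    stage = "geotree"
    try:
        tree = build_geotree(panel, strata)
        write_tree_json(out / "geotree.json", tree)
        (out / "geotree.nwk").write_text(tree_to_newick(tree) + "\n")
        _write_csv(out / "tree_summary.csv", summarize_tree(tree))
        register(stage, out / "geotree.json", out / "geotree.nwk",
                 out / "tree_summary.csv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: mlm -------------------------------------------------------
    stage = "mlm"
    try:
        if config.select:
            covariates, trace = stepwise_select(work, "le", groups=("env_type",
                                                                    "stage"))
            _write_json(out / "selection_trace.json", trace)
            register(stage, out / "selection_trace.json")
        else:
            covariates = config.covariates or DEFAULT_MODEL
        fit = fit_mlm(work, "le", covariates, groups=("env_type", "stage"))
        _write_json(out / "model.json", fit.to_dict())
        cv = cross_validate(work, "le", covariates,
                            n_folds=config.cv_folds, seed=config.seed)
        _write_csv(out / "cv.csv", cv, index=True)
        register(stage, out / "model.json", out / "cv.csv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: project ----------------------------------------------------
    stage = "project"
    try:
        env_types = strata.groupby("region")["env_type"].first()
        proj = project_regions(fit, scenario, env_types,
                               level=config.interval_level,
                               stage_thresholds=tuple(config.stage_thresholds))
        _write_csv(out / "projections.csv", proj)

        national = national_le(proj, level=config.interval_level)
        # national LE per observed year (population-weighted), then projection
        nat_series = {}
        for yr in config.years:
            sub = work[work["year"] == yr]
            w = sub["population"].to_numpy(float)
            nat_series[yr] = float(w @ sub["le"].to_numpy(float) / w.sum())
        nat_series[config.target_year] = national["le"]
        growth = decadal_change(pd.Series(nat_series))

        ineq = {}
        for yr in config.years:
            sub = work[work["year"] == yr]
            ineq[str(yr)] = inequality_metrics(sub["le"], sub["population"])
        ineq[str(config.target_year)] = inequality_metrics(
            proj["le_hat"], proj["population"] if "population" in proj else None
        )

        summary = {
            "national": national,
            "national_by_year": {str(k): v for k, v in nat_series.items()},
            "decadal_growth": growth.to_dict(orient="records"),
            "inequality_by_year": ineq,
            "target_year": config.target_year,
        }
        _write_json(out / "summary.json", summary)
        register(stage, out / "projections.csv", out / "summary.json")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    _write_json(out / "manifest.json", manifest)
    return manifest
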