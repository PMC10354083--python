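"""End-to-end orchestration: filter -> clip -> ALAN extraction -> grid
assignment -> per-species resampled index -> trait regression.

Every stage is a pure function of (inputs, config, master seed); the run
manifest written alongside the outputs records the configuration and seeds
needed to reproduce a run bit for bit.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .basis import SmoothSpec, default_smooths
from .checklists import (
    FilterConfig,
    FilterReport,
    clip_to_range,
    filter_checklists,
    load_range_geojson,
    read_checklists,
    resolve_counts,
)
from .exceptions import UnstableEstimateError
from .hexgrid import HexGrid
from .raster import RadianceRaster, composite_median_raster, median_radiance_at_points
from .tolerance import ToleranceEstimate, compute_tolerance_index, rank_species
from .traits import TraitModelSummary, fit_trait_model

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults mirror the standard protocol
    (300-min/5-km effort caps, 5-km grid and buffer, 100 runs, 1000-detection
    inclusion floor)."""

    checklists_path: str | Path = ""
    raster_paths: tuple[str, ...] = ()
    ranges_path: str | Path | None = None
    traits_path: str | Path | None = None
    out_dir: str | Path = "results"
    filter: FilterConfig = field(default_factory=FilterConfig)
    crs: str = "planar-km"
    grid_width_km: float = 5.0
    buffer_radius_km: float = 5.0
    n_runs: int = 100
    min_detections: int = 1000
    master_seed: int = 0
    ci_type: str = "percentile"
    pool_years: bool = False
    per_class: bool = True
    x_handling: str = "as_one"
    log_alan: bool = False
    smooths: tuple[SmoothSpec, ...] = field(default_factory=default_smooths)

    def __post_init__(self) -> None:
        for name in ("grid_width_km", "buffer_radius_km", "n_runs", "min_detections"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def prepare_covariates(
    checklists: pd.DataFrame,
    raster: RadianceRaster,
    grid: HexGrid,
    buffer_radius_km: float = 5.0,
) -> pd.DataFrame:
    """Attach buffer-median radiance, hex cell and day-of-year columns."""
    out = checklists.copy()
    out["x_alan"] = median_radiance_at_points(
        raster,
        out["lon"].to_numpy(float),
        out["lat"].to_numpy(float),
        buffer_radius_km,
    )
    q, r = grid.assign_cells(out["lon"].to_numpy(float), out["lat"].to_numpy(float))
    out["cell_q"] = q
    out["cell_r"] = r
    out["day_of_year"] = pd.to_datetime(out["date"]).dt.dayofyear.astype(float)
    return out


def assemble_species_dataset(
    prepared: pd.DataFrame, obs: pd.DataFrame, species_code: str
) -> pd.DataFrame:
    """One row per checklist for a focal species; absent -> count 0.

    ``obs`` must already have presence markers resolved
    (:func:`urbantol.checklists.resolve_counts`).
    """
    sp = obs.loc[obs["species_code"] == species_code, ["checklist_id", "count"]]
    out = prepared.merge(sp, on="checklist_id", how="left")
    out["count"] = out["count"].fillna(0.0)
    out["detection"] = out["count"] >= 1
    return out


def _manifest(config: PipelineConfig, extra: dict) -> dict:
    def enc(v):
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            return {k: enc(x) for k, x in dataclasses.asdict(v).items()}
        if isinstance(v, (tuple, list)):
            return [enc(x) for x in v]
        if isinstance(v, (Path, _dt.date)):
            return str(v)
        return v

    m = {k: enc(v) for k, v in dataclasses.asdict(config).items()}
    m["urbantol_version"] = __version__
    m.update(extra)
    return m


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and write stage outputs under ``out_dir``.

    Returns a bundle dict with the filter report, per-species tolerance
    estimates, the ranked index table and (when a trait table was given)
    the trait-model summary.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    checklists, obs = read_checklists(config.checklists_path)
    log.info("read %d checklists, %d observation rows", len(checklists), len(obs))

    filtered, report = filter_checklists(checklists, config.filter)
    log.info("filtering: %d -> %d (%s)", report.n_input, report.n_retained, report.removed)
    (out_dir / "filter_report.json").write_text(report.to_json())

    if config.ranges_path:
        polys = load_range_geojson(config.ranges_path)
        n_before = len(filtered)
        filtered = clip_to_range(filtered, polys)
        log.info("range clip: %d -> %d", n_before, len(filtered))

    rasters = [RadianceRaster.read_text(p) for p in config.raster_paths]
    raster = rasters[0] if len(rasters) == 1 else composite_median_raster(rasters)

    grid = HexGrid(config.grid_width_km, crs=config.crs)
    prepared = prepare_covariates(filtered, raster, grid, config.buffer_radius_km)
    n_no_alan = int(prepared["x_alan"].isna().sum())
    if n_no_alan:
        log.info("dropping %d checklists without radiance coverage", n_no_alan)
        prepared = prepared.loc[prepared["x_alan"].notna()].reset_index(drop=True)

    obs = resolve_counts(obs, config.x_handling)
    species = sorted(obs["species_code"].dropna().unique())

    estimates: list[ToleranceEstimate] = []
    for sp in species:
        dataset = assemble_species_dataset(prepared, obs, sp)
        try:
            est = compute_tolerance_index(
                dataset,
                sp,
                n_runs=config.n_runs,
                master_seed=config.master_seed,
                min_detections=config.min_detections,
                ci_type=config.ci_type,
                smooths=config.smooths,
                pool_years=config.pool_years,
                per_class=config.per_class,
                log_alan=config.log_alan,
            )
        except UnstableEstimateError as exc:
            log.warning("%s: %s", sp, exc)
            continue
        if est.excluded:
            log.info("%s excluded: %d detections (< %d)", sp, est.n_detections,
                     config.min_detections)
        else:
            log.info("%s: index %.4f [%.4f, %.4f] (%s)", sp, est.index,
                     est.ci_low, est.ci_high, est.classification)
        estimates.append(est)

    included = [e for e in estimates if not e.excluded]
    bundle: dict = {"filter_report": report, "estimates": estimates}
    if included:
        ranking = rank_species(estimates)
        ranking.to_csv(out_dir / "tolerance_index.csv", index=False)
        bundle["ranking"] = ranking
        log.info("%d tolerant, %d avoidant of %d included species",
                 ranking.attrs["n_tolerant"], ranking.attrs["n_avoidant"], len(ranking))
    else:
        pd.DataFrame(
            columns=["species_code", "index", "ci_low", "ci_high",
                     "classification", "runs_converged", "n_detections"]
        ).to_csv(out_dir / "tolerance_index.csv", index=False)
        log.info("no species passed the inclusion rule; empty index table written")

    if config.traits_path and included:
        traits = pd.read_csv(config.traits_path)
        idx = pd.Series(
            {e.species_code: e.index for e in included}, name="index"
        ).rename_axis("species_code")
        traits = traits[traits["species_code"].isin(idx.index)]
        summary = fit_trait_model(idx, traits)
        summary.terms.to_csv(out_dir / "trait_model_terms.csv", index=False)
        summary.anova.to_csv(out_dir / "trait_model_anova.csv", index=False)
        bundle["trait_model"] = summary
        log.info("trait model R^2 = %.4f", summary.r_squared)

    manifest = _manifest(config, {"n_species_included": len(included)})
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return bundle
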