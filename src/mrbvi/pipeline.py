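"""End-to-end pipeline: simulate/load → segment → index → evaluate → predict → map.

One :class:`RunConfig` drives the whole analysis and every stage writes its
tables under the output directory, together with a JSON manifest of the
seeds and parameters used, so a run is reproducible from the manifest
alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (
    compute_observations,
    stage_screen,
    trajectory_compare,
    trajectory_from_observations,
)
from .indices import ALL_INDICES, IndexId
from .raster import read_raster, read_rois
from .scaleup import build_stack, fit_full_model, plot_map_means, predict_map, write_yield_map
from .synthetic import SeasonConfig, SyntheticSeason, generate_season, write_season
from .yield_ml import MODEL_KINDS, YieldModelSpec, build_features, loo_predict

log = logging.getLogger("mrbvi")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_run_config"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Either ``season`` (synthetic generation) or all three of
    ``mosaic_paths``/``roi_path``/``spad_path``+``yield_path`` (measured
    inputs) must be provided.
    """

    outdir: Path
    season: SeasonConfig | None = None
    mosaic_paths: list[Path] | None = None
    roi_path: Path | None = None
    spad_path: Path | None = None
    yield_path: Path | None = None
    window: list[str] | None = None  # default: last 8 dates
    indices: list[IndexId] = field(default_factory=lambda: list(ALL_INDICES))
    models: list[str] = field(default_factory=lambda: list(MODEL_KINDS))
    scaleup_models: list[str] = field(default_factory=lambda: ["SVM"])
    model_seed: int = 0
    write_imagery: bool = False
    mask_non_green_map: bool = True


@dataclass
class PipelineResult:
    observations: pd.DataFrame
    screen_per_date: pd.DataFrame
    screen_per_index: pd.DataFrame
    trajectory: pd.DataFrame
    loo_table: pd.DataFrame
    loo_predictions: pd.DataFrame
    map_plot_means: pd.DataFrame
    manifest: dict


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (keys mirror the dataclass fields)."""
    raw = yaml.safe_load(Path(path).read_text())
    season = None
    if "season" in raw:
        season = SeasonConfig(**(raw["season"] or {}))
    return RunConfig(
        outdir=Path(raw["outdir"]),
        season=season,
        mosaic_paths=[Path(p) for p in raw.get("mosaic_paths", [])] or None,
        roi_path=Path(raw["roi_path"]) if "roi_path" in raw else None,
        spad_path=Path(raw["spad_path"]) if "spad_path" in raw else None,
        yield_path=Path(raw["yield_path"]) if "yield_path" in raw else None,
        window=raw.get("window"),
        indices=[IndexId(i) for i in raw.get("indices", [i.value for i in ALL_INDICES])],
        models=list(raw.get("models", MODEL_KINDS)),
        scaleup_models=list(raw.get("scaleup_models", ["SVM"])),
        model_seed=int(raw.get("model_seed", 0)),
        write_imagery=bool(raw.get("write_imagery", False)),
        mask_non_green_map=bool(raw.get("mask_non_green_map", True)),
    )


def _load_inputs(config: RunConfig):
    if config.season is not None:
        season = generate_season(config.season)
        if config.write_imagery:
            write_season(season, Path(config.outdir) / "season")
        return season.mosaics, season.rois, season.spad_table, season.yield_table
    if not (config.mosaic_paths and config.roi_path and config.yield_path):
        raise ValueError(
            "config must provide either a synthetic season or mosaic/roi/yield paths"
        )
    mosaics = [read_raster(p) for p in config.mosaic_paths]
    rois = read_rois(config.roi_path)
    spad = pd.read_csv(config.spad_path) if config.spad_path else None
    yields = pd.read_csv(config.yield_path)
    return mosaics, rois, spad, yields


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage and write the report bundle under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    mosaics, rois, spad_table, yield_table = _load_inputs(config)
    dates = sorted(m.date_label for m in mosaics)
    window = config.window or dates[-8:]
    log.info("pipeline: %d mosaics, %d plots, window %s", len(mosaics), len(rois), window)

    obs = compute_observations(mosaics, rois, spad_table, indices=config.indices)
    obs.to_csv(outdir / "observations.csv", index=False)
    dropped = int((obs["n_green"] == 0).sum())
    log.info("observations: %d rows, %d with zero green pixels", len(obs), dropped)

    screen = stage_screen(obs, yield_table, indices=config.indices)
    screen.per_date.to_csv(outdir / "r2_per_date.csv", index=False)
    screen.per_index.to_csv(outdir / "r2_per_index.csv")

    vi_series, spad_series = trajectory_from_observations(obs, indices=config.indices)
    trajectory = trajectory_compare(vi_series, spad_series)
    trajectory.to_csv(outdir / "trajectory_metrics.csv")

    features = build_features(obs, yield_table, window, indices=config.indices)
    loo_rows, pred_frames = [], []
    for kind in config.models:
        spec = YieldModelSpec(kind=kind, seed=config.model_seed)
        res = loo_predict(features, spec)
        loo_rows.append(
            {
                "model": kind,
                "rmse": res.result.rmse,
                "mae": res.result.mae,
                "n_folds": features.n_plots,
            }
        )
        pf = pd.DataFrame(
            {"plot_id": res.predictions.index, "model": kind,
             "truth": res.truths.values, "prediction": res.predictions.values}
        )
        pred_frames.append(pf)
        log.info("LOO %s: rmse=%.3f mae=%.3f", kind, res.result.rmse, res.result.mae)
    loo_table = pd.DataFrame(loo_rows)
    loo_table.to_csv(outdir / "loo_metrics.csv", index=False)
    loo_predictions = pd.concat(pred_frames, ignore_index=True)
    loo_predictions.to_csv(outdir / "loo_predictions.csv", index=False)

    stack = build_stack(
        mosaics, window, indices=config.indices,
        mask_non_green=config.mask_non_green_map,
    )
    map_rows = []
    for kind in config.scaleup_models:
        spec = YieldModelSpec(kind=kind, seed=config.model_seed)
        fitted = fit_full_model(features, spec)
        ymap = predict_map(stack, fitted)
        write_yield_map(ymap, outdir / f"yield_map_{kind.lower()}.tif")
        for pid, mean in plot_map_means(ymap, rois).items():
            map_rows.append({"model": kind, "plot_id": pid, "map_mean_yield": mean})
    map_plot_means = pd.DataFrame(map_rows)
    map_plot_means.to_csv(outdir / "map_plot_means.csv", index=False)

    manifest = {
        "mrbvi_version": __version__,
        "n_mosaics": len(mosaics),
        "n_plots": len(rois),
        "window": list(window),
        "indices": [IndexId(i).value for i in config.indices],
        "models": list(config.models),
        "scaleup_models": list(config.scaleup_models),
        "model_seed": config.model_seed,
        "season": dataclasses.asdict(config.season) if config.season else None,
        "dropped_zero_green": dropped,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return PipelineResult(
        observations=obs,
        screen_per_date=screen.per_date,
        screen_per_index=screen.per_index,
        trajectory=trajectory,
        loo_table=loo_table,
        loo_predictions=loo_predictions,
        map_plot_means=map_plot_means,
        manifest=manifest,
    )
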