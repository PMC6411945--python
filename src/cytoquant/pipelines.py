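"""End-to-end pipelines tying the modules together.

Each ``run_*`` function takes input paths plus a :class:`PipelineConfig`,
writes tidy CSV row tables, a summary CSV and a JSON run manifest into
an output directory, and returns the written paths.  Every run is
reproducible from its manifest: re-running with the recorded config and
seed regenerates bit-identical tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, comets, imgio, islands, kymo, preprocess, ridges, stats
from . import synthdata, tracking
from .config import PipelineConfig

log = logging.getLogger("cytoquant")


def _write_manifest(out_dir: Path, command: str, config: PipelineConfig,
                    inputs: list[str], outputs: list[str]) -> Path:
    manifest = {
        "command": command,
        "version": __version__,
        "config": config.to_dict(),
        "inputs": [str(i) for i in inputs],
        "outputs": [str(o) for o in outputs],
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path


def _summary_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["measure", "mean", "sem", "n"])


def run_comets(junction_path: str | Path, comet_path: str | Path,
               out_dir: str | Path, config: PipelineConfig) -> dict[str, Path]:
    """Fixed-image comet morphometry: segment cells from the junction
    channel, upscale + background-subtract the comet channel, detect
    particles, and summarize per-cell mean aspect ratios."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    junction = imgio.read_stack(junction_path, pixel_size=config.pixel_size)
    comet_st = imgio.read_stack(comet_path, pixel_size=config.pixel_size)
    jimg, cimg = junction.pixels, comet_st.pixels
    if junction.axes != "yx":
        jimg = preprocess.max_project(junction).pixels
    if comet_st.axes != "yx":
        cimg = preprocess.max_project(comet_st).pixels

    factor = config.preprocess.upscale_factor
    jup = preprocess.upscale(np.asarray(jimg, float), factor)
    cup = preprocess.upscale(np.asarray(cimg, float), factor)
    cup = preprocess.rolling_ball_subtract(cup, config.preprocess.comet_rolling_ball_radius)

    cells = comets.segment_cells(jup, min_cell_area=config.comets.min_cell_area * factor**2)
    particles = comets.detect_comet_particles(
        cup, cells, min_area=config.comets.min_particle_area,
        threshold_method=config.comets.threshold_method,
        fixed_threshold=config.comets.fixed_threshold,
    )
    log.info("comets: %d cells, %d particles after min_area filter",
             cells.n_cells, len(particles))
    per_cell = comets.per_cell_mean_ar(particles, cells)

    particles_df = pd.DataFrame([
        {"y": p.centroid[0], "x": p.centroid[1], "area_px2": p.area,
         "major_axis_px": p.major_axis, "minor_axis_px": p.minor_axis,
         "aspect_ratio": p.aspect_ratio, "cell": p.cell_label}
        for p in particles
    ])
    cells_df = pd.DataFrame([
        {"cell": c.cell_label, "n_comets": c.n_comets, "mean_ar": c.mean_ar}
        for c in per_cell
    ])
    rows = []
    if len(cells_df) >= 2:
        mean, sem, n = comets.condition_summary(cells_df["mean_ar"])
        rows.append({"measure": "mean_ar", "mean": mean, "sem": sem, "n": n})
    paths = {
        "particles": out_dir / "particles.csv",
        "cells": out_dir / "cells.csv",
        "summary": out_dir / "summary.csv",
    }
    particles_df.to_csv(paths["particles"], index=False)
    cells_df.to_csv(paths["cells"], index=False)
    _summary_frame(rows).to_csv(paths["summary"], index=False)
    paths["manifest"] = _write_manifest(out_dir, "comets", config,
                                        [junction_path, comet_path],
                                        [p.name for p in paths.values()])
    return paths


def run_mtdensity(image_paths: list[str | Path], out_dir: str | Path,
                  config: PipelineConfig) -> dict[str, Path]:
    """Microtubule density per image (mean of the ridge-rendered canvas)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = ridges.RidgeParams(
        sigma=config.ridge.sigma, upper_threshold=config.ridge.upper_threshold,
        lower_threshold=config.ridge.lower_threshold,
        min_length=config.ridge.min_length,
    )
    rows = []
    for path in image_paths:
        st = imgio.read_stack(path, pixel_size=config.pixel_size)
        img = st.pixels if st.axes == "yx" else preprocess.max_project(st).pixels
        density = ridges.mt_density(
            np.asarray(img, float), params,
            rolling_ball_radius=config.preprocess.mt_rolling_ball_radius,
            line_width=config.ridge.line_width,
        )
        rows.append({"image": Path(path).name, "density_au": density})
    df = pd.DataFrame(rows)
    srows = []
    if len(df) >= 2:
        mean, sem, n = stats.summarize(df["density_au"])
        srows.append({"measure": "density_au", "mean": mean, "sem": sem, "n": n})
    paths = {"densities": out_dir / "densities.csv", "summary": out_dir / "summary.csv"}
    df.to_csv(paths["densities"], index=False)
    _summary_frame(srows).to_csv(paths["summary"], index=False)
    paths["manifest"] = _write_manifest(out_dir, "mtdensity", config,
                                        list(map(str, image_paths)),
                                        [p.name for p in paths.values()])
    return paths


def run_track(movie_path: str | Path, out_dir: str | Path,
              config: PipelineConfig) -> dict[str, Path]:
    """Comet tracking: per-track speed, duration, displacement."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    movie = imgio.read_stack(movie_path, pixel_size=config.pixel_size,
                             frame_interval=config.frame_interval)
    tracks, metrics = tracking.track_movie(
        movie, sigma=config.tracking.spot_sigma,
        min_prominence=config.tracking.min_prominence,
        max_displacement=config.tracking.max_displacement,
        min_frames=config.tracking.min_frames,
    )
    log.info("track: %d tracks after min_frames filter", len(tracks))
    df = pd.DataFrame([
        {"track": i, "n_spots": len(t), "mean_speed_um_s": m.mean_speed,
         "duration_s": m.duration, "displacement_um": m.displacement,
         "path_length_um": m.path_length}
        for i, (t, m) in enumerate(zip(tracks, metrics))
    ])
    srows = []
    if len(df) >= 2:
        for col in ("mean_speed_um_s", "duration_s", "displacement_um"):
            mean, sem, n = stats.summarize(df[col])
            srows.append({"measure": col, "mean": mean, "sem": sem, "n": n})
    paths = {"tracks": out_dir / "tracks.csv", "summary": out_dir / "summary.csv"}
    df.to_csv(paths["tracks"], index=False)
    _summary_frame(srows).to_csv(paths["summary"], index=False)
    paths["manifest"] = _write_manifest(out_dir, "track", config, [str(movie_path)],
                                        [p.name for p in paths.values()])
    return paths


def run_kymo(movie_path: str | Path, regions: list[tuple[int, int, int, int]],
             out_dir: str | Path, config: PipelineConfig) -> dict[str, Path]:
    """Lateral motility: per-region mean Feret deviation from vertical."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    movie = imgio.read_stack(movie_path, pixel_size=config.pixel_size,
                             frame_interval=config.frame_interval)
    mcfg = kymo.MotilityConfig(
        stabilize=config.kymo.stabilize, window=config.kymo.window,
        stride=config.kymo.stride, axes=config.kymo.axes,
        trim_boundary=config.kymo.trim_boundary,
        ridge=kymo.streak_ridge_params(config.kymo.window,
                                       config.kymo.speed_estimate,
                                       config.kymo.feature_width),
    )
    results = kymo.region_motility(movie, [kymo.Rect(*r) for r in regions], mcfg)
    traces = pd.DataFrame([
        {"region": r.region_id, "trace": i, "deviation_deg": d}
        for r in results for i, d in enumerate(r.per_trace_deviations)
    ], columns=["region", "trace", "deviation_deg"])
    region_df = pd.DataFrame([
        {"region": r.region_id, "mean_deviation_deg": r.mean_deviation,
         "n_traces": r.n_traces}
        for r in results
    ])
    srows = []
    if len(region_df) >= 2:
        mean, sem, n = stats.summarize(region_df["mean_deviation_deg"].dropna())
        srows.append({"measure": "mean_deviation_deg", "mean": mean, "sem": sem, "n": n})
    paths = {
        "traces": out_dir / "traces.csv",
        "regions": out_dir / "regions.csv",
        "summary": out_dir / "summary.csv",
    }
    traces.to_csv(paths["traces"], index=False)
    region_df.to_csv(paths["regions"], index=False)
    _summary_frame(srows).to_csv(paths["summary"], index=False)
    paths["manifest"] = _write_manifest(out_dir, "kymo", config, [str(movie_path)],
                                        [p.name for p in paths.values()])
    return paths


def run_islands(annotation_path: str | Path, out_dir: str | Path,
                config: PipelineConfig) -> dict[str, Path]:
    """Aggregate manual island annotations into mesenchymal fractions."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    annotations = imgio.read_annotations(annotation_path)
    res = islands.mesenchymal_fraction(annotations, min_cells=config.islands.min_cells)
    log.info("islands: %d scored, %d excluded below %d cells",
             res.n_islands, res.n_excluded, config.islands.min_cells)
    srows = [{"measure": "percent_mesenchymal", "mean": res.mean,
              "sem": res.sem, "n": res.n_islands}]
    have_segments = all(a.perimeter_segments for a in annotations)
    if have_segments:
        perim = islands.perimeter_fraction(annotations)
        srows.append({"measure": "percent_perimeter_mesenchymal",
                      "mean": perim.mean, "sem": perim.sem, "n": perim.n_islands})
    paths = {"islands": out_dir / "islands.csv", "summary": out_dir / "summary.csv"}
    res.per_island.to_csv(paths["islands"], index=False)
    _summary_frame(srows).to_csv(paths["summary"], index=False)
    paths["manifest"] = _write_manifest(out_dir, "islands", config,
                                        [str(annotation_path)],
                                        [p.name for p in paths.values()])
    return paths


def run_qpcr(ct_path: str | Path, out_dir: str | Path,
             config: PipelineConfig) -> dict[str, Path]:
    """2^-ddCt fold changes from a Ct table CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(ct_path)
    folds = stats.ddct_fold_change(table, per_replicate=True)
    paths = {"folds": out_dir / "fold_changes.csv"}
    folds.to_csv(paths["folds"], index=False)
    paths["manifest"] = _write_manifest(out_dir, "qpcr", config, [str(ct_path)],
                                        [p.name for p in paths.values()])
    return paths


def run_simulate(kind: str, out_dir: str | Path,
                 config: PipelineConfig, **overrides) -> dict[str, Path]:
    """Generate a synthetic dataset with its ground truth.

    ``kind`` is one of filaments / comet_field / comet_movie /
    drift_movie; ``overrides`` are forwarded to the generator.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = overrides.pop("seed", config.seed)
    paths: dict[str, Path] = {}
    if kind == "filaments":
        stack, truth = synthdata.gen_filaments(
            overrides.pop("n_filaments", 20), seed=seed, **overrides)
        paths["image"] = imgio.write_stack(stack, out_dir / "filaments.tif")
    elif kind == "comet_field":
        junction, comet_img, truth = synthdata.gen_comet_field(seed=seed, **overrides)
        paths["junction"] = imgio.write_stack(junction, out_dir / "junction.tif")
        paths["comets"] = imgio.write_stack(comet_img, out_dir / "comets.tif")
    elif kind == "comet_movie":
        movie, truth = synthdata.gen_comet_movie(seed=seed, **overrides)
        paths["movie"] = imgio.write_stack(movie, out_dir / "comet_movie.tif")
    elif kind == "drift_movie":
        movie, truth = synthdata.gen_drift_movie(seed=seed, **overrides)
        paths["movie"] = imgio.write_stack(movie, out_dir / "drift_movie.tif")
    else:
        raise ValueError(f"unknown simulation kind {kind!r}")
    paths["truth"] = truth.to_json(out_dir / "truth.json")
    paths["manifest"] = _write_manifest(out_dir, f"simulate:{kind}", config, [],
                                        [p.name for p in paths.values()])
    return paths
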