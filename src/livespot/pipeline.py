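"""Config-driven orchestration of the analysis stages.

A run config is a plain mapping (usually parsed from YAML) with one block
per stage plus a global ``seed`` and ``outdir``.  ``run_pipeline`` executes
the requested stages in order and writes every artifact plus a JSON run
report carrying versions, parameters, seeds and headline numbers — enough
to re-execute the run identically.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

import livespot
from livespot import io, kinetics, linker, localize, mobility, quantify, synth

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_config"]


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def _require(cfg: dict, key: str, stage: str):
    if key not in cfg:
        raise ValueError(f"config stage {stage!r}: missing required field {key!r}")
    return cfg[key]


def run_pipeline(config: dict, outdir: str | Path | None = None) -> dict:
    """Execute the stages named in ``config['stages']`` and write a run report.

    Supported stages: ``simulate``, ``localize``, ``track``, ``msd``,
    ``frap``, ``spr``, ``runoff``, ``embryo``.  Later stages consume the
    in-memory products of earlier ones when their input paths are omitted.
    Returns the report dict (also written to ``<outdir>/report.json``).
    """
    outdir = Path(outdir or config.get("outdir", "livespot_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", [])
    report: dict = {"livespot_version": livespot.__version__, "seed": seed, "stages": {}, "config": config}
    state: dict = {}

    for stage in stages:
        params = dict(config.get(stage, {}))
        logger.info("running stage %s", stage)
        if stage == "simulate":
            model = synth.MotionModel(
                kind=params.get("kind", "brownian"),
                D=params.get("D", 0.1),
                jitter_sd=params.get("jitter_sd", 0.03),
            )
            tracks = synth.make_tracks(
                model,
                n_tracks=int(params.get("n_tracks", 50)),
                n_frames=int(params.get("n_frames", 50)),
                dt=float(params.get("dt", 1.0)),
                bounds=tuple(params.get("bounds", (10.0, 10.0))),
                seed=seed,
            )
            optics = synth.Optics(**params.get("optics", {}))
            movie = synth.render_movie(tracks, optics, seed=seed + 1)
            io.write_table(outdir / "truth_tracks.csv", tracks)
            io.write_movie(outdir / "movie.tif", movie)
            state["movie"], state["truth"], state["optics"] = movie, tracks, optics
            report["stages"]["simulate"] = {"n_tracks": int(tracks.track_id.nunique()), **params}
        elif stage == "localize":
            movie = state.get("movie")
            if "movie" in params:
                movie = io.read_movie(params["movie"])
            if movie is None:
                raise ValueError("localize: no movie available (run simulate or set movie:)")
            locs = localize.localize_movie(
                movie,
                channel=int(params.get("channel", 0)),
                threshold=params.get("threshold", "mean_sd"),
                min_area=int(params.get("min_area", 3)),
            )
            io.write_table(outdir / "localizations.csv", locs)
            state["locs"], state["movie"] = locs, movie
            report["stages"]["localize"] = {"n_localizations": int(len(locs))}
        elif stage == "track":
            locs = state.get("locs")
            if "localizations" in params:
                locs = io.read_table(params["localizations"])
            if locs is None:
                raise ValueError("track: no localizations available")
            tracks = linker.link_nearest_neighbor(
                locs,
                max_disp_um=float(params.get("max_disp_um", 1.5)),
                memory_frames=int(params.get("memory_frames", 0)),
            )
            if params.get("bound_filter", False):
                tracks = linker.filter_bound(
                    tracks,
                    linker.BoundFilterParams(
                        min_length_frames=int(params.get("min_length_frames", 16)),
                        max_jump_nm=float(params.get("max_jump_nm", 220.0)),
                    ),
                )
            io.write_table(outdir / "tracks.csv", tracks)
            io.write_table(outdir / "track_summary.csv", linker.track_jump_stats(tracks))
            state["tracks"] = tracks
            report["stages"]["track"] = {"n_tracks": int(tracks.track_id.nunique()) if len(tracks) else 0}
        elif stage == "msd":
            tracks = state.get("tracks")
            if "tracks" in params:
                tracks = io.read_table(params["tracks"])
            if tracks is None or not len(tracks):
                raise ValueError("msd: no tracks available")
            dt = float(params.get("frame_interval_s", getattr(state.get("movie"), "frame_interval_s", 1.0)))
            curve = mobility.ensemble_msd(tracks, int(params.get("max_lag_frames", 10)), dt)
            fit = mobility.fit_diffusion(curve, int(params.get("n_points", 5)))
            io.write_table(outdir / "msd.csv", curve.to_frame())
            (outdir / "diffusion_fit.json").write_text(json.dumps(asdict(fit), indent=2))
            state["msd"], state["diffusion"] = curve, fit
            report["stages"]["msd"] = {"D_um2_s": fit.D, "ci95": fit.ci95, "n_tracks": curve.n_tracks}
        elif stage == "frap":
            trace = synth.make_frap_trace(
                k=float(params.get("k", math.log(2) / 141.0)),
                mobile_fraction=float(params.get("mobile_fraction", 1.0)),
                bleach_depth=float(params.get("bleach_depth", 0.6)),
                noise_sd=float(params.get("noise_sd", 0.0)),
                seed=seed,
            )
            norm = kinetics.normalize_frap(trace)
            fit = kinetics.fit_frap(norm, model=params.get("model", "single"))
            io.write_table(outdir / "frap_normalized.csv", norm)
            (outdir / "frap_fit.json").write_text(json.dumps(asdict(fit), indent=2))
            report["stages"]["frap"] = {"t_half_s": fit.t_half_s, "mobile_fraction": fit.mobile_fraction}
        elif stage == "spr":
            k_on = float(params.get("k_on", 1e5))
            k_off = float(params.get("k_off", 1.47e-3))
            concs = [float(c) * 1e-9 for c in params.get("concentrations_nM", [100, 30])]
            noise = float(params.get("noise_sd", 0.0))
            traces = [
                synth.make_sensorgram(k_on, k_off, float(params.get("R_max", 100.0)), c, noise_sd=noise, seed=seed + i)
                for i, c in enumerate(concs)
            ]
            fit = kinetics.fit_binding(traces)
            (outdir / "binding_fit.json").write_text(json.dumps(asdict(fit), indent=2))
            report["stages"]["spr"] = {"K_D_nM": fit.K_D * 1e9, "k_on": fit.k_on, "k_off": fit.k_off}
        elif stage == "runoff":
            scene = synth.RunoffScene(**params.get("scene", {}))
            optics = synth.Optics(**params.get("optics", {"field_px": (96, 96), "frame_interval_s": 10.0}))
            movie, truth = synth.make_runoff_scene(scene, optics, seed=seed)
            counts = quantify.spot_counts(truth, scene.n_frames, optics.frame_interval_s)
            curve = quantify.runoff_curve(counts, scene.drug_time_s)
            io.write_table(outdir / "runoff_curve.csv", curve)
            report["stages"]["runoff"] = {"n_cells": scene.n_cells}
        elif stage == "embryo":
            movie, truth = synth.make_embryo_sequence(
                n_start_nuclei=int(params.get("n_start_nuclei", 4)),
                division_period_frames=int(params.get("division_period_frames", 10)),
                n_frames=int(params.get("n_frames", 25)),
                seed=seed,
            )
            labelings = [quantify.segment_nuclei(movie.frame(t, 0)) for t in range(movie.n_frames)]
            probe = [movie.frame(t, 1) for t in range(movie.n_frames)]
            lineages = quantify.track_nuclei(labelings, probe)
            series = quantify.nucleus_count_series(lineages)
            io.write_table(outdir / "embryo_lineages.csv", lineages)
            io.write_table(outdir / "embryo_series.csv", series)
            report["stages"]["embryo"] = {
                "final_count": int(series["count"].iloc[-1]),
                "final_mean_ratio": float(series["mean_ratio"].iloc[-1]),
            }
        else:
            raise ValueError(f"unknown stage {stage!r}")

    (outdir / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, pd.DataFrame):
        return f"<table {obj.shape}>"
    return obj
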