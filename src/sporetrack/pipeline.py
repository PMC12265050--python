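"""End-to-end orchestration: simulate -> localize -> track -> analyze.

A run is described by a single config mapping (typically loaded from
YAML). Stages communicate through documented file formats written into
the output directory, so any stage can be replaced by externally
produced files; a machine-readable ``report.json`` records every
parameter, the seed, the package version, a hash of the config, and
per-stage counts. Identical config + seed reproduces identical results.

Defaults mirror the measurement conditions the analysis assumes:
pixel size 0.16 um, frame interval 0.1 s (10 Hz), 4 MSD lags,
1,000 bootstrap samples, immobile classification window 0.4 - 1.2 s.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .movie import read_movie, write_movie
from .simulate import (MOBILITY_PRESETS, SimulationConfig, render_movie,
                       simulate_trajectories, trajectories_to_dataframe)
from .localization import localize_movie
from .tracking import (link_trajectories, trajectory_filter,
                       trajectories_from_dataframe,
                       trajectories_to_dataframe as tracks_to_dataframe)
from .mobility import summarize_population
from .morphology import segment_cells, shape_metrics, population_lw
from .muropeptide import (Chromatogram, assign_labels, anhydro_fraction,
                          detect_and_integrate_peaks, relative_abundances)

__all__ = ["run_pipeline", "load_config", "DEFAULTS"]

DEFAULTS: dict = {
    "seed": 0,
    "stages": ["simulate", "analyze"],
    "simulate": {
        "preset": None,                 # name in MOBILITY_PRESETS, or None
        "n_particles": 500,
        "immobile_fraction": 0.0,
        "d_mobile": 2.62e-2,
        "frame_interval": 0.1,
        "pixel_size": 0.16,
        "loc_noise_sd": 0.015,
        "track_length_frames": 12,
        "field_size": [64, 64],
        "activation_spacing_frames": 0.0,
        "render_movie": False,
        "psf_sigma": 0.13,
        "photons_per_spot": 400.0,
        "background": 10.0,
        "read_noise_sd": 2.0,
    },
    "localize": {"min_snr": 6.0, "min_separation_px": 3,
                 "window_halfwidth_px": 3},
    "track": {"max_link_distance": 0.4, "allow_gap_frames": 0,
              "min_duration": 0.4, "classification_window": 1.2},
    "analyze": {"pixel_size": 0.16, "n_lags": 4, "n_bootstrap": 1000,
                "fit_mode": "through_origin"},
    "morphology": {"image": None, "pixel_size": 0.16, "min_area_px": 30},
    "muropeptides": {"chromatograms": [], "windows": {},
                     "min_prominence": 0.01},
}


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Merge YAML config (optional) and overrides onto the defaults."""
    cfg = json.loads(json.dumps(DEFAULTS))   # deep copy
    for source in (yaml.safe_load(Path(path).read_text()) if path else None,
                   overrides):
        if not source:
            continue
        for key, val in source.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the selected stages and write outputs + report.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = load_config(overrides=config) if config is not DEFAULTS else config
    seed = int(cfg.get("seed", 0))
    stages = list(cfg["stages"])
    report: dict = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "stages": stages,
        "parameters": cfg,
        "counts": {},
    }

    ground_truth = None
    movie = None
    localizations = None
    tracks = None

    if "simulate" in stages:
        sim = cfg["simulate"]
        frac, d = sim["immobile_fraction"], sim["d_mobile"]
        if sim.get("preset"):
            frac, d = MOBILITY_PRESETS[sim["preset"]]
        sc = SimulationConfig(
            n_particles=int(sim["n_particles"]),
            immobile_fraction=float(frac),
            d_mobile=float(d),
            frame_interval=float(sim["frame_interval"]),
            pixel_size=float(sim["pixel_size"]),
            loc_noise_sd=float(sim["loc_noise_sd"]),
            track_length_frames=int(sim["track_length_frames"]),
            field_size=tuple(sim["field_size"]),
            activation_spacing_frames=float(sim["activation_spacing_frames"]),
            seed=seed,
        )
        ground_truth = simulate_trajectories(sc)
        gt_df = trajectories_to_dataframe(ground_truth)
        gt_df.to_csv(outdir / "ground_truth.csv", index=False)
        report["counts"]["simulated_tracks"] = len(ground_truth)
        if sim["render_movie"]:
            movie = render_movie(
                ground_truth,
                psf_sigma=float(sim["psf_sigma"]),
                photons_per_spot=float(sim["photons_per_spot"]),
                background=float(sim["background"]),
                read_noise_sd=float(sim["read_noise_sd"]),
                field_size=tuple(sim["field_size"]),
                pixel_size=float(sim["pixel_size"]),
                frame_interval=float(sim["frame_interval"]),
                seed=seed + 1,
            )
            write_movie(movie, outdir / "movie.tif")
            report["counts"]["movie_frames"] = movie.n_frames

    if "localize" in stages:
        if movie is None:
            movie = read_movie(cfg["localize"].get("movie")
                               or outdir / "movie.tif")
        loc = cfg["localize"]
        localizations = localize_movie(
            movie, min_snr=float(loc["min_snr"]),
            min_separation_px=int(loc["min_separation_px"]),
            window_halfwidth_px=int(loc["window_halfwidth_px"]))
        localizations.to_csv(outdir / "localizations.csv", index=False)
        report["counts"]["localizations"] = len(localizations)

    if "track" in stages:
        trk = cfg["track"]
        if localizations is None:
            localizations = pd.read_csv(trk.get("localizations")
                                        or outdir / "localizations.csv")
        dt = float(cfg["simulate"]["frame_interval"])
        tracks = link_trajectories(
            localizations, max_link_distance=float(trk["max_link_distance"]),
            allow_gap_frames=int(trk["allow_gap_frames"]), frame_interval=dt)
        tracks = trajectory_filter(
            tracks, min_duration=float(trk["min_duration"]),
            classification_window=float(trk["classification_window"]))
        tracks_to_dataframe(tracks).to_csv(outdir / "tracks.csv", index=False)
        report["counts"]["tracks"] = len(tracks)

    if "analyze" in stages:
        ana = cfg["analyze"]
        if tracks is None:
            if ground_truth is not None:
                # analyze the simulated trajectories directly
                gt_tracks = trajectories_from_dataframe(
                    trajectories_to_dataframe(ground_truth),
                    frame_interval=float(cfg["simulate"]["frame_interval"]))
                tracks = trajectory_filter(
                    gt_tracks,
                    min_duration=float(cfg["track"]["min_duration"]),
                    classification_window=float(
                        cfg["track"]["classification_window"]))
            else:
                df = pd.read_csv(ana.get("tracks") or outdir / "tracks.csv")
                tracks = trajectory_filter(trajectories_from_dataframe(
                    df, frame_interval=float(cfg["simulate"]["frame_interval"])))
        summary = summarize_population(
            tracks, pixel_size=float(ana["pixel_size"]),
            n_bootstrap=int(ana["n_bootstrap"]), seed=seed,
            n_lags=int(ana["n_lags"]), fit_mode=ana["fit_mode"])
        summary.per_track.to_csv(outdir / "per_track.csv", index=False)
        report["population"] = {
            "n_total": summary.n_total,
            "n_immobile": summary.n_immobile,
            "n_mobile_with_D": summary.n_mobile_with_D,
            "immobile_fraction_pct": summary.immobile_fraction_pct,
            "mean_D_um2_s": summary.mean_D,
            "bootstrap_sd_D_um2_s": summary.bootstrap_sd_D,
            "n_bootstrap": summary.n_bootstrap,
            "fit_mode": summary.fit_mode,
        }
        report["counts"]["analyzed_tracks"] = summary.n_total

    if "morphology" in stages:
        mor = cfg["morphology"]
        if mor["image"] is None:
            raise ValueError("morphology stage needs an input image path")
        import tifffile
        img = tifffile.imread(mor["image"])
        labels = segment_cells(img, min_area_px=int(mor["min_area_px"]))
        metrics = shape_metrics(labels, pixel_size=float(mor["pixel_size"]))
        metrics.to_csv(outdir / "shape_metrics.csv", index=False)
        report["morphology"] = population_lw(metrics)
        report["counts"]["cells"] = len(metrics)

    if "muropeptides" in stages:
        mur = cfg["muropeptides"]
        rows = []
        for path in mur["chromatograms"]:
            chrom = Chromatogram.from_csv(path)
            table = detect_and_integrate_peaks(
                chrom, min_prominence=float(mur["min_prominence"]))
            if len(table):
                if mur["windows"]:
                    table = assign_labels(table, {
                        k: tuple(v) for k, v in mur["windows"].items()})
                table = relative_abundances(table)
                table.insert(0, "sample_id", chrom.sample_id)
                rows.append(table)
        if rows:
            peaks = pd.concat(rows, ignore_index=True)
            peaks.to_csv(outdir / "peak_table.csv", index=False)
            report["muropeptides"] = {
                sid: {"n_peaks": int(len(g)),
                      "anhydro_fraction": anhydro_fraction(g)}
                for sid, g in peaks.groupby("sample_id")}
            report["counts"]["peaks"] = len(peaks)

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float))
    return report
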