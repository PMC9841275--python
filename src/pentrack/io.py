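"""File I/O and the end-to-end pipeline runner.

CSV schemas (comma-separated, dot decimal, header row, UTF-8):

* RFID reads:        time_s, tag, antenna
* detections:        frame, cls, cx, cy, w, h, conf
* ground truth:      frame, cls, cx, cy, w, h
* antenna track:     second, antenna, provenance
* point track:       second, x, y, antenna, provenance

``run_pipeline`` composes the stages into the full analysis: 1 Hz tracks
from both sensors, localization agreement, per-bird behavioral metrics with
the cohort summary, and (when ground truth is present) the detection
evaluation report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import agreement_fractions, paired_distances, time_budget_difference
from .behavior import (
    locomotion_summary,
    space_usage,
    summarize_cohort,
    zone_visits,
)
from .detection_eval import boxes_by_frame, map_over
from .errors import SchemaError
from .pen_model import (
    PenGeometry,
    build_default_geometry,
    load_geometry_config,
)
from .rfid import (
    AntennaTrack,
    build_antenna_track,
    deduplicate_reads,
    rfid_distance_series,
)
from .video import (
    PointTrack,
    build_point_track,
    correct_switches,
    downsample_to_1hz,
    pixel_distance_series,
    to_video_as_rfid,
)

__all__ = [
    "RunConfig",
    "load_geometry",
    "read_rfid_csv",
    "read_detections_csv",
    "read_gt_csv",
    "write_antenna_track_csv",
    "write_point_track_csv",
    "rfid_track_from_reads",
    "video_track_from_detections",
    "run_pipeline",
]


def load_geometry(path=None) -> PenGeometry:
    """Geometry from a JSON config file (bundled experimental pen by default)."""
    return build_default_geometry(load_geometry_config(path))


def _read_csv(path, columns) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def read_rfid_csv(path) -> pd.DataFrame:
    return _read_csv(path, ("time_s", "tag", "antenna"))


def read_detections_csv(path) -> pd.DataFrame:
    return _read_csv(path, ("frame", "cls", "cx", "cy", "w", "h", "conf"))


def read_gt_csv(path) -> pd.DataFrame:
    return _read_csv(path, ("frame", "cls", "cx", "cy", "w", "h"))


def write_antenna_track_csv(track: AntennaTrack, path) -> None:
    pd.DataFrame(
        {
            "second": np.arange(track.start_s, track.end_s),
            "antenna": ["" if a is None else a for a in track.antenna_at],
            "provenance": track.provenance_at,
        }
    ).to_csv(path, index=False)


def write_point_track_csv(track: PointTrack, geom: PenGeometry, path) -> None:
    from .pen_model import locate_antennas

    labels = locate_antennas(track.x_at, track.y_at, geom)
    pd.DataFrame(
        {
            "second": np.arange(track.start_s, track.end_s),
            "x": track.x_at,
            "y": track.y_at,
            "antenna": ["" if a is None else a for a in labels],
            "provenance": track.provenance_at,
        }
    ).to_csv(path, index=False)


def rfid_track_from_reads(
    reads: pd.DataFrame, bird: str, span: tuple[int, int]
) -> AntennaTrack:
    """Deduplicate and build the 1 Hz antenna track for one bird."""
    return build_antenna_track(deduplicate_reads(reads), bird, span)


def video_track_from_detections(
    dets: pd.DataFrame, cls: str, fps: int = 25, n_seconds: Optional[int] = None
) -> PointTrack:
    """Downsample, correct switches, and fill gaps for one tracked class."""
    boxes = downsample_to_1hz(dets, cls, fps=fps, n_seconds=n_seconds)
    boxes, prov = correct_switches(boxes)
    return build_point_track(boxes, prov, bird=cls)


@dataclass
class RunConfig:
    """Inputs, thresholds, and flags for one end-to-end analysis run."""

    rfid_csv: Optional[str] = None
    detections_csv: Optional[str] = None
    gt_csv: Optional[str] = None
    geometry_json: Optional[str] = None
    out_dir: str = "pentrack_out"
    birds: Optional[Sequence[str]] = None  # shared tag/class identifiers
    span: Optional[tuple[int, int]] = None
    fps: int = 25
    radius_px: float = 128.0
    taus_m: Sequence[float] = (0.0, 0.005, 0.05)
    exclude_defective: bool = True
    seed: int = 0


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every applicable stage and write the report bundle to ``out_dir``.

    Birds present in both the RFID log and the detection log get the full
    dual-sensor treatment (tracks, agreement, both behavior columns);
    single-sensor birds get the metrics their stream supports.  Outputs are
    deterministic for a fixed config.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom = load_geometry(cfg.geometry_json)

    reads = read_rfid_csv(cfg.rfid_csv) if cfg.rfid_csv else None
    dets = read_detections_csv(cfg.detections_csv) if cfg.detections_csv else None
    if reads is None and dets is None:
        raise ValueError("need at least one of rfid_csv / detections_csv")

    rfid_birds = sorted(reads["tag"].unique()) if reads is not None else []
    video_birds = sorted(dets["cls"].unique()) if dets is not None else []
    birds = list(cfg.birds) if cfg.birds else sorted(set(rfid_birds) | set(video_birds))

    if cfg.span is not None:
        span = (int(cfg.span[0]), int(cfg.span[1]))
    else:
        end = 0
        if reads is not None:
            end = max(end, int(np.floor(reads["time_s"].max())) + 1)
        if dets is not None:
            end = max(end, (int(dets["frame"].max()) + cfg.fps) // cfg.fps)
        span = (0, end)
    n_seconds = span[1] - span[0]

    dedup = deduplicate_reads(reads) if reads is not None else None
    results: dict = {
        "config": {
            "span": list(span),
            "fps": cfg.fps,
            "radius_px": cfg.radius_px,
            "taus_m": list(cfg.taus_m),
            "exclude_defective": cfg.exclude_defective,
            "seed": cfg.seed,
            "version": __version__,
        },
        "birds": {},
    }

    feeder_sectors = [geom.feeder_sectors[l] for l in geom.feeder_antennas]
    behavior_rows = []
    for bird in birds:
        entry: dict = {}
        r_track = v_track = var_track = None
        if dedup is not None and bird in rfid_birds:
            r_track = build_antenna_track(dedup, bird, span)
            write_antenna_track_csv(r_track, out / f"rfid_track_{bird}.csv")
        if dets is not None and bird in video_birds:
            v_track = video_track_from_detections(
                dets, bird, fps=cfg.fps, n_seconds=n_seconds
            )
            var_track = to_video_as_rfid(v_track, geom)
            write_point_track_csv(v_track, geom, out / f"video_track_{bird}.csv")

        row: dict = {"bird": bird}
        if r_track is not None:
            su = space_usage(r_track)
            d = rfid_distance_series(r_track, geom)
            fv = zone_visits(r_track, list(geom.feeder_antennas), geom)
            dv = zone_visits(r_track, geom.drinker_antenna, geom)
            row.update(
                rfid_unique_antennas=su.n_unique_antennas,
                rfid_switches=su.n_switches,
                rfid_distance_m=float(d.sum()),
                rfid_feed_visits=fv.n_visits,
                rfid_feed_s=fv.total_duration_s,
                rfid_drink_visits=dv.n_visits,
                rfid_drink_s=dv.total_duration_s,
            )
            entry["rfid_space_usage"] = su.seconds_per_antenna
        if v_track is not None:
            su = space_usage(var_track)
            loc = locomotion_summary(pixel_distance_series(v_track, geom), cfg.taus_m)
            var_d = rfid_distance_series(var_track, geom)
            fv_px = zone_visits(v_track, feeder_sectors, geom)
            fv_ant = zone_visits(var_track, list(geom.feeder_antennas), geom)
            dv = zone_visits(var_track, geom.drinker_antenna, geom)
            row.update(
                var_unique_antennas=su.n_unique_antennas,
                var_switches=su.n_switches,
                var_distance_m=float(var_d.sum()),
                var_feed_visits=fv_ant.n_visits,
                var_feed_s=fv_ant.total_duration_s,
                var_drink_visits=dv.n_visits,
                var_drink_s=dv.total_duration_s,
                px_feed_visits=fv_px.n_visits,
                px_feed_s=fv_px.total_duration_s,
            )
            for tau, total in loc.total_m_by_threshold.items():
                row[f"px_distance_m_tau{tau:g}"] = total
            entry["video_as_rfid_space_usage"] = su.seconds_per_antenna
        if r_track is not None and v_track is not None:
            d_px = paired_distances(
                r_track, v_track, geom, exclude_defective_video=cfg.exclude_defective
            )
            rep = agreement_fractions(
                d_px, radius_px=cfg.radius_px, cm_per_px=geom.cm_per_px
            )
            tb = time_budget_difference(r_track, var_track, labels=geom.labels)
            entry["agreement"] = rep.to_dict()
            entry["time_budget"] = {
                "per_antenna_diff_s": tb.per_antenna_diff_s,
                "mean_s": tb.mean_s,
                "sd_s": tb.sd_s,
            }
        behavior_rows.append(row)
        results["birds"][bird] = entry

    behavior_df = pd.DataFrame(behavior_rows).set_index("bird")
    behavior_df.to_csv(out / "behavior_metrics.csv")

    cohort_tables = {}
    if {"rfid_switches", "var_switches"} <= set(behavior_df.columns):
        cohort_tables["antenna_switches"] = behavior_df[
            ["rfid_switches", "var_switches"]
        ].rename(columns={"rfid_switches": "RFID", "var_switches": "video-as-RFID"})
    dist_cols = {
        "rfid_distance_m": "RFID",
        "var_distance_m": "video-as-RFID",
        "px_distance_m_tau0": "pixel-based",
    }
    have = [c for c in dist_cols if c in behavior_df.columns]
    if len(have) > 1:
        cohort_tables["distance_m"] = behavior_df[have].rename(columns=dist_cols)
    if cohort_tables:
        decimals = {"antenna_switches": 0, "distance_m": 2}
        results["cohort"] = summarize_cohort(cohort_tables, decimals)

    if cfg.gt_csv and dets is not None:
        gt = read_gt_csv(cfg.gt_csv)
        preds = boxes_by_frame(dets[dets["frame"].isin(gt["frame"].unique())])
        report = map_over(preds, boxes_by_frame(gt, with_conf=False))
        results["eval"] = report.to_dict()
        with open(out / "eval_report.json", "w") as fh:
            json.dump(results["eval"], fh, indent=2, default=str)

    with open(out / "report.json", "w") as fh:
        json.dump(results, fh, indent=2, default=str, sort_keys=True)
    return results
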