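"""Per-frame detection streams to 1 Hz point trajectories.

Detections arrive at 25 fps per tracked class.  Three post-processing steps
bring them to the one-second resolution of the antenna grid:

1. downsampling — per class and second, keep the highest-confidence
   detection, unless more than 80% of the frames in that second had no
   detection, in which case the second is reported missing;
2. identity-switch correction — two consecutive retained detections with
   zero overlap against the last accepted box flag a potential switch to a
   look-alike bird, and the animal is assumed to have stayed at its previous
   location; three consecutive non-overlapping detections are taken as real
   movement and kept;
3. gap filling — missing seconds carry the last detected location forward.

The resulting point track can also be projected onto the antenna grid
("video-as-RFID") so both sensors can be compared at the same resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .detection_eval import BoundingBox, iou
from .errors import EmptyTrackError, SchemaError
from .pen_model import PenGeometry, PointPx, locate_antenna
from .rfid import AntennaTrack, DETECTED, HELD, PRE_FIRST_FIX

HELD_MISSING = "held_missing"
HELD_SWITCH = "held_switch"

DETECTION_COLUMNS = ("frame", "cls", "cx", "cy", "w", "h", "conf")

__all__ = [
    "Detection",
    "PointTrack",
    "downsample_to_1hz",
    "correct_switches",
    "build_point_track",
    "to_video_as_rfid",
    "pixel_distance_series",
]


@dataclass(frozen=True)
class Detection:
    """One detector output: frame index at the camera frame rate plus a box."""

    frame: int
    box: BoundingBox

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError("frame index must be non-negative")


@dataclass
class PointTrack:
    """1 Hz pixel locations for one tracked class with per-second provenance."""

    bird: str
    start_s: int
    end_s: int
    x_at: np.ndarray
    y_at: np.ndarray
    box_at: list
    provenance_at: np.ndarray

    def __len__(self) -> int:
        return self.end_s - self.start_s

    @property
    def located(self) -> np.ndarray:
        return self.provenance_at != PRE_FIRST_FIX


def downsample_to_1hz(
    dets: pd.DataFrame, cls: str, fps: int = 25, n_seconds: Optional[int] = None
) -> list[Optional[BoundingBox]]:
    """Reduce a detection table to one box (or None) per second for ``cls``.

    Second ``k`` covers frames ``[fps*k, fps*(k+1))``.  The second is missing
    when strictly more than 80% of its ``fps`` frames have no detection of
    the class; otherwise the maximum-confidence detection is retained, ties
    broken by the earliest frame.
    """
    missing_cols = [c for c in DETECTION_COLUMNS if c not in dets.columns]
    if missing_cols:
        raise SchemaError(f"missing columns {missing_cols}")
    if n_seconds is None:
        max_frame = int(dets["frame"].max()) if len(dets) else -1
        n_seconds = (max_frame + fps) // fps if max_frame >= 0 else 0
    df = dets[dets["cls"] == cls]
    out: list[Optional[BoundingBox]] = [None] * n_seconds
    if not len(df):
        return out
    sec = df["frame"].to_numpy() // fps
    frames_present = df.groupby(sec)["frame"].nunique()
    best = (
        df.assign(_sec=sec)
        .sort_values(["_sec", "conf", "frame"], ascending=[True, False, True], kind="stable")
        .groupby("_sec", sort=True)
        .first()
    )
    cutoff = 0.8 * fps
    for s, row in best.iterrows():
        s = int(s)
        if s >= n_seconds:
            continue
        if fps - int(frames_present[s]) > cutoff:
            continue  # missing second
        out[s] = BoundingBox(
            cx=float(row["cx"]),
            cy=float(row["cy"]),
            w=float(row["w"]),
            h=float(row["h"]),
            cls=cls,
            conf=float(row["conf"]),
        )
    return out


def correct_switches(
    boxes: Sequence[Optional[BoundingBox]],
) -> tuple[list[Optional[BoundingBox]], list[Optional[str]]]:
    """Suppress short identity switches in a per-second box sequence.

    A retained box overlapping (IOU > 0) the last accepted box is accepted
    and becomes the new reference.  Non-overlapping boxes are buffered: if
    overlap with the reference resumes while at most two are buffered, the
    buffered seconds are replaced by the reference box (provenance
    ``held_switch``); once three consecutive non-overlapping boxes
    accumulate they are all accepted as genuine movement and the newest
    becomes the reference.  Missing seconds pass through untouched and do
    not interrupt a buffered run.  The operation is idempotent.
    """
    out = list(boxes)
    prov: list[Optional[str]] = [
        None if b is None else DETECTED for b in boxes
    ]
    ref: Optional[BoundingBox] = None
    buffer: list[int] = []
    for i, b in enumerate(boxes):
        if b is None:
            continue
        if ref is None:
            ref = b
            continue
        if iou(b, ref) > 0.0:
            for j in buffer:  # switch confirmed: restore previous location
                out[j] = ref
                prov[j] = HELD_SWITCH
            buffer = []
            ref = b
        else:
            buffer.append(i)
            if len(buffer) == 3:  # sustained: accept as movement
                buffer = []
                ref = b
    for j in buffer:  # stream ended inside a potential switch
        out[j] = ref
        prov[j] = HELD_SWITCH
    return out, prov


def build_point_track(
    boxes: Sequence[Optional[BoundingBox]],
    provenance: Optional[Sequence[Optional[str]]] = None,
    bird: str = "",
    start_s: int = 0,
) -> PointTrack:
    """Fill missing seconds by carrying the last location forward.

    ``provenance`` is the per-second output of :func:`correct_switches`;
    when omitted every present box counts as ``detected``.  Leading missing
    seconds carry no location (``pre_first_fix``).
    """
    n = len(boxes)
    if provenance is None:
        provenance = [None if b is None else DETECTED for b in boxes]
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    box_at: list = [None] * n
    prov = np.empty(n, dtype=object)
    last: Optional[BoundingBox] = None
    for k in range(n):
        b = boxes[k]
        if b is not None:
            last = b
            x[k], y[k] = b.cx, b.cy
            box_at[k] = b
            prov[k] = provenance[k]
        elif last is not None:
            x[k], y[k] = last.cx, last.cy
            box_at[k] = last
            prov[k] = HELD_MISSING
        else:
            prov[k] = PRE_FIRST_FIX
    if last is None:
        raise EmptyTrackError(f"no detections at all for {bird!r}")
    return PointTrack(bird, start_s, start_s + n, x, y, box_at, prov)


def to_video_as_rfid(track: PointTrack, geom: PenGeometry) -> AntennaTrack:
    """Project a point track onto the antenna grid (video-as-RFID).

    Each second's point is assigned to the antenna containing it; points
    outside the grid (bird near the wall, or in a seam) count as missing and
    hold the last in-grid antenna.  Seconds before the first in-grid fix are
    ``pre_first_fix``.
    """
    n = len(track)
    antenna_at = np.empty(n, dtype=object)
    provenance_at = np.empty(n, dtype=object)
    last = None
    for k in range(n):
        if track.provenance_at[k] == PRE_FIRST_FIX:
            label = None
        else:
            label = locate_antenna(PointPx(track.x_at[k], track.y_at[k]), geom)
        if label is not None:
            src_detected = track.provenance_at[k] == DETECTED
            antenna_at[k] = label
            provenance_at[k] = DETECTED if src_detected else HELD
            last = label
        elif last is not None:
            antenna_at[k] = last
            provenance_at[k] = HELD
        else:
            antenna_at[k] = None
            provenance_at[k] = PRE_FIRST_FIX
    return AntennaTrack(track.bird, track.start_s, track.end_s, antenna_at, provenance_at)


def pixel_distance_series(track: PointTrack, geom: PenGeometry) -> np.ndarray:
    """Per-second movement in meters between consecutive located points.

    Pixel displacements are scaled by the global conversion factor
    (``cm_per_px`` / 100).
    """
    mask = track.located
    if mask.sum() < 2:
        raise EmptyTrackError("need at least two located seconds")
    x = track.x_at[mask]
    y = track.y_at[mask]
    return np.hypot(np.diff(x), np.diff(y)) * geom.cm_per_px / 100.0
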