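"""Localization agreement between the RFID grid and video.

Two complementary views of how well the sensors agree on where a bird is:

* paired distances — per shared second, the pixel distance between the RFID
  antenna's center point and the video bounding-box center, summarized by
  the fraction of seconds within the mean radius of the antennas' enclosing
  circle (same location at grid resolution) and within twice that radius
  (at most one antenna apart);
* time budgets — per antenna, the difference in total seconds the two
  systems place the bird there, after projecting video onto the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SpanError
from .pen_model import PenGeometry, PointPx, locate_antenna
from .rfid import AntennaTrack, PRE_FIRST_FIX
from .video import PointTrack

__all__ = [
    "AgreementReport",
    "TimeBudgetDiff",
    "paired_distances",
    "agreement_fractions",
    "time_budget_difference",
]


@dataclass
class AgreementReport:
    """Summary of paired per-second location differences."""

    n_pairs: int
    mean_px: float
    mean_cm: float
    frac_within_radius: float
    frac_within_one_antenna: float
    histogram_edges_px: np.ndarray
    histogram_counts: np.ndarray
    radius_px: float

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "mean_px": self.mean_px,
            "mean_cm": self.mean_cm,
            "frac_within_radius": self.frac_within_radius,
            "frac_within_one_antenna": self.frac_within_one_antenna,
            "histogram_edges_px": [float(v) for v in self.histogram_edges_px],
            "histogram_counts": [int(v) for v in self.histogram_counts],
            "radius_px": self.radius_px,
        }


@dataclass
class TimeBudgetDiff:
    """Per-antenna difference in seconds (RFID minus video-as-RFID)."""

    per_antenna_diff_s: dict
    mean_s: float
    sd_s: float


def paired_distances(
    rfid: AntennaTrack,
    video: PointTrack,
    geom: PenGeometry,
    exclude_defective_video: bool = False,
) -> np.ndarray:
    """Pixel distance between the two systems' locations per shared second.

    Seconds where either system has no location yet are skipped.  With
    ``exclude_defective_video`` set, seconds whose video point falls on a
    defective antenna are excluded from the comparison (the grid could never
    report them, so the disagreement is an artifact of the broken antenna).
    """
    start = max(rfid.start_s, video.start_s)
    end = min(rfid.end_s, video.end_s)
    if end <= start:
        raise SpanError("tracks share no seconds")
    dists = []
    for s in range(start, end):
        kr = s - rfid.start_s
        kv = s - video.start_s
        if rfid.provenance_at[kr] == PRE_FIRST_FIX:
            continue
        if video.provenance_at[kv] == PRE_FIRST_FIX:
            continue
        vx, vy = video.x_at[kv], video.y_at[kv]
        if exclude_defective_video:
            label = locate_antenna(PointPx(vx, vy), geom)
            if label is not None and label in geom.defective_labels:
                continue
        c = geom.antenna(rfid.antenna_at[kr]).center_px
        dists.append(np.hypot(c.x - vx, c.y - vy))
    return np.asarray(dists, dtype=float)


def agreement_fractions(
    dists: np.ndarray,
    radius_px: float = 128.0,
    cm_per_px: float = 0.2199,
    bin_width_px: float = 64.0,
) -> AgreementReport:
    """Summarize paired distances against the enclosing-circle radius.

    ``frac_within_radius`` is the proportion of differences <= ``radius_px``
    (same location at antenna resolution); ``frac_within_one_antenna`` the
    proportion <= twice the radius (at most one antenna apart).
    """
    dists = np.asarray(dists, dtype=float)
    if dists.size == 0:
        raise ValueError("no paired distances")
    n_bins = max(1, int(np.ceil((dists.max() + 1e-9) / bin_width_px)))
    edges = np.arange(n_bins + 1) * bin_width_px
    counts, _ = np.histogram(dists, bins=edges)
    return AgreementReport(
        n_pairs=int(dists.size),
        mean_px=float(dists.mean()),
        mean_cm=float(dists.mean() * cm_per_px),
        frac_within_radius=float((dists <= radius_px).mean()),
        frac_within_one_antenna=float((dists <= 2 * radius_px).mean()),
        histogram_edges_px=edges,
        histogram_counts=counts,
        radius_px=float(radius_px),
    )


def time_budget_difference(
    rfid: AntennaTrack,
    video_as_rfid: AntennaTrack,
    labels=None,
) -> TimeBudgetDiff:
    """Per-antenna difference of total seconds: RFID minus video-as-RFID.

    Both tracks must cover the same span.  ``labels`` fixes the antenna
    universe over which the mean and standard deviation are taken (defaults
    to the union of labels either system visited).  When both systems locate
    every second, the differences sum to zero by conservation.
    """
    if (rfid.start_s, rfid.end_s) != (video_as_rfid.start_s, video_as_rfid.end_s):
        raise SpanError("tracks must cover the same span")

    def counts(track: AntennaTrack) -> dict:
        out: dict = {}
        for lbl in track.located_labels():
            out[lbl] = out.get(lbl, 0) + 1
        return out

    c_r = counts(rfid)
    c_v = counts(video_as_rfid)
    if labels is None:
        labels = sorted(set(c_r) | set(c_v))
    diff = {lbl: c_r.get(lbl, 0) - c_v.get(lbl, 0) for lbl in labels}
    values = np.array(list(diff.values()), dtype=float)
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return TimeBudgetDiff(per_antenna_diff_s=diff, mean_s=float(values.mean()), sd_s=sd)
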