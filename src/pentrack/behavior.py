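"""Behavioral metrics derived from 1 Hz tracks.

Space usage (time per antenna, unique antennas, switches), locomotion
activity (total distance moved, optionally with a minimum movement threshold
that discards sub-threshold per-second steps), and apparent feeding/drinking
behavior (visits to a feeder sector, a feeder/drinker antenna, or a union of
such zones — "apparent" because presence near the feeder does not prove
ingestion).  Imputed (held) seconds count toward all metrics, mirroring the
last-known-location convention of the pipelines.  Also provides the
cross-bird summary arithmetic used in reporting: rounded cohort means,
per-bird between-system differences, and between-bird ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import UnknownLabelError
from .pen_model import FeederSector, PenGeometry, PointPx, in_feeder_sector
from .rfid import AntennaTrack
from .video import PointTrack

__all__ = [
    "SpaceUsage",
    "LocomotionSummary",
    "ZoneVisitSummary",
    "space_usage",
    "thresholded_total_distance",
    "locomotion_summary",
    "zone_visits",
    "summarize_cohort",
    "round_half_up",
]


@dataclass
class SpaceUsage:
    """Time per antenna plus unique-antenna and switch counts for one bird."""

    seconds_per_antenna: dict
    n_unique_antennas: int
    n_switches: int


@dataclass
class LocomotionSummary:
    """Total distance moved per minimum-movement threshold."""

    total_m_by_threshold: dict
    n_terms: int


@dataclass
class ZoneVisitSummary:
    """Visit count and total dwell time for one zone."""

    n_visits: int
    total_duration_s: int


def space_usage(
    track: AntennaTrack,
    geom: Optional[PenGeometry] = None,
    include_defective: bool = True,
) -> SpaceUsage:
    """Seconds per antenna, unique antennas visited, and antenna switches.

    Held seconds count toward the held antenna.  Switches are transitions
    between differing consecutive located antennas.  With
    ``include_defective`` off, seconds on defective antennas are dropped
    from the tally before counting (requires ``geom``).
    """
    labels = track.located_labels()
    if not include_defective:
        if geom is None:
            raise ValueError("geometry required to exclude defective antennas")
        labels = np.array(
            [l for l in labels if l not in geom.defective_labels], dtype=object
        )
    seconds: dict = {}
    for lbl in labels:
        seconds[lbl] = seconds.get(lbl, 0) + 1
    switches = int(sum(1 for a, b in zip(labels, labels[1:]) if a != b))
    return SpaceUsage(
        seconds_per_antenna=seconds,
        n_unique_antennas=len(seconds),
        n_switches=switches,
    )


def thresholded_total_distance(dists, tau_m: float) -> float:
    """Total distance moved, keeping only per-second steps strictly above τ.

    The indicator is strict (d > τ), so τ = 0 drops exactly-zero steps,
    which leaves the sum unchanged.
    """
    if tau_m < 0:
        raise ValueError("threshold must be non-negative")
    d = np.asarray(dists, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    return float(d[d > tau_m].sum())


def locomotion_summary(dists, taus: Sequence[float] = (0.0, 0.005, 0.05)) -> LocomotionSummary:
    """Distance totals for a ladder of minimum movement thresholds (meters)."""
    d = np.asarray(dists, dtype=float)
    return LocomotionSummary(
        total_m_by_threshold={t: thresholded_total_distance(d, t) for t in taus},
        n_terms=int(d.size),
    )


Zone = Union[str, FeederSector, Iterable]


def _zone_mask(track, zone: Zone, geom: Optional[PenGeometry]) -> np.ndarray:
    if isinstance(zone, str):
        if not isinstance(track, AntennaTrack):
            raise TypeError("antenna-label zones need an antenna-level track")
        if geom is not None and zone not in geom.antennas:
            raise UnknownLabelError(zone)
        return np.array(
            [a == zone for a in track.antenna_at], dtype=bool
        ) & track.located
    if isinstance(zone, FeederSector):
        if not isinstance(track, PointTrack):
            raise TypeError("sector zones need a pixel-level point track")
        mask = np.zeros(len(track), dtype=bool)
        loc = track.located
        for k in range(len(track)):
            if loc[k]:
                mask[k] = in_feeder_sector(
                    PointPx(track.x_at[k], track.y_at[k]), zone
                )
        return mask
    # iterable of labels or sectors: union membership
    parts = [_zone_mask(track, z, geom) for z in zone]
    if not parts:
        raise ValueError("empty zone collection")
    return np.logical_or.reduce(parts)


def zone_visits(
    track, zone: Zone, geom: Optional[PenGeometry] = None
) -> ZoneVisitSummary:
    """Visits to a zone: maximal runs of consecutive member seconds.

    ``zone`` may be an antenna label (antenna-level track), a feeder sector
    (point track), or an iterable of either, treated as a union (e.g. the
    four feeder antennas).  No gap merging and no minimum duration are
    applied.
    """
    mask = _zone_mask(track, zone, geom)
    duration = int(mask.sum())
    entries = int(mask[0]) + int((mask[1:] & ~mask[:-1]).sum()) if len(mask) else 0
    return ZoneVisitSummary(n_visits=entries, total_duration_s=duration)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal rounding to nearest with ties going away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def summarize_cohort(
    per_bird: Mapping[str, pd.DataFrame],
    decimals: Union[int, Mapping[str, int]] = 2,
) -> dict:
    """Cross-bird reporting arithmetic over per-bird metric tables.

    ``per_bird`` maps a metric name to a table with birds as rows and
    measurement systems as columns.  For every metric the summary contains:

    * ``mean_by_system`` — cohort mean per system, rounded half-up to the
      metric's printed precision;
    * ``per_bird_system_diff`` — per bird, the difference between each
      ordered pair of systems (``"A-B"`` keys);
    * ``max_abs_system_diff`` — the largest absolute per-bird difference for
      each system pair;
    * ``between_bird_range`` — per system, max minus min across birds.
    """
    summary: dict = {}
    for metric, table in per_bird.items():
        nd = decimals[metric] if isinstance(decimals, Mapping) else decimals
        systems = list(table.columns)
        mean_by_system = {
            s: round_half_up(table[s].mean(), nd) for s in systems
        }
        per_bird_diff: dict = {}
        max_abs: dict = {}
        for i, a in enumerate(systems):
            for b in systems[i + 1 :]:
                key = f"{a}-{b}"
                d = {
                    bird: round_half_up(table.at[bird, a] - table.at[bird, b], nd)
                    for bird in table.index
                }
                per_bird_diff[key] = d
                max_abs[key] = round_half_up(max(abs(v) for v in d.values()), nd)
        between = {
            s: round_half_up(table[s].max() - table[s].min(), nd) for s in systems
        }
        summary[metric] = {
            "mean_by_system": mean_by_system,
            "per_bird_system_diff": per_bird_diff,
            "max_abs_system_diff": max_abs,
            "between_bird_range": between,
        }
    return summary
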