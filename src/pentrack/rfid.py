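"""RFID read streams to 1 Hz antenna-level trajectories.

The subfloor readers log (time, tag, antenna) triples whenever a leg tag is
registered.  The analysis works at one-second resolution: double reads inside
a second keep the first antenna received, and any second without a read
carries the last detected antenna forward (the bird is assumed to have stayed
put).  Seconds before a bird's first read carry no location and are excluded
from every downstream metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyTrackError, SchemaError
from .pen_model import PenGeometry

# provenance labels shared by antenna-level tracks
DETECTED = "detected"
HELD = "held"
PRE_FIRST_FIX = "pre_first_fix"

RFID_COLUMNS = ("time_s", "tag", "antenna")

__all__ = [
    "AntennaTrack",
    "deduplicate_reads",
    "build_antenna_track",
    "rfid_distance_series",
]


@dataclass
class AntennaTrack:
    """Per-second antenna locations for one bird with per-second provenance.

    ``antenna_at[k]`` is the location at second ``start_s + k`` (a label or
    None before the first fix); ``provenance_at[k]`` is one of ``detected``,
    ``held`` or ``pre_first_fix``.
    """

    bird: str
    start_s: int
    end_s: int
    antenna_at: np.ndarray
    provenance_at: np.ndarray

    def __post_init__(self) -> None:
        n = self.end_s - self.start_s
        if len(self.antenna_at) != n or len(self.provenance_at) != n:
            raise ValueError("sequence lengths must equal end_s - start_s")

    def __len__(self) -> int:
        return self.end_s - self.start_s

    @property
    def located(self) -> np.ndarray:
        """Boolean mask of seconds with a known location."""
        return self.provenance_at != PRE_FIRST_FIX

    def located_labels(self) -> np.ndarray:
        return self.antenna_at[self.located]


def _require_columns(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns {missing}; expected {list(cols)}")


def deduplicate_reads(reads: pd.DataFrame) -> pd.DataFrame:
    """Keep the first read per (tag, whole second); output sorted by time.

    Mirrors the logger rule for double reads: when two reads land in the same
    second, the first received antenna number is retained.
    """
    _require_columns(reads, RFID_COLUMNS)
    df = reads.sort_values("time_s", kind="stable")
    second = np.floor(df["time_s"].to_numpy(dtype=float)).astype(np.int64)
    keep = ~pd.DataFrame({"tag": df["tag"].to_numpy(), "s": second}).duplicated()
    return df.loc[keep.to_numpy()].reset_index(drop=True)


def build_antenna_track(
    reads: pd.DataFrame, bird: str, span: tuple[int, int]
) -> AntennaTrack:
    """1 Hz antenna track for one bird over ``span = (start_s, end_s)``.

    Seconds with a read are ``detected``; gaps repeat the last detected
    antenna (``held``); seconds before the first read ever received are
    ``pre_first_fix`` with no location.  Reads earlier than the span seed the
    last-known location, so a track windowed into an ongoing session starts
    ``held`` rather than unknown.
    """
    _require_columns(reads, RFID_COLUMNS)
    start_s, end_s = int(span[0]), int(span[1])
    if end_s <= start_s:
        raise ValueError("span must be non-empty")
    df = reads[reads["tag"] == bird]
    t = df["time_s"].to_numpy(dtype=float)
    order = np.argsort(t, kind="stable")
    t = t[order]
    ants = df["antenna"].to_numpy(dtype=object)[order]
    second = np.floor(t).astype(np.int64)
    in_scope = second < end_s
    if not in_scope.any():
        raise EmptyTrackError(f"no reads for bird {bird!r} before second {end_s}")
    second = second[in_scope]
    ants = ants[in_scope]

    n = end_s - start_s
    antenna_at = np.empty(n, dtype=object)
    provenance_at = np.empty(n, dtype=object)
    # seed with the latest read before the span, if any
    before = second < start_s
    last = ants[before][-1] if before.any() else None
    read_map: dict[int, object] = {}
    for s, a in zip(second[~before], ants[~before]):
        read_map.setdefault(int(s), a)  # first read of the second wins
    for k in range(n):
        s = start_s + k
        if s in read_map:
            last = read_map[s]
            antenna_at[k] = last
            provenance_at[k] = DETECTED
        elif last is not None:
            antenna_at[k] = last
            provenance_at[k] = HELD
        else:
            antenna_at[k] = None
            provenance_at[k] = PRE_FIRST_FIX
    return AntennaTrack(bird, start_s, end_s, antenna_at, provenance_at)


def rfid_distance_series(track: AntennaTrack, geom: PenGeometry) -> np.ndarray:
    """Per-second movement in meters between consecutive located antennas.

    Element ``k`` is the Euclidean distance between the center points of the
    antennas at located seconds ``k`` and ``k+1``; held seconds repeat an
    antenna and therefore contribute zeros.  Pre-first-fix seconds contribute
    nothing.
    """
    labels = track.located_labels()
    if len(labels) < 2:
        raise EmptyTrackError("need at least two located seconds")
    cx = np.array([geom.antenna(l).center_m[0] for l in labels])
    cy = np.array([geom.antenna(l).center_m[1] for l in labels])
    return np.hypot(np.diff(cx), np.diff(cy))
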