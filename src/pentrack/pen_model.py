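"""Pen geometry: antenna grid, feeder/drinker zones, and unit conversions.

The experimental pen is a 1.80 x 2.61 m floor area whose entire surface is
covered by a 6 x 5 grid of subfloor high-frequency RFID antennas (32 x 41 cm
each), labelled ``A1`` .. ``F5``.  Letters index grid rows along the long pen
side, digits index columns along the short side.  All coordinates follow the
image convention: pixels with the origin at the pen's top-left corner, x
increasing along the long (2.61 m) side, y along the short (1.80 m) side,
y pointing downward.  Physical coordinates in meters share the same axes,
scaled by ``cm_per_px / 100``.

The grid is modelled as axis-aligned, non-overlapping antenna rectangles
separated by configurable gaps (the physical grid leaves small seams between
antenna mats and a margin along the walls).  A point is assigned to the
antenna whose rectangle contains it under a half-open convention: the left
and top edges belong to the rectangle, the right and bottom edges do not, so
the assignment partitions the plane with no double counting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import numpy as np

from .errors import GeometryError, UnknownLabelError

ROW_LETTERS = "ABCDEF"

__all__ = [
    "PointPx",
    "AntennaSpec",
    "FeederSector",
    "PenGeometry",
    "DEFAULT_CONFIG",
    "load_geometry_config",
    "build_default_geometry",
    "px_to_cm",
    "locate_antenna",
    "locate_antennas",
    "in_feeder_sector",
    "antenna_center_distance_m",
]


@dataclass(frozen=True)
class PointPx:
    """A point in image coordinates (pixels, origin top-left)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError(f"non-finite point ({self.x}, {self.y})")


@dataclass(frozen=True)
class AntennaSpec:
    """One antenna of the grid: label, pixel rectangle, centers, status."""

    label: str
    left_px: float
    top_px: float
    w_px: float
    h_px: float
    center_m: tuple[float, float]
    defective: bool = False

    @property
    def center_px(self) -> PointPx:
        return PointPx(self.left_px + self.w_px / 2.0, self.top_px + self.h_px / 2.0)

    def contains(self, p: PointPx) -> bool:
        """Half-open containment: left/top edges inclusive, right/bottom exclusive."""
        return (
            self.left_px <= p.x < self.left_px + self.w_px
            and self.top_px <= p.y < self.top_px + self.h_px
        )

    @property
    def enclosing_radius_px(self) -> float:
        """Radius of the smallest circle containing the rectangle."""
        return math.hypot(self.w_px, self.h_px) / 2.0


@dataclass(frozen=True)
class FeederSector:
    """Circular sector marking the reachable area in front of a feeder opening.

    ``bisector_azimuth_deg`` is the direction the sector opens toward, in
    degrees with 0 along +x and 90 along +y (downward in image coordinates).
    """

    anchor_antenna: str
    apex_px: PointPx
    radius_px: float
    angle_deg: float
    bisector_azimuth_deg: float

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise GeometryError("sector radius must be positive")
        if not 0 < self.angle_deg <= 360:
            raise GeometryError("sector angle must be in (0, 360] degrees")


DEFAULT_CONFIG: dict = {
    # (length along x, width along y) in meters
    "pen_m": [2.61, 1.80],
    "frame_px": [1920, 1080],
    # antenna footprint (along x, along y) in cm
    "antenna_cm": [41.0, 32.0],
    "grid": [6, 5],  # letter rows along x, digit columns along y
    # optional explicit gap lists in cm: {"x": 7 values, "y": 6 values}
    # (margins + seams); None means uniform gaps filling the pen
    "gaps_cm": None,
    "cm_per_px": 0.2199,
    "feeders": ["E1", "F1", "E5", "F5"],
    "drinker": "D1",
    "defective": ["A2"],
    "feeder_sector": {"radius_px": 100.0, "angle_deg": 120.0},
    # optional per-feeder overrides: {"E1": {"azimuth_deg": ..}, ...}
    "feeder_overrides": {},
}


@dataclass(frozen=True)
class PenGeometry:
    """The pen: antenna grid, zones, and the pixel-to-physical scale."""

    pen_size_m: tuple[float, float]
    frame_size_px: tuple[int, int]
    cm_per_px: float
    antennas: Mapping[str, AntennaSpec]
    feeder_antennas: tuple[str, ...]
    drinker_antenna: str
    feeder_sectors: Mapping[str, FeederSector]
    defective_labels: frozenset[str]
    # cached grid edges for vectorized lookup
    _lefts_px: np.ndarray = field(repr=False, default=None)
    _tops_px: np.ndarray = field(repr=False, default=None)
    _cell_w_px: float = field(repr=False, default=0.0)
    _cell_h_px: float = field(repr=False, default=0.0)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.antennas)

    def antenna(self, label: str) -> AntennaSpec:
        try:
            return self.antennas[label]
        except KeyError:
            raise UnknownLabelError(label) from None

    def mean_enclosing_radius_px(self) -> float:
        """Grid mean of the antennas' enclosing-circle radii."""
        return float(np.mean([a.enclosing_radius_px for a in self.antennas.values()]))


def load_geometry_config(path=None) -> dict:
    """Load a geometry configuration JSON, defaulting to the bundled pen."""
    if path is None:
        text = resources.files("pentrack.data").joinpath("default_geometry.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(json.loads(text))
    return cfg


def _uniform_gaps(total_cm: float, n: int, a_cm: float) -> list[float]:
    free = total_cm - n * a_cm
    if free < -1e-9:
        raise GeometryError(
            f"{n} antennas of {a_cm} cm do not fit in {total_cm} cm"
        )
    return [free / (n + 1)] * (n + 1)


def build_default_geometry(config: Optional[dict] = None) -> PenGeometry:
    """Build a :class:`PenGeometry` from a configuration mapping.

    Missing keys fall back to the bundled defaults, which reproduce the
    experimental pen: 6 x 5 grid of 32 x 41 cm antennas, feeders on
    E1/F1/E5/F5, drinker on D1, antenna A2 flagged defective, and
    0.2199 cm per pixel.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)

    pen_L, pen_W = (float(v) for v in cfg["pen_m"])
    frame_w, frame_h = (int(v) for v in cfg["frame_px"])
    ax_cm, ay_cm = (float(v) for v in cfg["antenna_cm"])
    n_rows, n_cols = (int(v) for v in cfg["grid"])
    scale = float(cfg["cm_per_px"])
    if scale <= 0:
        raise GeometryError("cm_per_px must be positive")
    if n_rows > len(ROW_LETTERS):
        raise GeometryError(f"at most {len(ROW_LETTERS)} letter rows supported")

    gaps = cfg.get("gaps_cm") or {}
    gx = [float(g) for g in gaps.get("x", _uniform_gaps(pen_L * 100, n_rows, ax_cm))]
    gy = [float(g) for g in gaps.get("y", _uniform_gaps(pen_W * 100, n_cols, ay_cm))]
    if len(gx) != n_rows + 1 or len(gy) != n_cols + 1:
        raise GeometryError("gap lists must have one entry more than the grid size")

    lefts_cm = []
    pos = 0.0
    for i in range(n_rows):
        pos += gx[i]
        lefts_cm.append(pos)
        pos += ax_cm
    if pos + gx[-1] > pen_L * 100 + 1e-6:
        raise GeometryError("letter rows overflow the pen length")

    tops_cm = []
    pos = 0.0
    for j in range(n_cols):
        pos += gy[j]
        tops_cm.append(pos)
        pos += ay_cm
    if pos + gy[-1] > pen_W * 100 + 1e-6:
        raise GeometryError("digit columns overflow the pen width")

    defective = frozenset(cfg["defective"] or [])
    antennas: dict[str, AntennaSpec] = {}
    for i in range(n_rows):
        for j in range(n_cols):
            label = f"{ROW_LETTERS[i]}{j + 1}"
            left_px = lefts_cm[i] / scale
            top_px = tops_cm[j] / scale
            w_px = ax_cm / scale
            h_px = ay_cm / scale
            if left_px + w_px > frame_w + 1e-6 or top_px + h_px > frame_h + 1e-6:
                raise GeometryError(f"antenna {label} does not fit in the frame")
            cx_cm = lefts_cm[i] + ax_cm / 2.0
            cy_cm = tops_cm[j] + ay_cm / 2.0
            antennas[label] = AntennaSpec(
                label=label,
                left_px=left_px,
                top_px=top_px,
                w_px=w_px,
                h_px=h_px,
                center_m=(cx_cm / 100.0, cy_cm / 100.0),
                defective=label in defective,
            )

    for lbl in list(cfg["feeders"]) + [cfg["drinker"]]:
        if lbl not in antennas:
            raise GeometryError(f"zone label {lbl!r} not in the grid")
    for lbl in defective:
        if lbl not in antennas:
            raise GeometryError(f"defective label {lbl!r} not in the grid")

    sector_cfg = cfg["feeder_sector"]
    overrides = cfg.get("feeder_overrides") or {}
    sectors: dict[str, FeederSector] = {}
    for lbl in cfg["feeders"]:
        spec = antennas[lbl]
        c = spec.center_px
        ov = overrides.get(lbl, {})
        azimuth = ov.get("azimuth_deg")
        if azimuth is None:
            azimuth = _inward_azimuth(c, spec.center_m, pen_L, pen_W)
        apex = ov.get("apex_px")
        apex_pt = PointPx(*apex) if apex is not None else c
        sectors[lbl] = FeederSector(
            anchor_antenna=lbl,
            apex_px=apex_pt,
            radius_px=float(ov.get("radius_px", sector_cfg["radius_px"])),
            angle_deg=float(ov.get("angle_deg", sector_cfg["angle_deg"])),
            bisector_azimuth_deg=float(azimuth),
        )

    geom = PenGeometry(
        pen_size_m=(pen_L, pen_W),
        frame_size_px=(frame_w, frame_h),
        cm_per_px=scale,
        antennas=antennas,
        feeder_antennas=tuple(cfg["feeders"]),
        drinker_antenna=cfg["drinker"],
        feeder_sectors=sectors,
        defective_labels=defective,
        _lefts_px=np.array([lefts_cm[i] / scale for i in range(n_rows)]),
        _tops_px=np.array([tops_cm[j] / scale for j in range(n_cols)]),
        _cell_w_px=ax_cm / scale,
        _cell_h_px=ay_cm / scale,
    )
    _check_no_overlap(geom)
    return geom


def _inward_azimuth(c: PointPx, center_m, pen_L: float, pen_W: float) -> float:
    """Sector bisector perpendicular to the nearest pen wall, pointing inward."""
    cx, cy = center_m
    walls = [
        (cy, 90.0),           # y = 0 wall -> open toward +y
        (pen_W - cy, 270.0),  # y = W wall -> open toward -y
        (cx, 0.0),            # x = 0 wall -> open toward +x
        (pen_L - cx, 180.0),  # x = L wall -> open toward -x
    ]
    return min(walls)[1]


def _check_no_overlap(geom: PenGeometry) -> None:
    eps = 1e-6  # px; adjoining seams are not overlaps
    specs = list(geom.antennas.values())
    for i, a in enumerate(specs):
        for b in specs[i + 1 :]:
            if (
                a.left_px + eps < b.left_px + b.w_px
                and b.left_px + eps < a.left_px + a.w_px
                and a.top_px + eps < b.top_px + b.h_px
                and b.top_px + eps < a.top_px + a.h_px
            ):
                raise GeometryError(f"antennas {a.label} and {b.label} overlap")


def px_to_cm(d_px: float, geom: PenGeometry) -> float:
    """Convert a pixel distance to centimeters with the global scale factor."""
    if d_px < 0:
        raise ValueError("pixel distance must be non-negative")
    return d_px * geom.cm_per_px


def locate_antenna(p: PointPx, geom: PenGeometry) -> Optional[str]:
    """Label of the antenna whose rectangle contains ``p``, or None.

    Containment is half-open (left/top inclusive), so shared seams assign to
    exactly one antenna. Points in gaps, margins, or outside the grid return
    None — at antenna resolution such a fix counts as missing.
    """
    i = int(np.searchsorted(geom._lefts_px, p.x, side="right")) - 1
    j = int(np.searchsorted(geom._tops_px, p.y, side="right")) - 1
    if i < 0 or j < 0:
        return None
    if p.x >= geom._lefts_px[i] + geom._cell_w_px:
        return None
    if p.y >= geom._tops_px[j] + geom._cell_h_px:
        return None
    return f"{ROW_LETTERS[i]}{j + 1}"


def locate_antennas(x: np.ndarray, y: np.ndarray, geom: PenGeometry) -> np.ndarray:
    """Vectorized :func:`locate_antenna`; returns an object array of labels/None."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    i = np.searchsorted(geom._lefts_px, x, side="right") - 1
    j = np.searchsorted(geom._tops_px, y, side="right") - 1
    ok = (i >= 0) & (j >= 0)
    i_c = np.clip(i, 0, len(geom._lefts_px) - 1)
    j_c = np.clip(j, 0, len(geom._tops_px) - 1)
    ok &= x < geom._lefts_px[i_c] + geom._cell_w_px
    ok &= y < geom._tops_px[j_c] + geom._cell_h_px
    out = np.empty(x.shape, dtype=object)
    out[:] = None
    for k in np.nonzero(ok)[0]:
        out[k] = f"{ROW_LETTERS[i[k]]}{j[k] + 1}"
    return out


def in_feeder_sector(p: PointPx, sector: FeederSector) -> bool:
    """True iff ``p`` lies within the sector (apex included, edges inclusive)."""
    dx = p.x - sector.apex_px.x
    dy = p.y - sector.apex_px.y
    dist = math.hypot(dx, dy)
    if dist > sector.radius_px:
        return False
    if dist == 0.0:
        return True
    ang = math.degrees(math.atan2(dy, dx))
    diff = (ang - sector.bisector_azimuth_deg + 180.0) % 360.0 - 180.0
    return abs(diff) <= sector.angle_deg / 2.0


def antenna_center_distance_m(a: str, b: str, geom: PenGeometry) -> float:
    """Euclidean distance in meters between two antenna center points."""
    ca = geom.antenna(a).center_m
    cb = geom.antenna(b).center_m
    return math.hypot(ca[0] - cb[0], ca[1] - cb[1])
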