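"""Pen simulator: known-truth trajectories corrupted into sensor logs.

Generates per-second ground-truth bird positions in the pen and derives the
two sensor streams the pipelines consume:

* RFID read logs with state-dependent missed registrations (a moving bird's
  leg tag couples worse to the antenna field than a resting one), a leg-tag
  offset from the body center, the device's 5-second repeat of the last
  read, and silence from defective antennas;
* 25 fps detection logs with center-point jitter, per-frame dropouts,
  dropout bursts, and identity-switch episodes during which the tracked
  class's box sits on a look-alike distractor bird, plus clean ground-truth
  boxes for a sampled subset of frames.

The movement model is a two-state (rest/move) correlated random walk with
reflective pen boundaries and optional directed bouts to the feeder and
drinker zones.  It is deliberately simple: every step length is drawn from a
configured speed distribution, so realized speeds and distances can be
checked in closed form.  Within a second the bird is treated as stationary
(positions are piecewise-constant at 1 Hz), which is below the resolution of
either sensor.

The truth channel discretizes positions to antennas with the same rule the
pipelines use (containing antenna under the half-open convention, else the
last containing antenna held), so a noise-free run must be recovered exactly
by both pipelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .pen_model import PenGeometry, build_default_geometry, locate_antennas

__all__ = [
    "MoveParams",
    "RfidParams",
    "CamParams",
    "SimConfig",
    "TruthTrack",
    "SimOutput",
    "noise_free_config",
    "simulate_trajectories",
    "generate_rfid_reads",
    "generate_detections",
    "simulate",
]


@dataclass(frozen=True)
class MoveParams:
    """Two-state movement model parameters (per-second discrete time).

    Defaults describe young floor-housed broilers: mostly resting, short
    shuffling bouts, occasional directed trips to a feeder or the drinker
    followed by a dwell inside the zone.  Per-second displacement is capped
    at ``max_step_m`` so the 1 Hz sampling of a continuously moving bird
    keeps consecutive body boxes overlapping — the regime the identity-switch
    corrector is built for; sustained faster locomotion (reported up to
    ~0.3-1 m/s in older birds) is out of this model's scope.
    """

    p_rest_to_move: float = 0.05
    p_move_to_rest: float = 0.40
    speed_mean_mps: float = 0.12
    speed_sd_mps: float = 0.05
    max_step_m: float = 0.19
    heading_sd_rad: float = 0.7
    feeder_bout_rate: float = 0.002   # per second, while resting
    drinker_bout_rate: float = 0.001
    bout_dwell_mean_s: float = 60.0

    def __post_init__(self) -> None:
        for p in (self.p_rest_to_move, self.p_move_to_rest):
            if not 0.0 <= p <= 1.0:
                raise ValueError("transition probabilities must lie in [0, 1]")
        if self.speed_mean_mps < 0 or self.speed_sd_mps < 0:
            raise ValueError("speeds must be non-negative")


@dataclass(frozen=True)
class RfidParams:
    """RFID sensing model: state-dependent reads, leg offset, device hold."""

    p_read_rest: float = 0.90
    p_read_move: float = 0.50
    leg_offset_cm: float = 4.0
    device_hold_s: int = 5

    def __post_init__(self) -> None:
        for p in (self.p_read_rest, self.p_read_move):
            if not 0.0 <= p <= 1.0:
                raise ValueError("read probabilities must lie in [0, 1]")
        if self.leg_offset_cm < 0:
            raise ValueError("leg offset must be non-negative")


@dataclass(frozen=True)
class CamParams:
    """Detection stream model: jitter, dropouts, switch episodes."""

    fps: int = 25
    p_detect: float = 0.97
    jitter_sd_px: float = 3.0
    box_px: float = 90.0
    conf_beta: tuple[float, float] = (14.0, 2.0)
    dropout_rate_per_s: float = 0.002
    dropout_mean_s: float = 2.0
    switch_rate_per_s: float = 0.0005
    switch_mean_s: float = 2.0
    distractor_birds: bool = True
    n_gt_frames: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_detect <= 1.0:
            raise ValueError("detection probability must lie in [0, 1]")
        if self.jitter_sd_px < 0:
            raise ValueError("jitter must be non-negative")


@dataclass(frozen=True)
class SimConfig:
    """Full simulation configuration; every output is reproducible from it."""

    seed: int = 0
    duration_s: int = 600
    n_birds: int = 3
    tracked: Optional[tuple[str, ...]] = None  # classes with a camera stream
    move: MoveParams = field(default_factory=MoveParams)
    rfid: RfidParams = field(default_factory=RfidParams)
    cam: CamParams = field(default_factory=CamParams)
    geometry: Optional[PenGeometry] = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.n_birds < 1:
            raise ValueError("need at least one bird")

    @property
    def geom(self) -> PenGeometry:
        return self.geometry if self.geometry is not None else _DEFAULT_GEOM

    def bird_names(self) -> list[str]:
        return [f"bird{i:02d}" for i in range(self.n_birds)]

    def tracked_names(self) -> list[str]:
        if self.tracked is not None:
            return list(self.tracked)
        return self.bird_names()[: min(3, self.n_birds)]


_DEFAULT_GEOM = build_default_geometry()


def noise_free_config(seed: int = 0, duration_s: int = 600, n_birds: int = 3) -> SimConfig:
    """A configuration with every corruption channel switched off.

    Reads always succeed with no leg offset, detections are exact on every
    frame, and no antenna is defective: both pipelines must reproduce the
    truth channel exactly under this configuration.
    """
    geom = build_default_geometry({"defective": []})
    return SimConfig(
        seed=seed,
        duration_s=duration_s,
        n_birds=n_birds,
        rfid=RfidParams(p_read_rest=1.0, p_read_move=1.0, leg_offset_cm=0.0),
        cam=CamParams(
            p_detect=1.0,
            jitter_sd_px=0.0,
            dropout_rate_per_s=0.0,
            switch_rate_per_s=0.0,
        ),
        geometry=geom,
    )


@dataclass
class TruthTrack:
    """Ground truth for one bird: per-second position, state, and antenna."""

    bird: str
    x_m: np.ndarray
    y_m: np.ndarray
    moving: np.ndarray  # bool per second
    antenna_at: np.ndarray  # containing antenna, else last containing (None before first)

    def positions_px(self, geom: PenGeometry) -> tuple[np.ndarray, np.ndarray]:
        s = geom.cm_per_px / 100.0
        return self.x_m / s, self.y_m / s

    def path_distance_m(self) -> float:
        """Total length of the true per-second path."""
        return float(np.hypot(np.diff(self.x_m), np.diff(self.y_m)).sum())


@dataclass
class SimOutput:
    """Everything a pipeline test needs: the truth and both sensor streams."""

    config: SimConfig
    truth: dict
    rfid_reads: pd.DataFrame
    detections: pd.DataFrame
    gt_boxes: pd.DataFrame


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _zone_target_m(geom: PenGeometry, zone_label: str, rng) -> tuple[float, float]:
    """A point inside the zone: sector interior for feeders, antenna center else."""
    scale = geom.cm_per_px / 100.0
    if zone_label in geom.feeder_sectors:
        sec = geom.feeder_sectors[zone_label]
        r = 0.5 * sec.radius_px * rng.random()
        ang = math.radians(
            sec.bisector_azimuth_deg + (rng.random() - 0.5) * sec.angle_deg * 0.8
        )
        x = sec.apex_px.x + r * math.cos(ang)
        y = sec.apex_px.y + r * math.sin(ang)
        return x * scale, y * scale
    c = geom.antenna(zone_label).center_m
    return c


def simulate_trajectories(cfg: SimConfig) -> dict[str, TruthTrack]:
    """Simulate per-second ground-truth positions for every bird.

    Correlated random walk confined to the pen by reflection, with a
    rest/move Markov chain, truncated-normal step speeds, and directed
    feeder/drinker bouts.  Deterministic for a fixed config.
    """
    geom = cfg.geom
    rng = _rng(cfg, 0)
    L, W = geom.pen_size_m
    m = cfg.move
    out: dict[str, TruthTrack] = {}
    for bird in cfg.bird_names():
        n = cfg.duration_s
        x = np.empty(n)
        y = np.empty(n)
        moving = np.zeros(n, dtype=bool)
        px, py = rng.uniform(0.1 * L, 0.9 * L), rng.uniform(0.1 * W, 0.9 * W)
        heading = rng.uniform(0, 2 * math.pi)
        state = "rest"
        goal: Optional[tuple[float, float]] = None
        dwell = 0
        for t in range(n):
            x[t], y[t] = px, py
            if dwell > 0:  # resting inside a zone after a bout
                dwell -= 1
                continue
            if state == "rest" and goal is None:
                u = rng.random()
                if u < m.feeder_bout_rate and geom.feeder_antennas:
                    lbl = geom.feeder_antennas[rng.integers(len(geom.feeder_antennas))]
                    goal = _zone_target_m(geom, lbl, rng)
                elif u < m.feeder_bout_rate + m.drinker_bout_rate:
                    goal = _zone_target_m(geom, geom.drinker_antenna, rng)
                elif rng.random() < m.p_rest_to_move:
                    state = "move"
                    heading = rng.uniform(0, 2 * math.pi)
            elif state == "move" and goal is None:
                if rng.random() < m.p_move_to_rest:
                    state = "rest"
            speed = 0.0
            if goal is not None:
                gx, gy = goal
                d = math.hypot(gx - px, gy - py)
                speed = min(
                    max(rng.normal(m.speed_mean_mps, m.speed_sd_mps), 0.05),
                    m.max_step_m,
                )
                if d <= speed:  # arrive and dwell
                    px, py = gx, gy
                    goal = None
                    state = "rest"
                    dwell = 1 + int(rng.exponential(m.bout_dwell_mean_s))
                    moving[t] = True
                    continue
                heading = math.atan2(gy - py, gx - px)
            elif state == "move":
                heading += rng.normal(0.0, m.heading_sd_rad)
                speed = min(
                    max(rng.normal(m.speed_mean_mps, m.speed_sd_mps), 0.0),
                    m.max_step_m,
                )
            if speed > 0:
                moving[t] = True
                px += speed * math.cos(heading)
                py += speed * math.sin(heading)
                # reflective boundaries
                if px < 0:
                    px = -px
                    heading = math.pi - heading
                elif px > L:
                    px = 2 * L - px
                    heading = math.pi - heading
                if py < 0:
                    py = -py
                    heading = -heading
                elif py > W:
                    py = 2 * W - py
                    heading = -heading
                px = min(max(px, 0.0), L)
                py = min(max(py, 0.0), W)
        scale = geom.cm_per_px / 100.0
        raw = locate_antennas(x / scale, y / scale, geom)
        antenna_at = np.empty(n, dtype=object)
        last = None
        for t in range(n):
            if raw[t] is not None:
                last = raw[t]
            antenna_at[t] = last
        out[bird] = TruthTrack(bird, x, y, moving, antenna_at)
    return out


def generate_rfid_reads(truth: dict[str, TruthTrack], cfg: SimConfig) -> pd.DataFrame:
    """Corrupt the truth into an RFID read log (columns time_s, tag, antenna).

    Per second a genuine read of the antenna under the leg-tag point is
    emitted with a probability that depends on whether the bird is moving.
    The tag point is the body center displaced by a fixed-magnitude offset
    whose direction is redrawn while the bird moves and frozen while it
    rests.  No read is ever emitted while the tag is over a defective
    antenna or a grid gap.  When a device hold window is configured, seconds
    shortly after a genuine read repeat the last antenna, emulating the
    reader's 5-second continuation.
    """
    geom = cfg.geom
    rng = _rng(cfg, 1)
    p = cfg.rfid
    scale = geom.cm_per_px / 100.0
    rows: list[tuple[float, str, str]] = []
    for bird, tr in truth.items():
        n = len(tr.x_m)
        off = p.leg_offset_cm / 100.0
        theta = rng.uniform(0, 2 * math.pi)
        tagx = np.empty(n)
        tagy = np.empty(n)
        for t in range(n):
            if off > 0 and (t == 0 or tr.moving[t]):
                theta = rng.uniform(0, 2 * math.pi)
            tagx[t] = tr.x_m[t] + off * math.cos(theta)
            tagy[t] = tr.y_m[t] + off * math.sin(theta)
        ants = locate_antennas(tagx / scale, tagy / scale, geom)
        u = rng.random(n)
        jit = rng.uniform(0.0, 0.3, n)
        last_read_t = -10**9
        last_ant: Optional[str] = None
        for t in range(n):
            prob = p.p_read_move if tr.moving[t] else p.p_read_rest
            ant = ants[t]
            genuine = (
                ant is not None
                and ant not in geom.defective_labels
                and u[t] < prob
            )
            if genuine:
                rows.append((t + jit[t], bird, ant))
                last_read_t = t
                last_ant = ant
            elif (
                p.device_hold_s > 0
                and last_ant is not None
                and t - last_read_t <= p.device_hold_s
            ):
                rows.append((t + jit[t], bird, last_ant))
    df = pd.DataFrame(rows, columns=["time_s", "tag", "antenna"])
    return df.sort_values("time_s", kind="stable").reset_index(drop=True)


def generate_detections(
    truth: dict[str, TruthTrack], cfg: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Corrupt the truth into a 25 fps detection log plus ground-truth boxes.

    Detection centers are the true position (constant within each second)
    plus isotropic Gaussian jitter; frames drop out independently and in
    bursts; during a switch episode the tracked class's box sits on a
    distractor bird.  Ground-truth boxes are exact and emitted for a random
    subset of frames shared by all tracked classes.
    """
    geom = cfg.geom
    rng = _rng(cfg, 2)
    cam = cfg.cam
    fps = cam.fps
    n_s = cfg.duration_s
    n_f = n_s * fps
    frame_w, frame_h = geom.frame_size_px
    tracked = cfg.tracked_names()
    all_birds = cfg.bird_names()

    pos_px: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for b in all_birds:
        x, y = truth[b].positions_px(geom)
        pos_px[b] = (np.repeat(x, fps), np.repeat(y, fps))

    det_rows = []
    for bi, bird in enumerate(tracked):
        fx, fy = pos_px[bird]
        # suppressed frames: independent misses plus whole-burst dropouts
        detected = rng.random(n_f) < cam.p_detect
        burst_starts = np.nonzero(rng.random(n_s) < cam.dropout_rate_per_s)[0]
        for s0 in burst_starts:
            dur = 1 + rng.geometric(1.0 / max(cam.dropout_mean_s, 1.0))
            detected[s0 * fps : (s0 + dur) * fps] = False
        # identity-switch episodes: box follows a distractor
        use_x, use_y = fx.copy(), fy.copy()
        if cam.switch_rate_per_s > 0:
            ep_starts = np.nonzero(rng.random(n_s) < cam.switch_rate_per_s)[0]
            if cam.distractor_birds and len(all_birds) > 1:
                other = all_birds[(all_birds.index(bird) + 1) % len(all_birds)]
                dx, dy = pos_px[other]
            else:
                dx = np.full(n_f, frame_w * 0.5)
                dy = np.full(n_f, frame_h * 0.5)
            for s0 in ep_starts:
                dur = 1 + rng.geometric(1.0 / max(cam.switch_mean_s, 1.0))
                sl = slice(s0 * fps, min((s0 + dur) * fps, n_f))
                use_x[sl] = dx[sl]
                use_y[sl] = dy[sl]
        idx = np.nonzero(detected)[0]
        cx = use_x[idx] + rng.normal(0.0, cam.jitter_sd_px, idx.size)
        cy = use_y[idx] + rng.normal(0.0, cam.jitter_sd_px, idx.size)
        np.clip(cx, 0, frame_w - 1, out=cx)
        np.clip(cy, 0, frame_h - 1, out=cy)
        conf = rng.beta(*cam.conf_beta, idx.size)
        det_rows.append(
            pd.DataFrame(
                {
                    "frame": idx,
                    "cls": bird,
                    "cx": cx,
                    "cy": cy,
                    "w": cam.box_px,
                    "h": cam.box_px,
                    "conf": conf,
                }
            )
        )
    detections = (
        pd.concat(det_rows, ignore_index=True)
        .sort_values(["frame", "cls"], kind="stable")
        .reset_index(drop=True)
    )

    n_gt = min(cam.n_gt_frames, n_f)
    gt_frames = np.sort(rng.choice(n_f, size=n_gt, replace=False))
    gt_rows = []
    for bird in tracked:
        fx, fy = pos_px[bird]
        gt_rows.append(
            pd.DataFrame(
                {
                    "frame": gt_frames,
                    "cls": bird,
                    "cx": fx[gt_frames],
                    "cy": fy[gt_frames],
                    "w": cam.box_px,
                    "h": cam.box_px,
                }
            )
        )
    gt_boxes = (
        pd.concat(gt_rows, ignore_index=True)
        .sort_values(["frame", "cls"], kind="stable")
        .reset_index(drop=True)
    )
    return detections, gt_boxes


def simulate(cfg: SimConfig) -> SimOutput:
    """Run the full simulator: truth plus both corrupted sensor streams."""
    truth = simulate_trajectories(cfg)
    reads = generate_rfid_reads(truth, cfg)
    detections, gt_boxes = generate_detections(truth, cfg)
    return SimOutput(
        config=cfg,
        truth=truth,
        rfid_reads=reads,
        detections=detections,
        gt_boxes=gt_boxes,
    )
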