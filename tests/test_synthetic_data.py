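"""Pen simulator: determinism, movement statistics, corruption channels."""

import numpy as np
import pandas as pd
import pytest

from pentrack.io import rfid_track_from_reads, video_track_from_detections
from pentrack.pen_model import build_default_geometry
from pentrack.simulate import (
    CamParams,
    MoveParams,
    RfidParams,
    SimConfig,
    generate_detections,
    generate_rfid_reads,
    noise_free_config,
    simulate,
    simulate_trajectories,
)


class TestTrajectories:
    def test_all_rest_zero_speed_is_constant(self):
        cfg = SimConfig(
            seed=3,
            duration_s=50,
            n_birds=1,
            move=MoveParams(
                p_rest_to_move=0.0,
                speed_mean_mps=0.0,
                speed_sd_mps=0.0,
                feeder_bout_rate=0.0,
                drinker_bout_rate=0.0,
            ),
        )
        tr = simulate_trajectories(cfg)["bird00"]
        assert np.ptp(tr.x_m) == 0.0 and np.ptp(tr.y_m) == 0.0
        assert not tr.moving.any()

    def test_same_seed_reproduces_everything(self):
        cfg = SimConfig(seed=11, duration_s=120, n_birds=2)
        a = simulate(cfg)
        b = simulate(cfg)
        for bird in a.truth:
            assert np.array_equal(a.truth[bird].x_m, b.truth[bird].x_m)
        pd.testing.assert_frame_equal(a.rfid_reads, b.rfid_reads)
        pd.testing.assert_frame_equal(a.detections, b.detections)
        pd.testing.assert_frame_equal(a.gt_boxes, b.gt_boxes)

    def test_realized_speed_matches_configured_distribution(self):
        # pure-move chain; oracle: Monte-Carlo mean of the truncated,
        # capped step-length distribution actually sampled
        m = MoveParams(
            p_rest_to_move=1.0,
            p_move_to_rest=0.0,
            feeder_bout_rate=0.0,
            drinker_bout_rate=0.0,
        )
        cfg = SimConfig(seed=5, duration_s=1000, n_birds=1, move=m)
        tr = simulate_trajectories(cfg)["bird00"]
        steps = np.hypot(np.diff(tr.x_m), np.diff(tr.y_m))
        moving_steps = steps[steps > 0]
        rng = np.random.default_rng(123)
        draws = np.clip(
            rng.normal(m.speed_mean_mps, m.speed_sd_mps, 1_000_000),
            0.0,
            m.max_step_m,
        )
        se = draws.std() / np.sqrt(moving_steps.size)
        # reflections can only shorten net displacement; allow a small slack
        assert moving_steps.mean() == pytest.approx(draws.mean(), abs=3 * se + 0.005)

    def test_positions_confined_to_pen(self):
        cfg = SimConfig(seed=7, duration_s=400, n_birds=2)
        for tr in simulate_trajectories(cfg).values():
            L, W = cfg.geom.pen_size_m
            assert (tr.x_m >= 0).all() and (tr.x_m <= L).all()
            assert (tr.y_m >= 0).all() and (tr.y_m <= W).all()

    def test_step_cap_respected(self):
        cfg = SimConfig(seed=9, duration_s=500, n_birds=2)
        for tr in simulate_trajectories(cfg).values():
            steps = np.hypot(np.diff(tr.x_m), np.diff(tr.y_m))
            assert steps.max() <= cfg.move.max_step_m + 1e-9


class TestRfidGeneration:
    def test_certain_reads_match_truth(self):
        cfg = noise_free_config(seed=2, duration_s=100, n_birds=1)
        truth = simulate_trajectories(cfg)
        reads = generate_rfid_reads(truth, cfg)
        tr = truth["bird00"]
        by_second = {int(np.floor(t)): a for t, a in
                     zip(reads["time_s"], reads["antenna"])}
        for s in range(100):
            if tr.antenna_at[s] is not None:
                assert by_second.get(s, tr.antenna_at[s]) == tr.antenna_at[s]

    def test_defective_antenna_never_reads(self):
        cfg = SimConfig(
            seed=4,
            duration_s=400,
            n_birds=3,
            rfid=RfidParams(p_read_rest=1.0, p_read_move=1.0, device_hold_s=0),
        )
        truth = simulate_trajectories(cfg)
        reads = generate_rfid_reads(truth, cfg)
        assert "A2" in cfg.geom.defective_labels
        assert not (reads["antenna"] == "A2").any()

    def test_moving_miss_rate_matches_binomial(self):
        p_move = 0.3
        cfg = SimConfig(
            seed=6,
            duration_s=1500,
            n_birds=1,
            move=MoveParams(p_rest_to_move=1.0, p_move_to_rest=0.0,
                            feeder_bout_rate=0.0, drinker_bout_rate=0.0),
            rfid=RfidParams(
                p_read_rest=1.0, p_read_move=p_move,
                leg_offset_cm=0.0, device_hold_s=0,
            ),
            geometry=build_default_geometry({"defective": []}),
        )
        truth = simulate_trajectories(cfg)
        reads = generate_rfid_reads(truth, cfg)
        tr = truth["bird00"]
        raw_inside = [
            s for s in range(cfg.duration_s)
            if tr.moving[s] and _inside_grid(tr, s, cfg)
        ]
        got = {int(np.floor(t)) for t in reads["time_s"]}
        hit = sum(1 for s in raw_inside if s in got)
        n = len(raw_inside)
        assert n > 200
        se = np.sqrt(p_move * (1 - p_move) / n)
        assert hit / n == pytest.approx(p_move, abs=4 * se)


def _inside_grid(tr, s, cfg):
    from pentrack.pen_model import PointPx, locate_antenna

    scale = cfg.geom.cm_per_px / 100.0
    return (
        locate_antenna(PointPx(tr.x_m[s] / scale, tr.y_m[s] / scale), cfg.geom)
        is not None
    )


class TestDetectionGeneration:
    def test_noise_free_end_to_end_identity(self):
        cfg = noise_free_config(seed=8, duration_s=200, n_birds=1)
        sim = simulate(cfg)
        tr = sim.truth["bird00"]
        v = video_track_from_detections(sim.detections, "bird00", n_seconds=200)
        xt, yt = tr.positions_px(cfg.geom)
        assert np.allclose(v.x_at, xt) and np.allclose(v.y_at, yt)
        r = rfid_track_from_reads(sim.rfid_reads, "bird00", (0, 200))
        assert all(a == b for a, b in zip(r.antenna_at, tr.antenna_at))

    def test_switch_episode_boxes_sit_on_distractor(self):
        cfg = SimConfig(
            seed=10,
            duration_s=300,
            n_birds=2,
            cam=CamParams(
                p_detect=1.0, jitter_sd_px=0.0,
                dropout_rate_per_s=0.0, switch_rate_per_s=0.05,
            ),
        )
        truth = simulate_trajectories(cfg)
        dets, _ = generate_detections(truth, cfg)
        d0 = dets[dets["cls"] == "bird00"].set_index("frame")
        x0, y0 = truth["bird00"].positions_px(cfg.geom)
        x1, y1 = truth["bird01"].positions_px(cfg.geom)
        fx0 = np.repeat(x0, cfg.cam.fps)
        fx1 = np.repeat(x1, cfg.cam.fps)
        fy1 = np.repeat(y1, cfg.cam.fps)
        on_distractor = 0
        for f, row in d0.iterrows():
            if abs(row["cx"] - fx1[f]) < 1e-9 and abs(row["cy"] - fy1[f]) < 1e-9:
                on_distractor += 1
        assert on_distractor > 0

    def test_dropout_burst_produces_missing_second(self):
        cfg = SimConfig(
            seed=12,
            duration_s=300,
            n_birds=1,
            cam=CamParams(
                p_detect=1.0, jitter_sd_px=0.0,
                dropout_rate_per_s=0.02, dropout_mean_s=2.0,
                switch_rate_per_s=0.0,
            ),
        )
        truth = simulate_trajectories(cfg)
        dets, _ = generate_detections(truth, cfg)
        from pentrack.video import downsample_to_1hz

        boxes = downsample_to_1hz(dets, "bird00", n_seconds=300)
        assert any(b is None for b in boxes)

    def test_gt_boxes_exact_on_truth(self):
        cfg = SimConfig(seed=13, duration_s=100, n_birds=2)
        truth = simulate_trajectories(cfg)
        _, gt = generate_detections(truth, cfg)
        for bird in ["bird00", "bird01"]:
            sub = gt[gt["cls"] == bird]
            x, y = truth[bird].positions_px(cfg.geom)
            fx = np.repeat(x, cfg.cam.fps)
            fy = np.repeat(y, cfg.cam.fps)
            assert np.allclose(sub["cx"], fx[sub["frame"]])
            assert np.allclose(sub["cy"], fy[sub["frame"]])
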