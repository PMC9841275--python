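{
  "pen_m": [2.61, 1.8],
  "frame_px": [1920, 1080],
  "antenna_cm": [41.0, 32.0],
  "grid": [6, 5],
  "gaps_cm": null,
  "cm_per_px": 0.2199,
  "feeders": ["E1", "F1", "E5", "F5"],
  "drinker": "D1",
  "defective": ["A2"],
  "feeder_sector": {"radius_px": 100.0, "angle_deg": 120.0},
  "feeder_overrides": {}
}
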