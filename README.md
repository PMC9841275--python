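# pentrack

Dual-sensor localization and behavior metrics for floor-housed poultry.

Individual behavior — where a bird spends its time, how much it moves,
whether it visits the feeder — is a promising proxy for health, welfare,
and performance traits in broiler breeding, but it has to be measured
automatically on many animals. Two sensor systems can do this in a pen: a
grid of passive RFID antennas under the floor reading leg tags, and an
overhead camera feeding an object detector. They disagree in
characteristic ways, and quantifying that disagreement is the point of
this package.

`pentrack` is a Python library (with a thin CLI) for researchers working
with such recordings. It turns raw RFID read logs and per-frame detection
logs into 1 Hz trajectories, measures the localization agreement between
the two modalities, derives the standard behavioral metrics from either,
and evaluates detectors COCO-style. A built-in pen simulator with a known
truth channel makes every stage testable end to end.

## What it computes

**Trajectories.** RFID reads are deduplicated (first antenna per second
wins) and gaps are filled by holding the last detected antenna. Video
detections are downsampled from 25 fps to 1 Hz (highest confidence per
second; missing when > 80% of frames lack a detection), cleaned of
identity switches (a run of ≤ 2 consecutive detections with IOU = 0
against the last accepted box is held at the previous location; 3 or more
count as movement), and gap-filled the same way. Video points can be
projected onto the antenna grid ("video-as-RFID") for a like-for-like
comparison.

**Agreement.** Per-second Euclidean differences between the two systems'
locations, d_t = ‖x_t^rfid − x_t^cam‖₂, summarized by the fraction within
the mean antenna enclosing-circle radius (128 px ≙ 28.15 cm) and within
twice it, plus per-antenna time-budget differences.

**Behavior.** Space usage (seconds per antenna, unique antennas,
switches), locomotion activity as thresholded total distance

    D = Σ_t d_t · I(d_t > τ),   τ ∈ {0, 0.005, 0.05} m,

and apparent feeding/drinking visits (presence in a 120°, 100 px feeder
sector, or on feeder/drinker antennas; a visit is a maximal run of member
seconds). Cohort summaries reproduce the reporting arithmetic: half-up
rounded means, between-system and between-bird differences.

**Detection evaluation.** IOU, greedy one-to-one matching in descending
confidence, precision p = TP/(TP+FP), recall r = TP/(TP+FN), 101-point
interpolated average precision AP = (1/101) Σ_r p_interp(r), mAP over
classes and over IOU thresholds 0.50:0.05:0.95, the F1-optimal confidence
threshold, and median-IOU annotator reliability.

## A worked example

Ten simulated minutes of three tracked birds with the default noise model
(state-dependent RFID misses, 3 px detection jitter), compared second by
second (`examples/04_agreement.py`):

```
$ python examples/04_agreement.py
bird00: time budget diff 0.00 +/- 9.06 s per antenna
bird01: time budget diff 0.00 +/- 9.85 s per antenna
bird02: time budget diff -0.07 +/- 1.91 s per antenna
n pairs: 1794
mean difference: 65.1 px (14.3 cm)
within antenna radius (<=128 px): 97.0%
within one antenna (<=256 px):    99.7%
```

The two systems place each bird on the same antenna-sized patch 97% of the
time; the residual 65 px mean difference comes from the leg-tag offset,
detection jitter, and the RFID system's quantization to antenna centers.
The time-budget means are ~0 by conservation — both systems account for
every located second — while the standard deviation shows how differently
the seconds distribute over antennas. Each script in `examples/` walks
one capability: geometry, either pipeline, agreement, behavior metrics,
detection evaluation, and the end-to-end runner.

The same analyses run from a shell:

```sh
pentrack simulate --seed 7 --duration 600 --birds 3 --out sim/
pentrack run-all --reads sim/rfid_reads.csv --dets sim/detections.csv \
    --gt sim/gt_boxes.csv --out run/
```

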