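# Methods

`pentrack` compares two ways of localizing individual broilers in a pen —
a subfloor grid of passive RFID antennas reading leg tags, and an overhead
camera feeding an object detector — and derives behavioral metrics from
either. This note describes the models and procedures the package
implements, the parameters that matter, and what its built-in simulator
does and does not capture.

## Pen model

The pen (1.80 × 2.61 m) is covered by a 6 × 5 grid of 32 × 41 cm antennas,
labelled `A1`–`F5`. The published grid drawing shows inter-center distances
that vary with the mounting-panel layout but does not enumerate them, so
the default geometry places the antennas on a uniform-gap tiling: the free
length on each axis is split into equal gaps (including wall margins), and
explicit per-gap overrides are accepted in the geometry JSON for anyone who
wants to reproduce a particular physical layout. Antenna rectangles are
half-open (left/top edges inclusive), so point-to-antenna assignment
partitions the plane with no double counting; the tie-break is arbitrary
but deterministic.

Image pixels convert to physical units through a single global scale
factor, `cm_per_px = 0.2199` (100 px = 21.99 cm). There is no lens or
perspective correction — the source recordings had none — so pixel-derived
distances are approximations, and the package reports them as such.

Feeder zones are circular sectors (default θ = 120°, r = 100 px) centered
on the feeder opening. The sector's opening direction is not stated in the
source material; the default points into the pen perpendicular to the
nearest wall, and it is configurable per feeder. The drinker zone is its
antenna.

The 128 px "mean radius of the antennas' enclosing circle" used as the
agreement threshold cannot be re-derived from the printed geometry (the
uniform-gap default gives 118 px), so it is a configuration value with
default 128, not a computed quantity.

## RFID pipeline

Reads are bucketed into whole seconds per tag; double reads within a second
keep the first antenna received. Each second with a read is `detected`;
seconds without one carry the last detected antenna (`held`), on the
assumption that the bird stayed put; seconds before the first read ever
received are `pre_first_fix`, carry no location, and are excluded from all
metrics. The reader hardware also repeats the last antenna for 5 s on its
own; because indefinite last-known-location holding subsumes that window at
1 Hz, the device behavior lives in the simulator, not the pipeline.
Distance moved is the Euclidean distance between consecutive located
antenna centers, in meters; held seconds therefore contribute zero.

## Video pipeline

Detections arrive per frame (25 fps default) as center/width/height boxes
with confidences, per tracked class. Downsampling keeps, per second, the
highest-confidence detection (ties: earliest frame) unless strictly more
than 80% of the frames in that second lack a detection, in which case the
second is missing. The boundary is exact: 21 of 25 frames missing (84%)
→ missing; 20 of 25 (80%) → retained.

Identity-switch correction compares each retained box to the last
*accepted* box by intersection-over-union, where "non-overlapping" means
IOU exactly zero. Non-overlapping boxes are buffered; if overlap with the
reference resumes while at most two are buffered, the buffered seconds are
replaced by the reference (`held_switch`); three consecutive
non-overlapping boxes are accepted as genuine movement and the newest
becomes the reference. A run still buffered when the stream ends is treated
as a switch. Missing seconds pass through and do not interrupt a buffered
run. The automaton is idempotent. The bookkeeping between the stated
two-box correction and three-box acceptance is this package's
interpretation (compare-to-last-accepted rather than
compare-to-immediately-previous), chosen because it makes the two rules
consistent with a single reference location.

Missing seconds then carry the last accepted location forward, and the
point track can be projected onto the antenna grid ("video-as-RFID"):
points outside the grid count as missing and hold the last in-grid antenna.

## Agreement

Paired per-second distances are taken between the RFID antenna's center
and the video box center, in pixels, skipping seconds where either system
has no location yet. Seconds whose video point falls on a defective antenna
can be excluded (the grid could never report them); this exclusion applies
only to the paired-distance analysis, not to time budgets. The summary
reports the fraction of differences within the configured enclosing-circle
radius and within twice it, plus means in px and cm. All located seconds
enter the comparison, imputed or detected; detected-only analyses can be
had by masking on provenance. Time budgets count seconds per antenna for
both systems over a shared span; when both locate every second the
per-antenna differences sum to zero by construction.

## Behavioral metrics

Space usage is seconds per antenna (held seconds count toward the held
antenna), unique antennas visited, and switches between differing
consecutive located antennas; switches are not counted across
pre-first-fix gaps. Locomotion activity sums per-second distances that are
*strictly* greater than a minimum movement threshold τ ∈ {0, 0.005, 0.05} m
by default; the strict indicator means τ = 0 drops exactly-zero steps,
which leaves the total unchanged. Zone visits are maximal runs of
consecutive member seconds — no gap merging, no minimum duration — where
membership is sector containment for pixel-based feeding, label equality
for antenna-based feeding/drinking, and union membership for multi-antenna
zones (e.g. the four feeder antennas: crossing from E1 to F1 continues one
visit). "Apparent" feeding/drinking is deliberate: presence near the
feeder does not prove ingestion.

Cohort summaries (means per system, per-bird between-system differences,
between-bird ranges) round half-up to the printed precision: integers for
counts, two decimals for meters.

## Detection evaluation

Matching is greedy, one-to-one, in descending confidence order, against the
unmatched same-class ground truth of highest IOU; a surviving prediction
with best IOU ≥ the threshold is a TP, anything else an FP (wrong class
matches are always FP), and unmatched ground truths are FN. The
precision-recall curve sweeps the observed confidences; because greedy
matching at a higher threshold is a prefix of the matching at threshold
zero, the curve is computed in one cumulative sweep, and the per-threshold
full recount is kept as an independent test oracle. AP interpolates
precision at 101 uniform recall points (max precision over points with
recall ≥ r, zero when unreached); mAP averages over classes and optionally
over the IOU ladder 0.50:0.05:0.95. The reported operating point maximizes
F1 at IOU 0.5 (ties: higher threshold). Annotator reliability is the
median and IQR (linear-interpolation quantiles) of paired-annotation IOUs.

## Simulator

The simulator generates per-second ground-truth positions and corrupts
them into both sensor streams, so every pipeline stage can be tested
against a known truth.

**Movement.** A two-state (rest/move) correlated random walk confined to
the pen by reflection, with occasional directed bouts to a feeder sector or
the drinker followed by an exponential dwell. Defaults describe shuffling
18-day-old chicks: P(rest→move) = 0.05/s, P(move→rest) = 0.40/s, step
speeds N(0.12, 0.05²) m/s truncated at zero and capped at
`max_step_m = 0.19` m. The cap keeps per-second displacements below the
90 px body-box footprint (~19.8 cm), the regime in which consecutive boxes
of a continuously moving bird overlap and the switch corrector cannot
mistake genuine movement for an identity switch; sustained faster
locomotion (reported elsewhere at 0.3–1 m/s for older or feed-deprived
birds) is outside this model's scope. Positions are piecewise-constant
within a second — sub-second movement is below both sensors' resolution.

**Truth discretization.** The truth antenna channel uses the same rule as
both pipelines: containing antenna under the half-open convention, else the
last containing antenna held. With all noise off, both pipelines therefore
reproduce the truth channel exactly — the package's central recovery
property.

**RFID corruption.** Per second, a read of the antenna under the leg-tag
point is emitted with probability 0.90 at rest and 0.50 while moving (a
moving bird's tag couples worse to the field); no read is emitted from
gaps, margins, or defective antennas. The tag point is the body center
displaced by 4 cm in a direction redrawn while moving and frozen at rest —
a resting bird does not move its leg, and redrawing at rest would
manufacture antenna flicker the real device never showed. The reader's
5-second continuation is emulated as repeated reads of the last antenna.
The quantitative miss rates are free parameters: the source material
reports only event counts, not probabilities.

**Camera corruption.** Per frame, a detection is emitted with probability
0.97, centered on the truth plus isotropic N(0, 3² px) jitter, with
Beta(14, 2) confidence; dropout bursts (rate 0.002/s, mean 2 s) suppress
whole runs of frames; identity-switch episodes (rate 0.0005/s, mean 2 s)
place the tracked class's box on a distractor bird. Ground-truth boxes are
exact and cover a random subset of frames (default 100).

Under these defaults the simulator reproduces, as seeded-mean properties,
the qualitative sensor biases of the field comparison: RFID underestimates
total distance (missed movement plus within-antenna motion it cannot see),
raw pixel-based distance overestimates it (jitter accumulates at τ = 0),
and grid-projected video switches antennas more often than RFID
(edge-straddling jitter).

**What the simulator does not capture.** RF field physics and
tag-orientation effects (misses are i.i.d. given the movement state, not
velocity-graded); occlusion structure (dropouts are random, not
posture-driven); perspective and lens distortion; social behavior beyond
independent birds; box-size variation with posture. Passing tests
demonstrate the pipeline algebra and the direction of the sensor biases
under these assumptions — not that real recordings would yield the same
magnitudes.

## Problem sizes and numerical choices

The test suite runs the exact-recovery check on a 3600 s noise-free session
with 3 tracked birds, and the bias properties as means over 20 seeds of
600 s × 3 birds — sizes chosen so the full suite stays fast while the
binomial/Monte-Carlo margins are comfortable. The acceptance script
simulates one 8100 s session (the length of the original recording window)
with 40 birds, 3 of them tracked. Geometry validation tolerates 1e-6 px on
seam adjacency; strict-inequality thresholds (the >80% downsampling rule,
the d > τ indicator) are implemented exactly as stated, with dedicated
boundary tests. All randomness flows from one integer seed through
independent named substreams, so every output is reproducible from its
configuration.
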