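# Methods

## The loop in one paragraph

A rotating grating displayed beneath a (virtual) head-fixed larva drives its
optokinetic reflex; the resulting eye-angle deltas, thresholded per eye, are
mapped by a two-eye consensus rule to discrete robot commands (Left / Right
/ Forward) at 10 Hz; the robot's line sensor classifies it as left of / on /
right of a taped line, and that classification sets the grating's rotation
sense (CW when left, hidden when on, CCW when right), closing the loop. A
trial lasts 45 s and everything is logged on the shared 0.1 s grid.

## Stimulus model

Frames are rendered as alternating black/white angular sectors
(`n_gratings` dark wedges per revolution) restricted to concentric annular
rings of a given thickness separated by `spacing` percent of the radial
extent, around a central white circle. The "maximum thickness" preset is a
single ring tiling the annulus from the center circle to the raster edge.
Rendering uses nearest-neighbour sector assignment, no anti-aliasing, so a
frame is a pure, bit-reproducible function of (params, phase, size);
rotational symmetry is verified against an independent raster rotation to a
small mismatch tolerance rather than exactly, since pixel rotation of a
wedge pattern is only exact up to edge pixels. Angles are CCW-positive as
seen by the camera throughout the package; because image rows grow
downward, the polar angle is computed with the y-axis negated at exactly
one site per module.

## Eye tracking

Per eye: ROI crop, median blur (odd kernel, default 5 px), fixed global
threshold (default 100 on a 0–255 scale; dark-on-light polarity by
default), largest connected component, sub-pixel boundary via marching
squares, algebraic least-squares ellipse fit. The eye angle is the
minor-axis angle versus the horizontal, CCW-positive, wrapped to
(−90°, 90°]. Near-circular fits (major/minor < 1.05) keep their angle but
are flagged unreliable. Failed frames become NaN gaps, never interpolated;
deltas spanning a gap are NaN and excluded from all counts (zero-filling
would inflate parity denominators). Series-level unwrapping folds any
frame-to-frame jump > 90° back by 180° (axial equivalence), keeping slow
rotations through ±90° continuous. The blur kernel and threshold defaults
were fixed against the synthetic-eye fixtures; both are parameters, since
real footage will differ.

On rendered ellipses (semi-axes 22/11 px) the fit recovers orientation with
mean error ≈ 0.2° and max ≈ 0.9° over a 1°-step sweep of (−90°, 90°].

## Delta thresholding and directional parity

Deltas are differences of consecutive eye angles, first defined at the
second frame. The threshold filter keeps a delta only when its magnitude
strictly exceeds τ, else outputs 0; zeros count as neither positive nor
negative in all parity sums. The parity ratio for a CCW bin is
(#positive kept deltas)/(#negative kept deltas), reciprocal for CW. When
aggregating over a trial the aligned and misaligned counts are pooled
across all directed bins *before* the ratio (per-bin ratios of 10 s bins
are too unstable). Each delta is attributed to the bin containing its
earlier frame — the stimulus actually on screen while the eye moved — so
direction switches never leak one frame into the wrong bin. A zero
misaligned count gives S = +∞, which wins the argmax; ties break toward the
smallest τ (least signal suppression); 0/0 is undefined (NaN) and never
wins. The default grid is integers 1…55 in deg/frame at 10 Hz.

## NEA and statistics

`B_{i,t,b}` sums |θ_{f+1} − θ_f| over deltas whose two endpoint frames both
lie in bin b; bins sharing a label (the two blank segments, "B") are summed
together, so a characterization trial yields six activity bins (five
parameter levels + blank). NEA divides by the per-(larva, trial) maximum,
blank included; if every bin is zero the rows are flagged rather than
normalized. Kruskal–Wallis (scipy) tests the six bins pooled over larvae;
upon rejection, Dunn's pairwise z-tests run on the pooled ranks with the
standard tie correction and Bonferroni adjustment `min(1, p·m)`,
m = k(k−1)/2. With 5 observations per bin the χ² approximation of the H
statistic is slightly conservative: the measured null rejection rate at
α = 0.05 is ≈ 0.03–0.045 over 2000 seeded replicates.

## Saccade detection

Velocity detector: central-difference angular velocity on the 0.1 s grid,
events where |v| > 3 deg/s, consecutive supra-threshold frames merged into
one event at the velocity peak. Disagreement detector: scan the τ grid and
pick the τ maximizing (#stimulus-disagreeing kept deltas)/(#agreeing),
pooled over directed bins; saccades are then all frames with |Δθ| above
that τ (saccades oppose the slow phase, so they dominate disagreement). If
the best achievable ratio stays below 1 with no infinite value, the slow
phase and saccades are not separable and the trace is declared
saccade-free — otherwise any finite argmax on a saccade-free trace would
label every slow-phase frame a saccade.

## Virtual larva

Per frame and per eye: θ += sign(ω)·gain·min(|ω|, ω_sat)·dt + N(0, jitter²),
with a hard reset of `saccade_size` toward zero (recorded as ground truth)
whenever |θ| exceeds `saccade_trigger`; blank periods contribute jitter
only; stimulus changes reach the larva after a pure delay `latency`. The
two eyes share the stimulus and gains but draw independent jitter.

Defaults and why (deg, s): gains 0.8 (CCW = CW unless a directional
preference is being modeled), ω_sat 15 deg/s — larval OKR slow-phase
velocity is strongly sublinear in stimulus speed and effectively saturates
in the 10–20 deg/s range, and without saturation a single calibrated τ
cannot serve stimulus speeds spanning 15–60 deg/s (the per-frame delta
would quadruple across the range, driving the turn-command probability from
≈ 0 to ≈ 1); trigger 20 and size 15 give sawtooth beats of realistic
amplitude; jitter 0.3 deg/frame puts the noise floor just under the first
τ grid point so the calibration is meaningful; latency 0.2 s. What the
generator does *not* model: pursuit build-up dynamics, gain adaptation,
temporal-to-nasal per-eye asymmetry, vergence, or any dependence of gain on
spatial parameters (grating count/spacing/thickness affect only what the
characterization protocol displays, not the simulated response). Passing
tests therefore validate the rig's measurement and control machinery on a
larva-shaped signal, not any biological claim about real larvae.

## Robot, sensor and world

Unicycle kinematics: Forward advances `speed·dt` along the heading;
Left/Right rotate `turn_rate·dt` in place (default 45 deg/s; an arc mode
that also translates and a constant castor-drift term are config options).
The line sensor projects the line into a forward trapezoidal footprint
10–30 cm ahead (half-width 5 cm near, 15 cm far), mimicking a tilted
onboard camera; the mean lateral offset of visible line points, with a
deadband of half the tape width (1.27 cm), classifies left/on/right. The
footprint makes this a lookahead sensor: aiming the sensor axis at the
line ahead is what turns three-valued feedback into a smooth, damped
pursuit of the line. An image route renders the footprint, isolates the
tape by HSV in-range filtering and takes the pixel center of mass; it is
equivalence-tested against the geometric route and kept out of the inner
loop for speed. The overhead tracker solves the exact direct-linear-
transform homography from 4 correspondences (residual ≤ 1e-9 verified) and
localizes the rear marker by color center of mass in the rectified view
(≤ 0.5 cm error at 4 px/cm).

## Driving protocol and metrics

Per larva: a speed-characterization trial calibrates τ per eye, then 8
trials (ω ∈ {15, 30, 45, 60} deg/s × left/right start), 45 s at 10 Hz. The
start pose is 12 cm from the line, heading 60° oblique toward it, forward
speed 5 cm/s — chosen once so a trial reproduces the characteristic shape
of the physical experiment: crossing of the line ("intersection") around
15–20 s, a bounded overshoot, then steady following. Each trial reseeds
the larva deterministically from (larva seed, trial index). Metrics:
absolute x-error |robot_x| over time; intersection time = first sign change
of the signed error (undefined if never); cumulative error = trapezoidal
time integral (the natural reading of a "cumulative" error over a sampled
trajectory); mean error over the whole trial and over t > 20 s. The
directional-bias experiment sets gain_ccw = 0.8 > gain_cw = 0.6; left
starts then outperform right starts at every ω because the overshoot side
of a left start is corrected by the stronger CCW response — with equal
gains the left/right difference sits within seed-to-seed noise.

## Numerical and degenerate-input choices

Half-open bins [tb, tbn); strict inequalities everywhere a threshold is
compared (ties never trigger a turn or count as direction); NaN deltas are
Forward in the loop and excluded from counts in analytics; all-invalid
tracking raises; empty sensor footprints return "line lost" carrying the
last seen side; homography estimation rejects any 3 collinear calibration
points. Characterization levels default to speed {15,30,45,60,75} deg/s,
spacing {10…50} %, count {1…5}, thickness {20…100} px — five evenly spaced
levels per trial anchored at the standard defaults (ω 30, spacing 20 %,
thickness max, 5 gratings); trials run sequentially by default with a
randomized-order flag left to the caller via schedule construction.

## Problem sizes used by the tests and acceptance script

Angle sweep: 180 orientations at 1° steps; render/track round trip: 81
frames; oracle equivalence: 100 traces × 55 thresholds × 400 frames;
driving sets: 40 trials of 450 ticks each (plus 40 biased); statistics
null: 2000 Kruskal–Wallis replicates of 6 × 5 observations. These sizes
keep the full suite and the acceptance script in the tens of seconds while
leaving every measured rate well-resolved.

## Known limitations

The larva model is a caricature (see above); the robot has no wheel slip,
motor dynamics or sensing latency; the geometric line sensor sees an
idealized line (the image route exists to check the geometry, not to model
optics); heading-only in-place turns make the robot's translation duty
cycle depend directly on the larva's turn-command rate, which couples
stimulus speed to effective ground speed; and the arena boundary is not
enforced — the line is treated as extending beyond the 55 cm sheet.
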