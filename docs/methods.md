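# Methods

## Trial model and coordinate conventions

A trial is a set of five labelled 3D marker trajectories (wrist, index
finger, two peg-top markers, goal marker) sampled at 120 Hz, in
millimetres. Coordinates follow the task geometry: x is the
frontoparallel (left–right) axis, y the sagittal depth axis, z vertical;
the "horizontal plane" is x–y. Left-hand trials are mirrored about the
mid-sagittal plane (x negated) before analysis so a single right-hand
geometry serves both hands; under that reflection the goal slot's
orientation angle changes sign, which the pipeline applies when computing
the residual angle.

Dropouts are explicit: a blank cell in the TSV becomes an invalid frame,
never silently interpolated. Interior gaps of ≤ 10 frames are repaired
automatically, gaps of 11–20 frames only when `allow_manual` is set (the
programmatic stand-in for accepting a gap-fill after visual inspection);
longer gaps make the trial unusable. Interpolation uses shape-preserving
piecewise-cubic (PCHIP) polynomials: a global natural spline was found to
ring visibly on noisy anchor frames, producing phantom velocity
excursions of tens of mm/s that corrupt threshold-based event detection,
whereas a monotone Hermite interpolant cannot overshoot its anchors.

All marker trajectories are smoothed with a second-order 12 Hz
Butterworth filter applied forward–backward (zero phase). Zero-phase
application preserves event timing, at the cost of doubling the effective
order and spreading sharp bursts symmetrically in time — a property the
event detectors below must account for.

## Velocity features and movement units

Tangential velocity is the norm of the central difference of smoothed
positions times the sampling rate (one-sided at span edges);
differentiating the smoothed trajectory keeps velocity consistent with
the positions rather than filtering raw frame differences.

A movement unit (MU) is a velocity peak whose rise from the preceding
minimum and fall to the following minimum each reach 20 mm/s, with
frame-wise |acceleration| exceeding 5 mm/s² somewhere inside the unit.
"Accumulated increase and decrease" is read as
rise-from-preceding-minimum / fall-to-following-minimum. Peaks failing
the velocity rule are merged into the neighbour across their higher
bounding minimum, smallest prominence first, ties resolved toward the
earlier neighbour; this makes segmentation deterministic and, because
merging only deepens the surviving minima, the MU count is monotone
non-increasing in the threshold. The acceleration clause acts as a final
accept/reject guard (it is applied to the magnitude of frame-wise
acceleration; with realistic profiles it is almost always satisfied).
Truncated rises or falls at a segment edge never form a unit on their
own. The implementation is validated against an independent brute-force
enumeration of the same rule on hundreds of random profiles.

Segment metrics follow the standard definitions: PPV is the speed
maximum's position as a percentage of segment duration; the acceleration
and deceleration phases split the segment at the peak; path distance sums
frame-to-frame Euclidean steps. The index–wrist peak-time difference is
negative when the index finger peaks first.

## Phase segmentation

All detectors operate on the smoothed data and are deterministic.

- **Movement onset**: first frame at or after goal visibility where
  wrist speed reaches 20 mm/s, sustained for 3 frames and reaching 1.5×
  the threshold within 6 frames. The sustain/trigger guards exist because
  filtered marker noise (≈ 4–6 mm/s sd on the speed of a resting marker
  at 0.3 mm coordinate noise) occasionally produces brief 20 mm/s
  excursions; a genuine onset rises monotonically through the threshold,
  so the detected frame is unbiased.
- **Reach end (object contact)**: the paper-style criterion "wrist-speed
  low point with a simultaneous change in the object markers" is
  operationalised in two steps. Peg-motion onset is a run of peg-centre
  speed above 10 mm/s lasting ≥ 4 frames, peaking above 30 mm/s, while
  the wrist is within 80 mm of the peg; the run's first trigger-level
  crossing anchors the event (the run's start is smeared backward by the
  zero-phase filter, and a short grasp can merge the contact burst with
  the transport burst, so neither the run start nor its global peak is
  stable). The low point is then the first local minimum of the last
  near-minimum run of wrist speed in a ~12-frame window before the
  anchor, so dips between earlier approach corrections cannot end the
  reach prematurely ("including any final movement unit"). Reach start
  and end carry the five-frame corrections (onset − 5, low point + 5).
- **Transport start**: five frames before the peg centre has risen 1 mm
  above its resting height (median height over the six frames after
  contact — a short grasp may already be lifting later in a longer
  window).
- **Transport end**: with the peg seated (inside the 10 mm goal radius
  and at rest for six frames), the first frame where wrist speed is at
  least 60 mm/s for three frames, the horizontal wrist velocity has an
  outward radial component of at least 30 mm/s, and the peg remains at
  rest. The radial-velocity and peg-rest conditions prevent the descent
  of the peg into the slot, or a late fitting correction, from being
  mistaken for the hand's return. If the hand never returns the last
  frame is used and flagged.
- **Grasp duration** is the interval from the low point to the 1 mm lift
  crossing, i.e. the boundary corrections excluded.

On synthetic trials these detectors recover the constructed event frames
within ±3 frames noise-free and ±6 frames at 0.3 mm marker noise, and
latency / grasp-duration means recover the generator parameters within
two standard errors of the measured mean (about 5–15 ms here).

## Rotation decomposition

The peg angle is atan2 of the marker-pair difference projected on the
horizontal plane, unwrapped over time and re-zeroed on the start-holder
orientation; swapping marker identities shifts the raw angle by 180° but
leaves the re-zeroed series unchanged. With the pair only 20 mm apart,
0.3 mm coordinate noise maps to ≈ 0.5° angle noise per frame, and naive
differentiation yields ≈ 20 °/s angular-speed noise — twice the 10 °/s
rotation threshold. The estimator therefore:

1. low-passes angular speed at 6 Hz (zero phase);
2. counts frames with |ω| > 10 °/s only inside runs that last ≥ 4 frames
   and peak above 3× the threshold (hysteresis: genuine rotation episodes
   always reach 30 °/s, filtered angle noise effectively never does);
3. clips each counted episode to the span over which the angle itself has
   measurably departed from its pre-episode level and not yet settled at
   its post-episode level (0.5° tolerance, ≈ 1.5× the angle-noise sd).
   This removes the symmetric broadening the 6 Hz filter adds to each
   episode, recovering near-unbiased durations (e.g. a 140 ms, 5.6°
   correction measured at ≈ 110–150 ms instead of ≈ 200 ms without the
   clip). Episodes with no net angle change (out-and-back wobbles) are
   left unclipped.

Rota I sums rotating time before arrival at the goal, Rota II from
arrival to transport end; arrival is the peg centre first entering a
10 mm horizontal radius around the goal slot centre (the residual angle
is evaluated at that frame, before any at-goal correction). Rotations
slower than the detection level (below ≈ 30 °/s peak) are not counted —
a deliberate trade-off documented here because very slow creeping
rotations are indistinguishable from angle noise at this marker
geometry. Rotation durations are summed rotating-frame time rather than
a single contiguous interval. Round-peg trials have no orientation
demand and report a residual of zero.

## Synthetic trials

Trials are superpositions of minimum-jerk submovements
(s(τ) = 10τ³ − 15τ⁴ + 6τ⁵, peak speed 1.875·A/D), the standard model for
bell-shaped reaching profiles, on the task scene: holders 250 mm apart,
peg-top markers 20 mm apart at 40 mm height, goal visible at 200 ms.
The wrist performs a main reach (placed so its noise-free 20 mm/s
crossing lands exactly at goal-visibility + latency), optional corrective
submovements covering a 10–25 mm undershoot, a grasp dwell (with a small
horizontal peg jostle at contact — the physical signature of touch the
reach-end criterion keys on), a brisk 30 mm pickup timed so the 1 mm
height crossing falls exactly at dwell end, a 250 mm transport, fitting
corrections at the goal (paired out-and-back legs that overlap ~15% so
the peg never falsely appears seated), a descent into the slot, and a
return. The index finger is the wrist path time-advanced by the
index-lead parameter plus a fixed offset and opening perturbations.

Rotation strategy is the core group contrast: `in_transport` profiles
(adult) rotate smoothly from pickup through transport, arriving within a
few degrees of the goal and making one brief correction; `at_goal`
profiles (6-year-olds) arrive 20–25° short in the 180° condition and
correct in 1–3 discrete steps at the goal; `mixed` (10-year-olds) draws a
strategy per trial. Condition difficulty (RP < 0° < −90° < 90° < 180°)
scales correction counts, rotation times and residual angles, normalised
so group-level parameter means hold across a full five-condition cohort.

A per-trial latent "sluggishness" factor loads negatively on peak speed
and positively on grasp dwell, transport time and corrective counts,
inducing the documented positive coupling between reach-phase and
transport-phase durations (strongest in the 6-year profile).

Gaussian coordinate noise (default 0.3 mm sd — an assumption; the true
capture-volume noise is unreported) and geometric-length dropouts
(capped at 8 frames so they remain auto-repairable) are added last.
Ground truth (event frames, MU counts, rotation components, residual
angle) is computed from the noise-free construction, analytically where
possible and otherwise on an 8× oversampled grid.

Default profile parameters are calibration values chosen to emulate
typical adult / 10-year / 6-year performance on this task (e.g. 296 /
128 / 187 ms latencies, 77 / 64 / 254 ms grasps, 6.5 / 7.5 / 13.3
transport MUs). They define the study conditions the tests run under;
passing tests demonstrate correct recovery of *these* constructions, not
reproduction of any human dataset. Features of real data the generator
does not emulate: soft-tissue marker artefacts, non-Gaussian and
spatially correlated capture noise, hand-opening kinematics of the index
finger (its peak speed matches the wrist's rather than exceeding it),
online feedback corrections coupled to visual error, and failed trials
(drops, wrong hand).

## Statistics layer

Aggregation produces group × condition means with standard errors
(single-trial cells report a missing SE). Correlations are Pearson, or
partial via `pingouin`, computed per group with a default per-test
significance level of 0.005 (the Bonferroni-style convention for large
correlation families); both plain and condition-partialled variants are
available because pooling across conditions can induce or mask
correlations. The ANOVA layer is reporting plumbing on top of
statsmodels: a two-way fixed-effects group × condition model (the
synthetic cohorts have no subject structure to support a mixed design)
with partial η² from Type-II sums of squares and Scheffé-criterion
pairwise group contrasts at the 0.01 level.

## Problem sizes and determinism

The bundled validation suite uses cohorts of 100 trials per profile for
boundary recovery, 40 trials per strategy for the rotation contrast, and
a 3 × 5 × 20 cohort for the study-level signatures; these sizes give the
reported recovery tolerances comfortable statistical margins while
keeping a full run in tens of seconds. All randomness flows through
numpy `SeedSequence`s spawned from a single seed; the same seed yields
byte-identical trial files.

## Known limitations

- Event thresholds (20 / 60 mm/s, 10 °/s, 1 mm, 10 mm radius, 80 mm
  contact radius) are protocol constants; trials recorded under other
  geometries need a re-tuned `AnalysisConfig`.
- The contact and arrival operationalisations (sustained runs with
  trigger levels; spatial radius) are this package's choices where the
  underlying criteria are qualitative; they are exposed in the
  configuration and documented above.
- Rotation durations are conditional on the detection level: slow
  sub-30 °/s rotations are not counted, and residual smearing of ±1–2
  frames per episode edge remains.
- The grasp-duration estimate inherits the 1 mm-lift definition; for
  very short grasps (< 50 ms) the lift and contact bursts merge and the
  estimate degrades gracefully but loses frame-level accuracy.
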