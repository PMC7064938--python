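# reachfit

Kinematic analysis of sequential reach–grasp–transport–fit actions from
3D motion-capture marker trajectories, built for studies of second-order
motor planning (planning a grasp not just for the object in hand but for
what must be done with it next).

The experimental paradigm: a participant grasps a peg from a start holder
and carries it 25 cm to a goal holder whose slot is presented at 0°, 90°,
180° or −90° relative to the frontoparallel axis (plus a round-peg
baseline with no orientation demand). Five markers are tracked at 120 Hz —
wrist, index finger, two markers on the peg top, and a goal marker whose
appearance tells the participant (and the pipeline) when the goal became
visible. From each trial the package extracts:

- **Phase boundaries.** Latency ends at the first frame the wrist's
  tangential speed reaches 20 mm/s; reach-to-grasp runs from five frames
  before that onset to five frames after the wrist-speed low point that
  coincides with the peg markers starting to move (object contact); the
  grasp phase ends when the peg has risen 1 mm from its resting height;
  transport-to-fit ends when, with the peg seated, the wrist moves away
  from the goal at 60 mm/s.
- **Movement units (MUs).** A movement unit is one
  acceleration–deceleration cycle of the speed profile: a velocity peak
  whose accumulated rise and fall both reach 20 mm/s with acceleration
  exceeding 5 mm/s² — the standard proxy for a corrective submovement.
  Per phase the pipeline reports MU counts, peak velocity and its
  placement (PPV, the peak's position as a percentage of segment
  duration), acceleration/deceleration phase split, average velocity and
  3D path distance, for wrist and index finger.
- **Rotation decomposition.** The two peg-top markers define the peg's
  horizontal orientation θ(t) = atan2(Δy, Δx). Rotation time is split at
  arrival (the peg centre entering a 10 mm radius around the goal slot)
  into an in-transport component (**Rota I**, pro-active orientation) and
  an at-goal corrective component (**Rota II**, reactive adjustment),
  counting frames with smoothed |ω| > 10 °/s. The **residual angle**
  |θ(arrival) − θ_goal|, folded to [0°, 180°], measures how predictively
  the peg was oriented.

Because raw study data of this kind are rarely shared, the package
includes a first-class synthetic-trial generator: trials are superposed
minimum-jerk submovements on the task geometry, with calibrated adult /
10-year-old / 6-year-old actor profiles (latencies, durations, MU counts,
and — centrally — the rotation strategy: adults rotate while
transporting, young children correct at the goal). Every generated trial
carries its ground-truth event frames and rotation components, so every
pipeline stage is testable end to end.

## Worked example

```python
from reachfit import simulate_trial, default_profiles, analyze_trial

profile = default_profiles()["adult"]
rec, truth = simulate_trial(profile, "180", seed=7)
tm, bounds, rot = analyze_trial(rec, return_details=True)
print(f"latency          {tm.latency_ms:7.1f} ms   (true {truth.latency_ms:.1f})")
print(f"reach duration   {tm.reach_duration_ms:7.1f} ms   ({tm.reach_wrist_mus} wrist MU)")
print(f"grasp duration   {tm.grasp_duration_ms:7.1f} ms   (true {truth.grasp_dwell_ms:.1f})")
print(f"transport        {tm.transport_duration_ms:7.1f} ms   ({tm.transport_wrist_mus} wrist MU)")
print(f"Rota I / Rota II {tm.rota1_ms:7.1f} / {tm.rota2_ms:.1f} ms")
print(f"residual angle   {tm.residual_angle_deg:7.1f} deg  (true {truth.residual_angle_deg:.1f})")
```

prints

```
latency            233.3 ms   (true 242.6)
reach duration     833.3 ms   (1 wrist MU)
grasp duration      83.3 ms   (true 78.4)
transport         1591.7 ms   (7 wrist MU)
Rota I / Rota II   458.3 / 125.0 ms
residual angle       5.4 deg  (true 5.8)
```

— a pro-active adult trial: one smooth reach, a brief grasp, rotation
essentially finished during transport (Rota II is a short touch-up), and
the peg arriving within ~5° of the 180° goal orientation.

A command-line interface mirrors the library:

```bash
reachfit simulate --profile child6 --condition 180 --n 10 --seed 42 --out trials/
reachfit segment trials/child6_180_000.tsv        # phase boundaries as JSON
reachfit rotate  trials/child6_180_000.tsv        # Rota I/II + residual angle
reachfit analyze trials/manifest.csv --out tables/  # metrics.csv, table1-3.csv
```

Trials are plain tab-separated text (`#rate_hz`/`#condition` headers, one
row per frame, blank cells marking marker dropouts); see
`reachfit.trial_io` for the dialect.

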