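# Methods

## Model and assumptions

The detector treats sleep as the *maximal non-usage episode* of the night.
Its assumptions, stated plainly:

- the participant uses their phone proactively shortly before falling
  asleep and shortly after waking, so the longest gap between proactive
  sessions brackets sleep;
- phone sessions triggered by notifications (reactive use) do not mark
  being awake in any behaviorally meaningful way for sleep bracketing, so
  they are ignored when forming gaps;
- one sleep per night, anchored to a 22:00→10:00 search window; naps,
  split sleep and shift-work schedules are out of scope (the CLI warns when
  a detected sleep is shorter than a 3 h floor).

The nightly procedure: clip candidate gaps to the window by labeling
provisional ("dummy") boundaries at 22:00/10:00, take the argmax of the
clipped durations, then un-clip the winner — its original screen-off before
22:00 or screen-on after 10:00 is resumed as onset/wake. Resumption is
bounded by a noon→noon scan window so it cannot absorb the previous
afternoon. Ties in clipped duration go to the earliest-starting episode and
are flagged. Nights with no candidate gap are reported as missing, never
interpolated; downstream statistics skip them pairwise.

## Algorithm parameters

| parameter | default | meaning |
|---|---|---|
| `reactive_lookback_s` | 60 s | notification window before screen-on that marks reactive use; half-open `[on−60, on)` — a notification exactly 60 s before counts, one in the same second as screen-on does not |
| `flood_threshold` | 500/day | per-(app, calendar day) notification count above which all of that app-day's notifications are dropped (strictly more than) |
| `window_start`/`window_end` | 22:00 / 10:00 | nightly sleep-search window |
| `scan_start`/`scan_end` | 12:00 / 12:00 | per-night bound on candidate episodes and boundary resumption |
| `exclude_first_last_days` | on | drop the nights waking on the log's first and last calendar day |
| `min_sleep_floor_s` | 3 h | below this, a warning (nap/shift-work territory) |
| `weekend_basis` | `wake_date` | weekend night = Sat/Sun morning; `onset_date` classifies by the evening instead |

The flood filter runs *before* classification, and excluded notifications
are invisible to the reactive-lookback test — the exclusion exists
precisely to keep flooding apps from confounding proactive use.

## Numerical conventions

- All event arithmetic is on a whole-second grid; parsed timestamps are
  truncated to the second.
- Midpoint = onset + floor(TST/2) seconds (a 2-s sleep has its midpoint
  1 s after onset; odd durations round to the earlier second).
- Indicator statistics use float "elapsed seconds since midnight" anchored
  at 00:00 of each night's wake date; onsets before midnight are negative.
  On this common scale mean(midpoint) = (mean(onset)+mean(wake))/2 up to
  the 1-s rounding.
- Cohort paired t tests are computed on per-participant means
  (df = participants − 1) by default; night-level pooling is available.
  With zero variance of differences, t is reported as 0 (p = 1) when all
  differences are zero and as undefined (flagged) for a constant nonzero
  shift, never ±∞. No multiple-testing correction is applied.
- Pearson correlations require ≥3 pairs and nonzero variance; otherwise
  they are reported missing with a reason. Social jetlag is an absolute
  difference, so it is invariant to which class is labeled "weekend".
- Simultaneous events order screen-off < notification < screen-on, so a
  same-second off/on pair yields an empty, discarded gap. Sensor glitches
  are repaired deterministically (second screen-on restarts the episode,
  orphan screen-off ignored, trailing screen-on discarded), counted and
  logged; `--strict` parsing fails instead on malformed rows.
- Timestamps may be ISO-8601 or epoch seconds; epoch and zone-aware inputs
  are converted to a configurable participant zone and handled as naive
  local times thereafter. No DST-night flagging is performed (limitation).

### First/last-day exclusion

A night consumes data from two calendar days. The exclusion drops the
nights that *wake* on the log's first day (which cannot exist) and on its
last day, so a 32-day log yields 30 analyzable nights and a 3-day log
yields 1. In field data the first day is additionally incomplete before
install time; the maximal-gap rule degrades gracefully there because an
evening-side candidate still exists whenever any pre-sleep use was
recorded.

## The simulator

`SimParams` defaults describe the study conditions the package is built
around: a late-chronotype student cohort, 28 participants × 32 days
(30 analyzable nights each) starting Monday 2018-02-05.

- **Sleep.** Per participant, a baseline midpoint ~ N(04:54, 90 min) and
  baseline TST ~ N(6.92 h, 45 min) (chronotype spread); per night, jitter
  of 45 min (midpoint) and 60 min (TST), plus a +30 min weekend midpoint
  delay — the ground-truth social jetlag. True boundaries are clipped to
  19:30–04:00 (onset) and 06:00–11:30 (wake) so every simulated night is
  inside the algorithm's detectable range.
- **Usage.** Waking hours are filled by a renewal process: exponential
  inter-session gaps at 4 sessions/h and exponential session lengths of
  mean 300 s (≈5.7 h screen time/day), with anchor sessions ending
  `pre_sleep_gap` before true onset and starting `post_wake_gap` after true
  wake. Both gaps default to 0: the self-report bias parameters already
  absorb the *net* boundary discrepancies that bedtime scrolling and
  lingering in bed produce, and nonzero gaps are exposed for
  mechanism-level experiments (their effect on detection is exact and
  tested).
- **Notifications.** 5 apps at 20/day each as homogeneous streams, plus a
  flooding app at ~600/day constructed to always exceed the 500/day
  exclusion threshold. With probability 0.25 per night a *reactive*
  nocturnal check is inserted: a notification followed 10–50 s later by a
  30–120 s session in mid-sleep.
- **Self-report.** True boundaries shifted by fixed biases (onset −4.0 min,
  wake +10.4 min — the diary reports falling asleep earlier and waking
  later than the device records) plus independent N(0, 30 min) noise per
  boundary, a typical sleep-diary error scale.
- **Randomness.** Each participant's draws come from named substreams
  (sleep, sessions, notifications, flood, checks, self-report) seeded by
  `(seed, participant index)` only. Toggling one process (e.g. nocturnal
  checks, the flooding app) leaves every other draw bit-identical, which
  is what the paired-seed invisibility tests exploit; fixed seeds give
  byte-identical output files.

Two named scenarios fix the experimental designs used by the test suite:
`SimParams.noise_free()` switches off every process that can perturb
detection (notifications, flooding, checks, gaps, self-report error), so
detection must equal ground truth exactly; `SimParams.bias_recovery()`
keeps the self-report bias/noise model but removes detection perturbations,
so the pipeline's paired differences are unbiased estimates of the
configured biases and the app–self midpoint correlation follows the
analytic attenuation r = σ_app / √(σ_app² + σ_noise²/2). Under full
defaults, background notifications occasionally land within 60 s of a
boundary session (≈7% of nights), realistically nudging detected onset
earlier or wake later; that is a feature of the condition, not of the
estimator, which is why parameter-recovery checks use the controlled
scenario.

### What the simulator does not emulate

Real logs contain device reboots, logging dropouts, partial first/last
days, time-zone changes and DST, naps and split sleep, apps whose
notification counts hover near the flood threshold, and weekday-dependent
usage habits. Passing tests therefore demonstrate the algorithm's
correctness under its own behavioral assumptions and its robustness to the
modeled perturbations — not field accuracy, which can only be established
against diaries or actigraphy.

## Problem sizes in the tests

The oracle-equivalence suites use 1000 randomized nights/logs; end-to-end
checks use the full 28 × 32-day cohort for exact recovery and parameter
recovery, and smaller cohorts (≤8 × 12 days) where only structural
equality is asserted. These sizes give stable statistics (e.g. SE of a
mean paired difference ≈ 1 min at 840 nights) while keeping the default
test run fast.

## Known limitations

- A phone left unused for a full day produces a >24 h gap that both
  adjacent nights claim (each clamped to its own scan window); genuinely
  silent nights are reported missing.
- The detector cannot see sleep that starts after noon or ends after the
  following noon, and treats the longest gap as the only sleep of the
  night.
- Sleep efficiency (TST_app / TST_self) is a proxy that treats the
  self-report as time in bed; values above 1 are flagged, not clamped.
- The weekend classifier is calendar-based; cultures or cohorts with other
  workweek structures need the `weekend_basis`/calendar extended.
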