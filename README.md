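# rhythmkit

Sleep and circadian-rhythm inference from passively collected smartphone
screen and notification events.

Smartphone use leaves a second-resolution digital footprint: every
screen-on, screen-off and incoming notification. `rhythmkit` turns a
multi-week stream of those events into one sleep record per night — sleep
onset, wake time, midpoint of sleep, and total sleep time (TST) — and into
cohort-level circadian summaries (midpoint rhythm over the study, social
jetlag, agreement with self-reported sleep). It is aimed at digital
phenotyping and chronobiology researchers who have event logs and nightly
sleep diaries and want a tested, scriptable reference pipeline.

## The algorithm

1. **Episodes.** Screen-on to the successive screen-off is one *usage
   episode*; the gap from a screen-off to the next screen-on is a
   *non-usage episode*.
2. **Proactive vs reactive use.** A usage episode with no notification in
   the minute before screen-on is *proactive* (user-initiated); otherwise
   it is *reactive*. Only proactive episodes bound non-usage episodes, so
   answering a 3 a.m. message does not split the night. To keep
   constantly-buzzing apps from relabeling everything reactive, any app
   posting more than 500 notifications in a calendar day has all of that
   day's notifications excluded first.
3. **Nightly window with dummy boundaries.** For each night, non-usage
   episodes crossing 22:00 / 10:00 get provisional ("dummy") boundaries at
   the window edges. The episode with maximal within-window duration is the
   night's sleep; if the winner carries a dummy boundary, the original
   screen-off before 22:00 or screen-on after 10:00 is resumed as the true
   onset or wake (bounded by a noon-to-noon scan window).
4. **Indicators.** TST = wake − onset; midpoint = onset + TST/2. Agreement
   between an app-recorded night *a* and a self-reported night *s* is the
   overlap ratio

   `OR = |a ∩ s| / ((|a| + |s|) / 2) × 100%`,

   and social jetlag is |mean weekend-night midpoint − mean weeknight
   midpoint| in minutes.

A built-in simulator generates cohorts of event logs with known true sleep
(chronotype spread, weekend phase delay, bedtime/waking phone habits,
reactive nocturnal checks, notification streams including a flooding app,
and biased/noisy self-reports), so the whole pipeline is testable end to
end without any participant data.

## Worked example

```sh
printf 'n_participants: 6\nn_days: 16\n' > params.yaml
rhythmkit simulate --params params.yaml --out sim --seed 7
rhythmkit detect   --events sim --out det
rhythmkit validate --app det/daily_summary.csv --self sim/self_report.csv --out val
```

prints

```
pairs: 84 nights, 6 participants
mean overlap ratio: 93.2%
  onset    app-self   +191.0 s (t(5)=0.57, p=0.591)
  wake     app-self   -608.5 s (t(5)=-3.40, p=0.019)
  midpoint app-self   -208.8 s (t(5)=-1.13, p=0.308)
  tst      app-self   -799.4 s (t(5)=-2.06, p=0.094)
overall midpoint r: 0.965 (N=84)
social jetlag: app 16.7 min, self 29.3 min
sleep efficiency (TSTapp/TSTself): 0.970
```

Reading: across 84 simulated nights the device-detected and self-reported
sleep intervals overlap by 93.2% on average. The paired differences are on
the elapsed-seconds-since-midnight scale: detected wake is about 10 min
earlier than self-reported wake (the simulated participants linger in bed),
so detected TST runs about 13 min short and the TST-over-time-in-bed
efficiency proxy is 0.97. Midpoints of sleep are nearly unbiased and
correlate at r = 0.97, so the circadian phase signal survives the boundary
discrepancies. `det/daily_summary.csv` holds the per-night records;
`val/agreement_report.json` holds the full machine-readable report, and
`rhythmkit report --plot` draws the per-day midpoint rhythm with 1-SD error
bars.

## Library use

```python
from rhythmkit import SimParams, simulate_participant, detect_series

sim = simulate_participant(SimParams.noise_free(n_days=8), 0)
series = detect_series(sim.events, sim.participant_id)
print(series.records[0])
```

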