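# Methods

This document records the monitoring model, the exact rule semantics, the
simulator design, and the numerical and tie-breaking conventions the
package commits to. It is the reference for anyone interpreting alarm
counts produced by the engine or extending the rule base.

## 1. Monitoring model

The system observes a single patient per engine instance through a merged,
time-ordered stream of three event kinds:

* **samples** — physiological measurements; any subset of the six sensors
  may be present on a given sample,
* **care events** — a caregiver performed one activity of a category
  (`measurement`, `medication`, `hygiene`, `feeding`),
* **ticks** — clock events that let time-based rules fire between samples.

Reasoning is organized in three levels over a blackboard-style data store:

* the **strategy rule**: every incoming event starts one reasoning cycle;
* **control rules**: decide which process runs in the cycle. Treatment
  determination runs first, but only when *no physiological alarm is
  active* — this is the focus-of-attention gate: while the patient is in a
  detected emergency, routine-care alerts are suspended, and a deferred
  alert fires on the first cycle after the alarm clears (if still due).
  Physiological reasoning then runs on sample events;
* **knowledge rules**: the detection criteria themselves (§2, §3).

The store is split into *domain data* (latest vitals, per-category care
counters) and *control data* (active situations, current process, and an
append-only trace recording every rule evaluation with its trigger — the
basis for explaining any raised alarm).

There are eight situations: a normal state, three physiological alarm axes
(*abnormal heart*, *abnormal cardiorespiratory function*, *abnormal body
temperature*) and four treatment alert axes (one per care category). Each
axis is independently either inactive or active; the alert log records a
strictly alternating `RAISED`/`CLEARED` sequence per axis, so "number of
alarms" always means number of `RAISED` events.

Assumptions: events arrive in nondecreasing time order (out-of-order input
is rejected, not reordered); timestamps have second resolution; one engine
instance serves one patient; sensor dropout is tolerated (missing vitals
simply skip the clauses that need them).

## 2. Physiological rules

All comparisons are **strict**; the printed criterion value itself is
normal. Defaults (all configurable via `ThresholdConfig` / YAML):

| Quantity | Alarm condition | Default |
| --- | --- | --- |
| Heart rate | > hi or < lo | 100 / 60 bpm |
| Systolic blood pressure | > hi or < lo | 160 / 90 mmHg |
| ECG waveform | peak amplitude outside range, or RR-interval variation above max | 0.5–2.5 mV, CV ≤ 0.15 |
| Breath rate | > hi or < lo | 24 / 8 min⁻¹ |
| SpO2 | < lo | 90 % |
| Body temperature | > hi or < lo | 37 / 35 °C |

*Abnormal heart* fires on heart rate, blood pressure or ECG; *abnormal
cardiorespiratory function* on breath rate or SpO2; *abnormal body
temperature* on temperature. A rule with missing inputs skips the clauses
it cannot evaluate (it cannot fire on absent data).

**Recovery** rules clear an active alarm only when *every* vital of that
axis is present and strictly inside its band (open interval). Alarm and
recovery conditions are therefore mutually exclusive but not exhaustive: a
sample sitting exactly on a boundary neither raises nor clears. This
deliberate hysteresis gap prevents flapping on boundary-hugging values; a
property-based test verifies the mutual exclusion over the whole input
space.

An alarm axis already active is not re-raised by continued violation; one
contiguous abnormal period yields exactly one `RAISED`/`CLEARED` pair.

## 3. Treatment rules

Each category has a plan `(required_per_day, interval)`. At time *t*, with
`count_today` care events of the category so far today and `last_time` the
most recent such event (any day), the alert condition is

```
count_today < required_per_day  AND  (t − last) > interval
```

where `last` falls back to **the start of the current day** when no event
of the category has ever been seen (cold start: the clock starts at
midnight, not at −∞ and not at engine start). The recovery condition is
the exact negation. Comparisons are strict: at elapsed time exactly equal
to the interval, nothing fires.

Counters reset at each local midnight (`count_today` to zero; `last_time`
is preserved across midnight so the elapsed-time clause keeps measuring
real elapsed time). An active treatment alert is cleared by the recovery
rule as soon as care is given or the count requirement is met.

Optional reminder schedules emit informational `REMINDER` events on the
half-open interval `(t_prev, t_now]` between consecutive engine events;
they do not participate in situation state.

## 4. Determinism and tie-breaking

The engine is fully deterministic. When several events share one
timestamp, they are processed in the order *care event → sample → tick*,
with input order breaking remaining ties. Within one cycle the fixed
evaluation order is: treatment categories in declaration order
(measurement, medication, hygiene, feeding), then physiological axes
heart → cardiorespiratory → temperature. `run_stream` inserts ticks every
60 s by default (configurable) between the first and last event.

One visible consequence of the cycle structure: a sample that clears an
alarm does so *after* that cycle's treatment phase (which still saw the
alarm), so a deferred treatment alert fires on the next cycle — possibly
at the same wall-clock second, on a following tick.

## 5. Simulator

`generate_stream` draws baseline vitals from truncated normal
distributions per profile (defaults: HR 72 ± 4 bpm, temperature
36.5 ± 0.2 °C, systolic BP 118 ± 6 mmHg, SpO2 97 ± 1 %, breath
16 ± 2 min⁻¹, ECG amplitude 1.0 ± 0.1 mV, RR CV 0.05 ± 0.01; one sample
per minute). Baselines are clipped to the alarm-free band of each vital
shrunk by 2 % on each side, so a clean stream is *structurally* incapable
of producing a false positive regardless of noise draws. Episodes pin one
vital to `criterion ± magnitude` (default magnitude 5 % of the criterion)
for their duration; overlapping episodes on the same situation axis are
rejected so each episode maps to exactly one `RAISED`/`CLEARED` pair.
Values are rounded to sensor-realistic precision (0.1 for rates and
pressures, 0.01 °C, etc.); timestamps to whole seconds, matching the
archive format's resolution.

`generate_care_events` spaces each category's `k` daily activities evenly
(gap 24 h/k, category-specific phase offsets) and jitters each by at most
±2 min, bounded by a quarter of the slack between gap and interval so
compliant days can never drift into an alert. A *missed* activity omits
the second occurrence of the day (the first, if only one is required),
guaranteeing an overdue period strictly longer than the interval and hence
exactly one alert.

### Benchmark scenario

`build_benchmark_scenario(seed)` creates five patients over seven days
with per-patient injected counts — physiological (3, 7, 7, 5, 3), treatment
(4, 2, 7, 8, 2); 25 + 23 = 48 situations total. The plan requires
measurement/medication/feeding 3×/day (interval 8 h 10 min) and hygiene
2×/day (interval 12 h 10 min). Episodes (kinds cycled across all ten
generators: tachy-/bradycardia, hyper-/hypotension, two ECG anomalies,
tachy-/bradypnea, hypoxia, fever/hypothermia) run 21:00–21:15, a window
disjoint from every possible treatment-alert raise time, so the benchmark
counts are exact by construction rather than by coincidence: each injected
situation yields exactly one raise, and nothing else raises anything.

### Reference detector

`oracle_intervals` is an independent flat per-timepoint scan — no shared
code with the rule or engine modules; the comparisons are written inline —
applying the same criteria, gate, cold-start and tie-break conventions.
Engine/oracle equivalence is asserted over 100+ randomized scenarios
(random episodes, durations, magnitudes, missed-care patterns).

## 6. Verification, and what it does not show

The test suite establishes: exact boundary behaviour of every criterion;
engine ≡ reference detector on randomized inputs; zero alerts on clean
compliant days; the gate invariant (no treatment alert raised inside any
physiological alarm window); one pair per episode; archive and config
round-trips; and the benchmark totals 25/23 with 100 % detection of the
48 injected situations, end to end through the CLI.

That 100 % figure is a property of *this synthetic benchmark*: episodes
exceed criteria decisively, last many sampling periods, and never coincide
with treatment-alert windows. It validates the inference machinery, not
clinical sensitivity/specificity on real sensor data, where noise,
artifacts, dropout bursts and borderline pathology would dominate.

Other limitations: ECG analysis consumes precomputed waveform features
(peak amplitude, RR variation), not raw signal; blood pressure is systolic
only; thresholds are global, not per-patient-adapted; daily counters use
naive local time (no DST/timezone handling); the engine is single-patient
and in-memory (multi-patient deployments run one store per patient, as the
CLI does).

## 7. Reproducibility

All stochastic code takes explicit integer seeds, expanded through
`numpy.random.SeedSequence.spawn` so per-patient and per-component streams
are independent and stable under code reordering. Identical seeds produce
byte-identical archives; `scripts/acceptance.py --seed N` reproduces the
headline numbers deterministically.
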