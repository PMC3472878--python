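# carewatch

Knowledge-based physiological and homecare monitoring for dependent patients
at home, plus a synthetic patient simulator for validating it.

`carewatch` implements a rule-based inference engine that watches two things
at once:

1. **Physiological state** — streamed vital signs (heart rate, blood
   pressure, body temperature, SpO2, breath rate, ECG waveform features) are
   checked against clinical threshold criteria, raising *abnormal heart*,
   *abnormal cardiorespiratory function* and *abnormal body temperature*
   alarms, with explicit recovery rules that clear them.
2. **Treatment compliance** — scheduled care activities (measurement,
   medication, hygiene, feeding) are tracked against a per-category daily
   plan; when a category is under-served and overdue, the engine raises
   *irregular measurement*, *uncharacteristic medication*, *hygiene* or
   *feeding* alerts.

The engine organizes its reasoning in three levels — a strategy rule that
starts a reasoning cycle on every incoming event, control rules that decide
which process runs (treatment determination is *gated*: it is suspended
whenever any physiological alarm is active, so caregiver attention is
focused on the emergency), and knowledge rules that do the detection — over
a shared data store split into domain data (latest vitals, care counters)
and control data (active situations, current process, an auditable rule
trace).

## Quick start

Simulate the built-in five-patient, seven-day benchmark, then replay the
generated archives through the engine and score them against the recorded
ground truth:

```sh
carewatch simulate --benchmark --seed 1 --out sim
carewatch monitor sim/patient-*.xml \
    --config sim/monitor_config.yaml \
    --ground-truth sim/ground_truth.json
```

Output:

```text
ABNORMAL_HEART               raised: 12
ABNORMAL_CARDIORESPIRATORY   raised: 8
ABNORMAL_BODY_TEMPERATURE    raised: 5
IRREGULAR_MEASUREMENT        raised: 7
UNCHARACTERISTIC_MEDICATION  raised: 7
HYGIENE_ALERT                raised: 5
FEEDING_ALERT                raised: 4
physiological alarms total: 25
treatment alerts total:     23
detection accuracy: 48/48 = 100.0%
```

Each simulated patient carries injected physiological episodes (e.g.
hypoxia, fever, bradycardia) and deliberately skipped care activities; the
ground-truth sidecar records exactly what was injected, and `monitor`
reports how many of those situations the engine raised. A plain-text
summary of any archive is available via:

```sh
carewatch report --archive sim/patient-1.xml --config sim/monitor_config.yaml
```

```text
Patient record report: patient-1
Samples: 10080   Care events: 73

Daily vital signs (min / mean / max)
  2025-01-06
    heart_rate         60.80 /    72.27 /   105.00 bpm
    body_temp          35.82 /    36.50 /    36.96 degC
    ...
```

## Library use

```python
from datetime import datetime, timedelta
from carewatch import (
    EngineEvent, TreatmentPlan, default_thresholds, run_stream,
)
from carewatch.simulate import EpisodeSpec, default_profile, generate_stream

cfg = default_thresholds()
plan = TreatmentPlan.uniform(3, timedelta(hours=8, minutes=10))
t0 = datetime(2025, 1, 6)

episode = EpisodeSpec("hypoxia", t0 + timedelta(hours=2), timedelta(minutes=20))
samples, truth = generate_stream(
    default_profile("p1"), t0, t0 + timedelta(hours=6), [episode], seed=4
)
log = run_stream(
    [EngineEvent(sample=s) for s in samples], cfg, plan, patient_id="p1"
)
for alert in log.events:
    print(alert.t, alert.situation.value, alert.phase.value)
```

prints one `RAISED`/`CLEARED` pair on the cardiorespiratory axis bracketing
the injected hypoxia episode.

## Package layout

| Module | Contents |
| --- | --- |
| `carewatch.core` | Data types, situations, threshold/plan configuration, YAML config I/O |
| `carewatch.rules` | Knowledge rules: alarm/alert criteria and their recovery counterparts |
| `carewatch.engine` | Blackboard store, reasoning cycle, stream runner, alert log |
| `carewatch.treatment` | Care-event counters, daily reset, reminder schedules |
| `carewatch.records` | XML patient-record archives and plain-text reports |
| `carewatch.simulate` | Synthetic vitals/care generator, benchmark scenario, reference detector |
| `carewatch.cli` | `carewatch simulate / monitor / report` |
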