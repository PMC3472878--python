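"""Three-level rule-based inference over a stream of monitoring events.

The reasoning cycle mirrors a blackboard architecture:

* **Strategy level** — every new event (sensor sample, care event, or clock
  tick) triggers one reasoning cycle (:func:`step`).
* **Control level** — meta-rules select the processing phase.  While no
  physiological alarm is active the engine first runs the treatment
  determination phase (the four care-category rules); it then advances to
  the physiological reasoning phase whenever fresh sensor data arrived.
  While a physiological alarm is active the treatment phase is skipped
  entirely: caregiver attention is on the alarm, and deferred treatment
  alerts fire on the first cycle after all alarms clear.
* **Knowledge level** — the alarm/alert rules and their recovery rules,
  evaluated in the fixed order heart -> cardiorespiratory -> temperature so
  traces are reproducible.  Rule outcomes are order-independent; only the
  trace order depends on it.

Situations follow a raise/clear hysteresis: a situation is entered once
when its alarm rule fires and left only when its distinct recovery rule
fires, so one sustained excursion produces exactly one RAISED/CLEARED pair.

Clock ticks exist because the treatment rules compare elapsed wall-clock
time: an overdue medication must alert even if no sensor reports anything.
:func:`run_stream` interleaves ticks (default every 60 s) with the data
events automatically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Any, Callable, Iterable, Sequence

from .core import (
    CATEGORIES,
    CATEGORY_SITUATION,
    PHYSIOLOGICAL_ALARMS,
    TREATMENT_ALERTS,
    ActiveSituation,
    AlertEvent,
    AlertPhase,
    GlobalDataStore,
    PhysiologicalSample,
    Process,
    Situation,
    ThresholdConfig,
    TraceEntry,
    TreatmentCounters,
    TreatmentPlan,
)
from . import rules
from .treatment import CareEvent, ReminderSchedule, due_reminders, record_care_event, reset_daily

__all__ = [
    "EngineEvent",
    "AlertLog",
    "SituationReport",
    "new_store",
    "step",
    "run_stream",
    "situation_report",
    "write_alert_log",
    "read_alert_log",
    "write_trace",
]


@dataclass(frozen=True)
class EngineEvent:
    """One input to the engine: exactly one of sample, care event, or tick."""

    sample: PhysiologicalSample | None = None
    care: CareEvent | None = None
    tick: datetime | None = None

    def __post_init__(self) -> None:
        n = sum(x is not None for x in (self.sample, self.care, self.tick))
        if n != 1:
            raise ValueError("an EngineEvent must carry exactly one of sample/care/tick")

    @property
    def t(self) -> datetime:
        if self.sample is not None:
            return self.sample.t
        if self.care is not None:
            return self.care.t
        assert self.tick is not None
        return self.tick

    @property
    def patient_id(self) -> str | None:
        if self.sample is not None:
            return self.sample.patient_id
        if self.care is not None:
            return self.care.patient_id
        return None


@dataclass
class AlertLog:
    """Chronological record of emitted alerts with per-situation tallies.

    Appending enforces the engine's contract that RAISED and CLEARED
    strictly alternate for each (patient, situation) pair.
    """

    events: list[AlertEvent] = field(default_factory=list)
    _open: dict[tuple[str, Situation], bool] = field(default_factory=dict, repr=False)

    def append(self, ev: AlertEvent) -> None:
        if self.events and ev.t < self.events[-1].t:
            raise ValueError(
                f"alert log must be chronological: {ev.t} after {self.events[-1].t}"
            )
        key = (ev.patient_id, ev.situation)
        if ev.phase is AlertPhase.RAISED:
            if self._open.get(key, False):
                raise ValueError(f"{key}: RAISED while already raised")
            self._open[key] = True
        elif ev.phase is AlertPhase.CLEARED:
            if not self._open.get(key, False):
                raise ValueError(f"{key}: CLEARED without a matching RAISED")
            self._open[key] = False
        self.events.append(ev)

    def extend(self, evs: Iterable[AlertEvent]) -> None:
        for ev in evs:
            self.append(ev)

    def raised_counts(self) -> dict[Situation, int]:
        counts: dict[Situation, int] = {}
        for ev in self.events:
            if ev.phase is AlertPhase.RAISED:
                counts[ev.situation] = counts.get(ev.situation, 0) + 1
        return counts

    def intervals(self) -> list[tuple[str, Situation, datetime, datetime | None]]:
        """(patient, situation, raised-at, cleared-at) for every RAISED event.

        The clear time is ``None`` for situations still open at the end of
        the log.
        """
        out: list[tuple[str, Situation, datetime, datetime | None]] = []
        open_idx: dict[tuple[str, Situation], int] = {}
        for ev in self.events:
            key = (ev.patient_id, ev.situation)
            if ev.phase is AlertPhase.RAISED:
                open_idx[key] = len(out)
                out.append((ev.patient_id, ev.situation, ev.t, None))
            elif ev.phase is AlertPhase.CLEARED:
                i = open_idx.pop(key)
                p, s, t0, _ = out[i]
                out[i] = (p, s, t0, ev.t)
        return out


@dataclass(frozen=True)
class SituationReport:
    """Per-situation RAISED counts, with physiological/treatment totals."""

    counts: dict[Situation, int]

    @property
    def physiological_total(self) -> int:
        return sum(self.counts.get(s, 0) for s in PHYSIOLOGICAL_ALARMS)

    @property
    def treatment_total(self) -> int:
        return sum(self.counts.get(s, 0) for s in TREATMENT_ALERTS)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def situation_report(log: AlertLog) -> SituationReport:
    """Tally RAISED events per situation (reminders are not counted)."""
    return SituationReport(counts=log.raised_counts())


def new_store(
    patient_id: str, plan: TreatmentPlan, start: datetime
) -> GlobalDataStore:
    """Initialize a blackboard for one patient at the given stream start time."""
    store = GlobalDataStore(patient_id=patient_id)
    store.domain.plan = plan
    store.domain.counters = TreatmentCounters(day=start.date())
    store.last_event_time = start
    return store


# Physiological axes in fixed evaluation order: (situation, alarm, recovery).
_PHYS_AXES: tuple[tuple[Situation, str, str], ...] = (
    (Situation.ABNORMAL_HEART, "heart", "heart_recovery"),
    (Situation.ABNORMAL_CARDIORESPIRATORY, "cardio", "cardio_recovery"),
    (Situation.ABNORMAL_BODY_TEMPERATURE, "temp", "temp_recovery"),
)


def _eval_phys(
    axis: str, s: PhysiologicalSample, cfg: ThresholdConfig,
    ecg_predicate: rules.EcgPredicate | None,
) -> rules.RuleResult:
    if axis == "heart":
        return rules.eval_heart(s, cfg, ecg_predicate)
    if axis == "heart_recovery":
        return rules.eval_heart_recovery(s, cfg, ecg_predicate)
    if axis == "cardio":
        return rules.eval_cardiorespiratory(s, cfg)
    if axis == "cardio_recovery":
        return rules.eval_cardio_recovery(s, cfg)
    if axis == "temp":
        return rules.eval_temperature(s, cfg)
    assert axis == "temp_recovery"
    return rules.eval_temp_recovery(s, cfg)


def step(
    store: GlobalDataStore,
    ev: EngineEvent,
    cfg: ThresholdConfig,
    schedule: ReminderSchedule | None = None,
    ecg_predicate: rules.EcgPredicate | None = None,
) -> list[AlertEvent]:
    """Run one reasoning cycle on a new event; return the alerts it emitted.

    The cycle: update the domain partition from the event (rolling the
    daily counters at midnight), emit any patient reminders that came due,
    run the treatment determination phase if no physiological alarm is
    active, then run the physiological reasoning phase on fresh sensor
    data.  Every rule evaluation is appended to the control-partition
    trace.
    """
    t = ev.t
    if store.last_event_time is not None and t < store.last_event_time:
        raise ValueError(
            f"out-of-order event: {t} precedes previous event time {store.last_event_time}"
        )
    pid = ev.patient_id
    if pid is not None and pid != store.patient_id:
        raise ValueError(f"unknown patient {pid!r}; this store monitors {store.patient_id!r}")
    if store.domain.plan is None or store.domain.counters is None:
        raise ValueError("store not initialized; use new_store()")

    emitted: list[AlertEvent] = []
    plan = store.domain.plan
    situations = store.control.situations

    # --- domain update -----------------------------------------------------
    store.domain.counters = reset_daily(store.domain.counters, t.date())
    if ev.sample is not None:
        for name, value in ev.sample.present_vitals().items():
            store.domain.latest[name] = (t, value)
        if ev.sample.ecg is not None:
            store.domain.latest["ecg"] = (t, ev.sample.ecg)
    if ev.care is not None:
        store.domain.counters = record_care_event(store.domain.counters, ev.care)

    # --- patient reminders -------------------------------------------------
    if schedule is not None and store.last_event_time is not None and store.last_event_time < t:
        for r in due_reminders(schedule, store.last_event_time, t):
            emitted.append(
                AlertEvent(
                    t=r.t,
                    patient_id=store.patient_id,
                    situation=CATEGORY_SITUATION[r.category],
                    phase=AlertPhase.REMINDER,
                    detail={"category": r.category, "message": r.message},
                )
            )

    # --- treatment determination phase (gated on the normal situation) ----
    if not situations.any_physiological_alarm():
        store.control.current_process = Process.TREATMENT_DETERMINATION
        for category in CATEGORIES:
            situation = CATEGORY_SITUATION[category]
            if situations.is_active(situation):
                rr = rules.eval_treatment_recovery(category, store.domain.counters, plan, t)
                store.control.trace.append(TraceEntry(t, rr.rule_id, rr.fired, rr.trigger))
                if rr.fired:
                    del situations.active[situation]
                    emitted.append(
                        AlertEvent(t, store.patient_id, situation, AlertPhase.CLEARED, rr.trigger)
                    )
            else:
                rr = rules.eval_treatment(category, store.domain.counters, plan, t)
                store.control.trace.append(TraceEntry(t, rr.rule_id, rr.fired, rr.trigger))
                if rr.fired:
                    situations.active[situation] = ActiveSituation(t, rr.trigger)
                    emitted.append(
                        AlertEvent(
                            t, store.patient_id, situation, AlertPhase.RAISED,
                            {**rr.trigger, "video_ref": f"video://{store.patient_id}"},
                        )
                    )

    # --- physiological reasoning phase (on fresh sensor data) --------------
    if ev.sample is not None:
        store.control.current_process = Process.PHYSIOLOGICAL_REASONING
        for situation, alarm_axis, recovery_axis in _PHYS_AXES:
            if situations.is_active(situation):
                rr = _eval_phys(recovery_axis, ev.sample, cfg, ecg_predicate)
                store.control.trace.append(TraceEntry(t, rr.rule_id, rr.fired, rr.trigger))
                if rr.fired:
                    del situations.active[situation]
                    emitted.append(
                        AlertEvent(t, store.patient_id, situation, AlertPhase.CLEARED, rr.trigger)
                    )
            else:
                rr = _eval_phys(alarm_axis, ev.sample, cfg, ecg_predicate)
                store.control.trace.append(TraceEntry(t, rr.rule_id, rr.fired, rr.trigger))
                if rr.fired:
                    situations.active[situation] = ActiveSituation(t, rr.trigger)
                    emitted.append(
                        AlertEvent(
                            t, store.patient_id, situation, AlertPhase.RAISED,
                            {**rr.trigger, "video_ref": f"video://{store.patient_id}"},
                        )
                    )

    store.last_event_time = t
    return emitted


# Tie-break at equal timestamps: care events update counters before the
# engine re-evaluates the treatment rules, samples next, bare ticks last.
_EVENT_PRIORITY = {"care": 0, "sample": 1, "tick": 2}


def _priority(ev: EngineEvent) -> int:
    if ev.care is not None:
        return _EVENT_PRIORITY["care"]
    if ev.sample is not None:
        return _EVENT_PRIORITY["sample"]
    return _EVENT_PRIORITY["tick"]


def run_stream(
    events: Sequence[EngineEvent],
    cfg: ThresholdConfig,
    plan: TreatmentPlan,
    patient_id: str | None = None,
    start: datetime | None = None,
    end: datetime | None = None,
    tick_interval: timedelta = timedelta(seconds=60),
    schedule: ReminderSchedule | None = None,
    ecg_predicate: rules.EcgPredicate | None = None,
    store_out: list[GlobalDataStore] | None = None,
) -> AlertLog:
    """Drive :func:`step` over a sorted event stream for one patient.

    Clock ticks are auto-inserted every ``tick_interval`` between ``start``
    and ``end`` (defaulting to the first/last data event time) so that
    elapsed-time treatment conditions fire even when no new data arrives.
    Deterministic: identical inputs produce identical logs.
    """
    events = list(events)
    for i in range(1, len(events)):
        if events[i].t < events[i - 1].t:
            raise ValueError(
                f"event {i} at {events[i].t} precedes event {i - 1} at {events[i - 1].t}"
            )
    if patient_id is None:
        pids = {p for ev in events if (p := ev.patient_id) is not None}
        if len(pids) != 1:
            raise ValueError(f"cannot infer patient: stream names patients {sorted(pids)}")
        (patient_id,) = pids

    log = AlertLog()
    if not events and start is None:
        return log
    t0 = start if start is not None else events[0].t
    t1 = end if end is not None else (events[-1].t if events else t0)

    ticks: list[EngineEvent] = []
    k, tk = 0, t0
    while tk <= t1:
        ticks.append(EngineEvent(tick=tk))
        k += 1
        tk = t0 + k * tick_interval

    merged = sorted(
        [(ev.t, _priority(ev), i, ev) for i, ev in enumerate(events)]
        + [(ev.t, _priority(ev), len(events) + i, ev) for i, ev in enumerate(ticks)],
        key=lambda item: item[:3],
    )

    store = new_store(patient_id, plan, t0)
    for idx, (_, _, _, ev) in enumerate(merged):
        try:
            log.extend(step(store, ev, cfg, schedule=schedule, ecg_predicate=ecg_predicate))
        except ValueError as exc:
            raise ValueError(f"event {idx} at {ev.t}: {exc}") from exc
    if store_out is not None:
        store_out.append(store)
    return log


# ---------------------------------------------------------------------------
# Sinks: JSON-lines alert log and tab-separated rule trace.

def write_alert_log(log: AlertLog, path: str | Path) -> None:
    """Append-friendly JSON-lines sink: one alert event per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for ev in log.events:
            fh.write(json.dumps(ev.to_json_dict(), sort_keys=True) + "\n")


def read_alert_log(path: str | Path) -> AlertLog:
    log = AlertLog()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                log.append(AlertEvent.from_json_dict(json.loads(line)))
    return log


def write_trace(store: GlobalDataStore, path: str | Path) -> None:
    """Tab-separated rule-firing trace from the control partition."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("t\trule_id\tfired\ttrigger\n")
        for entry in store.control.trace:
            fh.write(
                f"{entry.t.isoformat(timespec='seconds')}\t{entry.rule_id}\t"
                f"{int(entry.fired)}\t{json.dumps(entry.trigger, sort_keys=True, default=str)}\n"
            )
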