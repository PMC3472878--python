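"""Inference engine: reasoning cycle, gating, hysteresis, determinism."""

from __future__ import annotations

from datetime import datetime, timedelta

import pytest

from carewatch.core import (
    AlertPhase,
    CategoryPlan,
    Process,
    Situation,
    TreatmentPlan,
    default_thresholds,
)
from carewatch.engine import (
    AlertLog,
    EngineEvent,
    new_store,
    run_stream,
    situation_report,
    step,
)
from carewatch.treatment import CareEvent

from conftest import make_sample

CFG = default_thresholds()
T0 = datetime(2025, 1, 6, 8, 0)
# Interval exceeds the 8 h between midnight and T0, so a store cold-started
# at T0 has no category overdue yet.
PLAN = TreatmentPlan.uniform(3, timedelta(hours=9))


def _store(t=T0, plan=PLAN, pid="p1"):
    return new_store(pid, plan, t)


class TestStep:
    def test_bradycardia_raises_heart_alarm(self):
        store = _store()
        out = step(store, EngineEvent(sample=make_sample(t=T0, heart_rate=59.0)), CFG)
        assert [(e.situation, e.phase) for e in out] == [
            (Situation.ABNORMAL_HEART, AlertPhase.RAISED)
        ]
        assert out[0].detail["heart_rate"] == 59.0

    def test_treatment_rules_run_before_the_alarm_is_raised(self):
        # same cycle: the treatment phase sees a still-normal situation,
        # so its rules are evaluated before the heart alarm fires
        store = _store()
        step(store, EngineEvent(sample=make_sample(t=T0, heart_rate=59.0)), CFG)
        rule_order = [e.rule_id for e in store.control.trace]
        assert rule_order.index("K8") < rule_order.index("K1")
        assert store.control.current_process is Process.PHYSIOLOGICAL_REASONING

    def test_gate_closed_while_alarm_active(self):
        # overdue medication while a heart alarm is active: no treatment alert
        store = _store()
        step(store, EngineEvent(sample=make_sample(t=T0, heart_rate=59.0)), CFG)
        t1 = T0 + timedelta(hours=5)
        out = step(store, EngineEvent(tick=t1), CFG)
        assert out == []
        assert Situation.UNCHARACTERISTIC_MEDICATION not in store.control.situations.active

    def test_recovery_sample_clears_alarm(self):
        store = _store()
        step(store, EngineEvent(sample=make_sample(t=T0, heart_rate=59.0)), CFG)
        out = step(
            store,
            EngineEvent(sample=make_sample(t=T0 + timedelta(minutes=1), heart_rate=75.0)),
            CFG,
        )
        cleared = [e for e in out if e.phase is AlertPhase.CLEARED]
        assert [e.situation for e in cleared] == [Situation.ABNORMAL_HEART]

    def test_deferred_treatment_alert_fires_after_recovery(self):
        store = _store()
        step(store, EngineEvent(sample=make_sample(t=T0, heart_rate=59.0)), CFG)
        t1 = T0 + timedelta(hours=5)
        assert step(store, EngineEvent(tick=t1), CFG) == []
        # the recovering sample clears the alarm; the treatment phase of that
        # same cycle still saw the alarm, so the deferred alert fires on the
        # next cycle
        out = step(
            store, EngineEvent(sample=make_sample(t=t1 + timedelta(minutes=1))), CFG
        )
        assert [e.situation for e in out] == [Situation.ABNORMAL_HEART]
        out = step(store, EngineEvent(tick=t1 + timedelta(minutes=2)), CFG)
        raised = {e.situation for e in out if e.phase is AlertPhase.RAISED}
        assert Situation.UNCHARACTERISTIC_MEDICATION in raised

    def test_out_of_order_event_rejected_naming_both_times(self):
        store = _store()
        step(store, EngineEvent(tick=T0), CFG)
        with pytest.raises(ValueError) as exc:
            step(store, EngineEvent(tick=T0 - timedelta(seconds=1)), CFG)
        assert str(T0) in str(exc.value)

    def test_unknown_patient_rejected(self):
        store = _store()
        with pytest.raises(ValueError, match="unknown patient"):
            step(store, EngineEvent(sample=make_sample(t=T0, patient_id="p2")), CFG)

    def test_trace_is_append_only_across_cycles(self):
        store = _store()
        step(store, EngineEvent(sample=make_sample(t=T0)), CFG)
        n = len(store.control.trace)
        step(store, EngineEvent(sample=make_sample(t=T0 + timedelta(minutes=1))), CFG)
        assert len(store.control.trace) > n
        assert [e.t for e in store.control.trace] == sorted(e.t for e in store.control.trace)


class TestRunStream:
    def test_empty_stream_empty_log(self):
        assert run_stream([], CFG, PLAN, patient_id="p1").events == []

    def test_hypoxia_episode_one_raise_one_clear(self):
        # SpO2 dips below criterion for 5 minutes then recovers
        events = []
        for i in range(10):
            o = 88.0 if 2 <= i < 7 else 95.0
            events.append(
                EngineEvent(sample=make_sample(t=T0 + timedelta(minutes=i), spo2=o))
            )
        log = run_stream(events, CFG, PLAN, patient_id="p1")
        phases = [
            (e.phase, e.situation)
            for e in log.events
            if e.situation is Situation.ABNORMAL_CARDIORESPIRATORY
        ]
        assert phases == [
            (AlertPhase.RAISED, Situation.ABNORMAL_CARDIORESPIRATORY),
            (AlertPhase.CLEARED, Situation.ABNORMAL_CARDIORESPIRATORY),
        ]

    def test_missed_medication_alert_is_deduplicated_over_a_day(self):
        # no medication ever given: the alert is raised once, not every tick
        plan = TreatmentPlan(
            measurement=CategoryPlan(0, timedelta(hours=8)),
            medication=CategoryPlan(2, timedelta(hours=4)),
            hygiene=CategoryPlan(0, timedelta(hours=8)),
            feeding=CategoryPlan(0, timedelta(hours=8)),
        )
        start = datetime(2025, 1, 6, 0, 0)
        log = run_stream(
            [],
            CFG,
            plan,
            patient_id="p1",
            start=start,
            end=start + timedelta(hours=24),
            tick_interval=timedelta(minutes=5),
        )
        raised = [e for e in log.events if e.phase is AlertPhase.RAISED]
        assert len(raised) == 1
        assert raised[0].situation is Situation.UNCHARACTERISTIC_MEDICATION
        # first tick strictly past the 4-hour interval from start of day
        assert raised[0].t == start + timedelta(hours=4, minutes=5)

    def test_unsorted_stream_rejected_with_index(self):
        events = [
            EngineEvent(tick=T0 + timedelta(minutes=1)),
            EngineEvent(tick=T0),
        ]
        with pytest.raises(ValueError, match="event 1"):
            run_stream(events, CFG, PLAN, patient_id="p1")

    def test_determinism_identical_logs(self):
        events = [
            EngineEvent(sample=make_sample(t=T0 + timedelta(minutes=i), heart_rate=hr))
            for i, hr in enumerate([72, 59, 59, 75, 72])
        ]
        log1 = run_stream(events, CFG, PLAN, patient_id="p1")
        log2 = run_stream(events, CFG, PLAN, patient_id="p1")
        assert [e.to_json_dict() for e in log1.events] == [
            e.to_json_dict() for e in log2.events
        ]

    def test_raising_hr_ceiling_never_adds_heart_alarms(self):
        # monotonicity: a more permissive tachycardia criterion cannot
        # create more heart alarms on a fixed stream
        hrs = [72, 101, 103, 75, 108, 72, 99, 110, 72]
        events = [
            EngineEvent(sample=make_sample(t=T0 + timedelta(minutes=i), heart_rate=float(h)))
            for i, h in enumerate(hrs)
        ]
        counts = []
        for hi in (100.0, 102.0, 105.0, 120.0):
            cfg = default_thresholds().__class__(hr_hi=hi)
            log = run_stream(events, cfg, PLAN, patient_id="p1")
            counts.append(
                situation_report(log).counts.get(Situation.ABNORMAL_HEART, 0)
            )
        assert counts == sorted(counts, reverse=True)


class TestSituationReport:
    def test_counts_and_totals(self):
        log = AlertLog()
        for i in range(3):
            log.append(_alert(i * 2, Situation.ABNORMAL_HEART, AlertPhase.RAISED))
            log.append(_alert(i * 2 + 1, Situation.ABNORMAL_HEART, AlertPhase.CLEARED))
        for i in range(4):
            log.append(
                _alert(10 + 2 * i, Situation.UNCHARACTERISTIC_MEDICATION, AlertPhase.RAISED)
            )
            log.append(
                _alert(11 + 2 * i, Situation.UNCHARACTERISTIC_MEDICATION, AlertPhase.CLEARED)
            )
        rep = situation_report(log)
        assert rep.physiological_total == 3
        assert rep.treatment_total == 4
        assert rep.total == 7

    def test_empty_log_all_zero(self):
        rep = situation_report(AlertLog())
        assert rep.total == rep.physiological_total == rep.treatment_total == 0


def _alert(minute, situation, phase):
    from carewatch.core import AlertEvent

    return AlertEvent(
        t=T0 + timedelta(minutes=minute),
        patient_id="p1",
        situation=situation,
        phase=phase,
        detail={"x": 1} if phase is AlertPhase.RAISED else {},
    )


def test_alert_log_enforces_raise_clear_alternation():
    log = AlertLog()
    log.append(_alert(0, Situation.ABNORMAL_HEART, AlertPhase.RAISED))
    with pytest.raises(ValueError, match="already raised"):
        log.append(_alert(1, Situation.ABNORMAL_HEART, AlertPhase.RAISED))
    log.append(_alert(1, Situation.ABNORMAL_HEART, AlertPhase.CLEARED))
    with pytest.raises(ValueError, match="without a matching"):
        log.append(_alert(2, Situation.ABNORMAL_HEART, AlertPhase.CLEARED))


def test_alert_log_roundtrips_through_jsonl(tmp_path):
    from carewatch.engine import read_alert_log, write_alert_log

    log = AlertLog()
    log.append(_alert(0, Situation.FEEDING_ALERT, AlertPhase.RAISED))
    log.append(_alert(5, Situation.FEEDING_ALERT, AlertPhase.CLEARED))
    path = tmp_path / "alerts.jsonl"
    write_alert_log(log, path)
    back = read_alert_log(path)
    assert [e.to_json_dict() for e in back.events] == [e.to_json_dict() for e in log.events]
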