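"""Knowledge-rule predicates: criteria, hysteresis, and oracle equivalence."""

from __future__ import annotations

import itertools
from datetime import datetime, timedelta

import pytest
from hypothesis import given, settings, strategies as st

from carewatch.core import (
    CATEGORIES,
    CategoryCounters,
    CategoryPlan,
    EcgFeature,
    TreatmentCounters,
    TreatmentPlan,
    default_thresholds,
)
from carewatch.rules import (
    ecg_abnormal,
    eval_cardio_recovery,
    eval_cardiorespiratory,
    eval_heart,
    eval_heart_recovery,
    eval_temp_recovery,
    eval_temperature,
    eval_treatment,
    eval_treatment_recovery,
)

from conftest import make_sample, T0

CFG = default_thresholds()


class TestHeartRules:
    def test_bradycardia_fires(self):
        r = eval_heart(make_sample(heart_rate=59.0), CFG)
        assert r.fired and r.trigger == {"heart_rate": 59.0}

    def test_boundary_values_fire_nothing(self):
        s = make_sample(heart_rate=100.0, blood_pressure=160.0)
        assert not eval_heart(s, CFG).fired
        # the exact boundary satisfies neither the alarm nor the recovery rule
        assert not eval_heart_recovery(s, CFG).fired

    def test_hypertension_fires_with_normal_heart_rate(self):
        r = eval_heart(make_sample(heart_rate=72.0, blood_pressure=165.0), CFG)
        assert r.fired and r.trigger == {"blood_pressure": 165.0}

    def test_abnormal_ecg_alone_fires(self):
        r = eval_heart(make_sample(ecg=EcgFeature(3.0, 0.05)), CFG)
        assert r.fired and "ecg" in r.trigger

    def test_recovery_requires_all_three_axes(self):
        assert eval_heart_recovery(make_sample(heart_rate=75.0, blood_pressure=120.0), CFG).fired
        assert not eval_heart_recovery(
            make_sample(heart_rate=75.0, blood_pressure=120.0, ecg=None), CFG
        ).fired
        assert not eval_heart_recovery(
            make_sample(heart_rate=100.0, blood_pressure=120.0), CFG
        ).fired

    def test_missing_values_cannot_fire_alarm(self):
        s = make_sample(heart_rate=None, blood_pressure=None, ecg=None)
        assert not eval_heart(s, CFG).fired


class TestCardiorespiratoryRules:
    def test_hypoxia_fires(self):
        assert eval_cardiorespiratory(make_sample(spo2=89.0), CFG).fired

    def test_recovery_inside_band(self):
        assert eval_cardio_recovery(make_sample(breath_rate=16.0, spo2=95.0), CFG).fired

    def test_spo2_boundary_hysteresis_gap(self):
        s = make_sample(spo2=90.0, breath_rate=16.0)
        assert not eval_cardiorespiratory(s, CFG).fired
        assert not eval_cardio_recovery(s, CFG).fired


class TestTemperatureRules:
    def test_fever_fires(self):
        assert eval_temperature(make_sample(body_temp=37.5), CFG).fired

    def test_recovery_inside_band(self):
        assert eval_temp_recovery(make_sample(body_temp=36.0), CFG).fired

    def test_boundary_belongs_to_neither_rule(self):
        s = make_sample(body_temp=37.0)
        assert not eval_temperature(s, CFG).fired
        assert not eval_temp_recovery(s, CFG).fired


class TestEcgPredicate:
    @pytest.mark.parametrize(
        "amp,rr_cv,expected",
        [
            (1.0, 0.05, False),
            (3.0, 0.05, True),   # amplitude above the default normal range
            (0.4, 0.05, True),   # amplitude below it
            (1.0, 0.20, True),   # rhythm irregularity above the CV cap
            (2.5, 0.15, False),  # exact boundaries are still normal
        ],
    )
    def test_default_ranges(self, amp, rr_cv, expected):
        assert ecg_abnormal(EcgFeature(amp, rr_cv), CFG) is expected

    def test_pluggable_predicate_overrides_default(self):
        always = lambda e, cfg: True
        assert ecg_abnormal(EcgFeature(1.0, 0.05), CFG, predicate=always)


def _counters(day, **per_cat):
    c = TreatmentCounters(day=day)
    for cat, (count, last) in per_cat.items():
        c.categories[cat] = CategoryCounters(count_today=count, last_time=last)
    return c


class TestTreatmentRules:
    PLAN = TreatmentPlan.uniform(3, timedelta(hours=4))

    def test_overdue_medication_fires(self):
        t = datetime(2025, 1, 6, 13, 0)
        c = _counters(t.date(), medication=(1, t - timedelta(hours=5)))
        r = eval_treatment("medication", c, self.PLAN, t)
        assert r.fired and r.trigger["count_today"] == 1

    def test_met_requirement_never_fires(self):
        t = datetime(2025, 1, 6, 23, 0)
        c = _counters(t.date(), feeding=(3, t - timedelta(hours=10)))
        assert not eval_treatment("feeding", c, self.PLAN, t).fired

    def test_elapsed_exactly_interval_does_not_fire(self):
        t = datetime(2025, 1, 6, 12, 0)
        c = _counters(t.date(), hygiene=(0, t - timedelta(hours=4)))
        assert not eval_treatment("hygiene", c, self.PLAN, t).fired

    def test_cold_start_measures_from_start_of_day(self):
        # no care event yet today or ever: a fully missed morning alerts
        t = datetime(2025, 1, 6, 4, 30)
        c = TreatmentCounters(day=t.date())
        assert eval_treatment("medication", c, self.PLAN, t).fired
        assert not eval_treatment("medication", c, self.PLAN, t.replace(hour=3)).fired

    def test_unknown_category_rejected(self):
        c = TreatmentCounters(day=T0.date())
        with pytest.raises(ValueError):
            eval_treatment("exercise", c, self.PLAN, T0)

    def test_recovery_after_care_event(self):
        t = datetime(2025, 1, 6, 13, 0)
        c = _counters(t.date(), medication=(1, t))
        assert eval_treatment_recovery("medication", c, self.PLAN, t).fired

    def test_recovery_when_count_reaches_requirement(self):
        # brute-force check: the alert condition is false once count == required
        t = datetime(2025, 1, 6, 13, 0)
        c = _counters(t.date(), medication=(3, t - timedelta(hours=6)))
        assert not eval_treatment("medication", c, self.PLAN, t).fired
        assert eval_treatment_recovery("medication", c, self.PLAN, t).fired

    def test_no_recovery_while_condition_holds(self):
        t = datetime(2025, 1, 6, 13, 0)
        c = _counters(t.date(), medication=(1, t - timedelta(hours=5)))
        assert not eval_treatment_recovery("medication", c, self.PLAN, t).fired


# ---------------------------------------------------------------------------
# Properties

_AXES = [
    (eval_heart, eval_heart_recovery),
    (eval_cardiorespiratory, eval_cardio_recovery),
    (eval_temperature, eval_temp_recovery),
]


@settings(max_examples=200, derandomize=True)
@given(
    hr=st.floats(30, 200, allow_nan=False),
    bp=st.floats(40, 250, allow_nan=False),
    breath=st.floats(0, 60, allow_nan=False),
    spo2=st.floats(50, 100, allow_nan=False),
    temp=st.floats(30, 43, allow_nan=False),
    rr_cv=st.floats(0, 0.5, allow_nan=False),
)
def test_alarm_and_recovery_are_mutually_exclusive(hr, bp, breath, spo2, temp, rr_cv):
    """On any sample, an alarm rule and its recovery rule never both fire."""
    s = make_sample(
        heart_rate=hr, blood_pressure=bp, breath_rate=breath, spo2=spo2,
        body_temp=temp, ecg=EcgFeature(1.0, rr_cv),
    )
    for alarm, recovery in _AXES:
        assert not (alarm(s, CFG).fired and recovery(s, CFG).fired)


def _grid(threshold: float, step: float = 0.5, span: int = 4):
    return [threshold + k * step for k in range(-span, span + 1)]


def test_predicates_match_brute_force_truth_table():
    """Each predicate agrees with independently coded comparisons on a grid
    spanning every criterion +-2 units."""
    for hr in _grid(CFG.hr_lo) + _grid(CFG.hr_hi):
        s = make_sample(heart_rate=hr)
        expected = hr > 100.0 or hr < 60.0  # plain literals, not the config
        assert eval_heart(s, CFG).fired is expected
        assert eval_heart_recovery(s, CFG).fired is (60.0 < hr < 100.0)
    for bp in _grid(CFG.bp_lo) + _grid(CFG.bp_hi):
        s = make_sample(blood_pressure=bp)
        assert eval_heart(s, CFG).fired is (bp > 160.0 or bp < 90.0)
    for b in _grid(CFG.breath_lo) + _grid(CFG.breath_hi):
        s = make_sample(breath_rate=b)
        assert eval_cardiorespiratory(s, CFG).fired is (b > 24.0 or b < 8.0)
        assert eval_cardio_recovery(s, CFG).fired is (8.0 < b < 24.0 and True)
    for o in _grid(CFG.spo2_lo):
        s = make_sample(spo2=o)
        assert eval_cardiorespiratory(s, CFG).fired is (o < 90.0)
    for t in _grid(CFG.temp_lo) + _grid(CFG.temp_hi):
        s = make_sample(body_temp=t)
        assert eval_temperature(s, CFG).fired is (t > 37.0 or t < 35.0)
        assert eval_temp_recovery(s, CFG).fired is (35.0 < t < 37.0)


@settings(max_examples=100, derandomize=True)
@given(
    count=st.integers(0, 5),
    required=st.integers(0, 5),
    elapsed_min=st.integers(0, 600),
    interval_min=st.integers(1, 600),
    category=st.sampled_from(CATEGORIES),
)
def test_treatment_alert_and_recovery_partition_the_state_space(
    count, required, elapsed_min, interval_min, category
):
    """Exactly one of the treatment alert / recovery rules holds in any state."""
    t = datetime(2025, 1, 6, 12, 0)
    plan = TreatmentPlan.uniform(required, timedelta(minutes=interval_min))
    c = TreatmentCounters(day=t.date())
    c.categories[category] = CategoryCounters(
        count_today=count, last_time=t - timedelta(minutes=elapsed_min)
    )
    fired = eval_treatment(category, c, plan, t).fired
    recovered = eval_treatment_recovery(category, c, plan, t).fired
    assert fired != recovered
    assert fired is (count < required and elapsed_min > interval_min)
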