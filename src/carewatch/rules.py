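"""Pure predicates for the knowledge rules.

Three physiological alarm rules with matching recovery rules:

* heart (K1/K2): heart rate or systolic blood pressure outside criteria, or
  an abnormal ECG feature pair, raises the abnormal-heart alarm; recovery
  requires every one of heart rate, blood pressure and ECG to be present
  and inside the reference band.
* cardiorespiratory (K3/K4): breath rate outside criteria or SpO2 below its
  floor; recovery requires both inside/above.
* temperature (K5/K6): body temperature outside the 35-37 degC band;
  recovery requires it strictly inside.

Four treatment alert rules (K7-K10, one per care category) share a single
condition: today's count is below the daily requirement AND the time since
the last care event exceeds the category's interval.  Their recovery rules
(R7-R10) fire when that condition no longer holds.

All comparisons are strict, so a value exactly at a criterion fires neither
the alarm nor the recovery rule — alarms have a built-in hysteresis gap.
An alarm clause whose sensor value is missing is skipped (it cannot fire);
a recovery rule requires all of its values present, so an alarm is never
cleared on absent evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Any, Callable

from .core import (
    EcgFeature,
    PhysiologicalSample,
    ThresholdConfig,
    TreatmentCounters,
    TreatmentPlan,
)

__all__ = [
    "RuleResult",
    "ecg_abnormal",
    "eval_heart",
    "eval_heart_recovery",
    "eval_cardiorespiratory",
    "eval_cardio_recovery",
    "eval_temperature",
    "eval_temp_recovery",
    "eval_treatment",
    "eval_treatment_recovery",
    "TREATMENT_RULE_ID",
    "TREATMENT_RECOVERY_RULE_ID",
]

EcgPredicate = Callable[[EcgFeature, ThresholdConfig], bool]


@dataclass(frozen=True)
class RuleResult:
    """Outcome of evaluating one knowledge rule.

    ``trigger`` holds the clause values that satisfied the condition (for a
    fired alarm rule) or, for a fired recovery rule, the values that
    demonstrate recovery.  ``fired=True`` implies a non-empty trigger.
    """

    rule_id: str
    fired: bool
    trigger: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fired and not self.trigger:
            raise ValueError(f"{self.rule_id}: fired result must carry a trigger")


def ecg_abnormal(
    e: EcgFeature,
    cfg: ThresholdConfig,
    predicate: EcgPredicate | None = None,
) -> bool:
    """Abnormal-ECG predicate: magnitude or rhythm irregularity out of range.

    Default: peak amplitude outside ``cfg.ecg_amp_range`` or RR-interval
    coefficient of variation above ``cfg.ecg_rr_cv_max``.  Pass ``predicate``
    to substitute a custom abnormality test.
    """
    if predicate is not None:
        return predicate(e, cfg)
    lo, hi = cfg.ecg_amp_range
    return e.peak_amplitude < lo or e.peak_amplitude > hi or e.rr_cv > cfg.ecg_rr_cv_max


def eval_heart(
    s: PhysiologicalSample,
    cfg: ThresholdConfig,
    ecg_predicate: EcgPredicate | None = None,
) -> RuleResult:
    """Abnormal-heart alarm rule (heart rate / blood pressure / ECG)."""
    trigger: dict[str, Any] = {}
    if s.heart_rate is not None and (s.heart_rate > cfg.hr_hi or s.heart_rate < cfg.hr_lo):
        trigger["heart_rate"] = s.heart_rate
    if s.blood_pressure is not None and (
        s.blood_pressure > cfg.bp_hi or s.blood_pressure < cfg.bp_lo
    ):
        trigger["blood_pressure"] = s.blood_pressure
    if s.ecg is not None and ecg_abnormal(s.ecg, cfg, ecg_predicate):
        trigger["ecg"] = s.ecg
    return RuleResult("K1", bool(trigger), trigger)


def eval_heart_recovery(
    s: PhysiologicalSample,
    cfg: ThresholdConfig,
    ecg_predicate: EcgPredicate | None = None,
) -> RuleResult:
    """Heart-alarm recovery rule: all three axes present and in reference range."""
    ok = (
        s.heart_rate is not None
        and s.blood_pressure is not None
        and s.ecg is not None
        and cfg.hr_lo < s.heart_rate < cfg.hr_hi
        and cfg.bp_lo < s.blood_pressure < cfg.bp_hi
        and not ecg_abnormal(s.ecg, cfg, ecg_predicate)
    )
    trigger = (
        {"heart_rate": s.heart_rate, "blood_pressure": s.blood_pressure, "ecg": s.ecg}
        if ok
        else {}
    )
    return RuleResult("K2", ok, trigger)


def eval_cardiorespiratory(s: PhysiologicalSample, cfg: ThresholdConfig) -> RuleResult:
    """Cardiorespiratory alarm rule (breath rate / blood oxygen saturation)."""
    trigger: dict[str, Any] = {}
    if s.breath_rate is not None and (
        s.breath_rate > cfg.breath_hi or s.breath_rate < cfg.breath_lo
    ):
        trigger["breath_rate"] = s.breath_rate
    if s.spo2 is not None and s.spo2 < cfg.spo2_lo:
        trigger["spo2"] = s.spo2
    return RuleResult("K3", bool(trigger), trigger)


def eval_cardio_recovery(s: PhysiologicalSample, cfg: ThresholdConfig) -> RuleResult:
    """Cardiorespiratory recovery rule: breath rate in band and SpO2 above floor."""
    ok = (
        s.breath_rate is not None
        and s.spo2 is not None
        and cfg.breath_lo < s.breath_rate < cfg.breath_hi
        and s.spo2 > cfg.spo2_lo
    )
    trigger = {"breath_rate": s.breath_rate, "spo2": s.spo2} if ok else {}
    return RuleResult("K4", ok, trigger)


def eval_temperature(s: PhysiologicalSample, cfg: ThresholdConfig) -> RuleResult:
    """Body-temperature alarm rule."""
    fired = s.body_temp is not None and (
        s.body_temp > cfg.temp_hi or s.body_temp < cfg.temp_lo
    )
    return RuleResult("K5", fired, {"body_temp": s.body_temp} if fired else {})


def eval_temp_recovery(s: PhysiologicalSample, cfg: ThresholdConfig) -> RuleResult:
    """Body-temperature recovery rule: strictly inside the reference band."""
    ok = s.body_temp is not None and cfg.temp_lo < s.body_temp < cfg.temp_hi
    return RuleResult("K6", ok, {"body_temp": s.body_temp} if ok else {})


# Rule ids of the treatment alert/recovery rules, by care category.
TREATMENT_RULE_ID: dict[str, str] = {
    "measurement": "K7",
    "medication": "K8",
    "hygiene": "K9",
    "feeding": "K10",
}
TREATMENT_RECOVERY_RULE_ID: dict[str, str] = {
    "measurement": "R7",
    "medication": "R8",
    "hygiene": "R9",
    "feeding": "R10",
}


def _elapsed_since_last_care(
    counters: TreatmentCounters, category: str, t: datetime
) -> timedelta:
    # Cold start: with no recorded care event yet, elapsed time is measured
    # from 00:00 of the current day so a fully missed morning still alerts.
    last = counters.for_category(category).last_time
    if last is None:
        last = datetime.combine(counters.day, datetime.min.time())
    return t - last


def eval_treatment(
    category: str,
    counters: TreatmentCounters,
    plan: TreatmentPlan,
    t: datetime,
) -> RuleResult:
    """Treatment alert rule for one care category.

    Fires iff today's count is below the daily requirement and the elapsed
    time since the last care event strictly exceeds the category interval.
    The caller must have rolled ``counters`` to the calendar day of ``t``.
    """
    cat_plan = plan.for_category(category)
    cc = counters.for_category(category)
    if counters.day != t.date():
        raise ValueError(
            f"counters are for day {counters.day} but event is at {t}; reset first"
        )
    elapsed = _elapsed_since_last_care(counters, category, t)
    fired = cc.count_today < cat_plan.required_per_day and elapsed > cat_plan.interval
    trigger = (
        {
            "category": category,
            "count_today": cc.count_today,
            "required_per_day": cat_plan.required_per_day,
            "last_time": cc.last_time,
            "elapsed_minutes": elapsed.total_seconds() / 60.0,
            "interval_minutes": cat_plan.interval.total_seconds() / 60.0,
        }
        if fired
        else {}
    )
    return RuleResult(TREATMENT_RULE_ID[category], fired, trigger)


def eval_treatment_recovery(
    category: str,
    counters: TreatmentCounters,
    plan: TreatmentPlan,
    t: datetime,
) -> RuleResult:
    """Treatment recovery rule: fires when the alert condition no longer holds.

    Either the daily requirement has been met, or a care event refreshed the
    last-care time so the elapsed gap is back within the interval.
    """
    alert = eval_treatment(category, counters, plan, t)
    if alert.fired:
        return RuleResult(TREATMENT_RECOVERY_RULE_ID[category], False, {})
    cat_plan = plan.for_category(category)
    cc = counters.for_category(category)
    trigger = {
        "category": category,
        "count_today": cc.count_today,
        "required_per_day": cat_plan.required_per_day,
        "last_time": cc.last_time,
    }
    return RuleResult(TREATMENT_RECOVERY_RULE_ID[category], True, trigger)
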