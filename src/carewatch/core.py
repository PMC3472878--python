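"""Domain types, units, and default configuration for homecare monitoring.

The monitoring engine reasons over two kinds of domain data:

* **Physiological features** — timestamped sensor readings: heart rate
  (beats/min), body temperature (degC), systolic blood pressure (mmHg),
  blood oxygen saturation (%), breath rate (breaths/min), and a pair of
  summary ECG features (peak amplitude in mV, coefficient of variation of
  the RR intervals).
* **Treatment features** — per-category daily care requirements
  (measurement, medication, hygiene, feeding) and the running counters
  tracking how often and how recently each kind of care was performed.

Everything here is plain data: validation helpers report problems instead
of raising, so a malformed sensor reading never brings the monitor down.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

__all__ = [
    "CATEGORIES",
    "VITAL_FIELDS",
    "EcgFeature",
    "PhysiologicalSample",
    "ThresholdConfig",
    "default_thresholds",
    "validate_sample",
    "CategoryPlan",
    "TreatmentPlan",
    "CategoryCounters",
    "TreatmentCounters",
    "Situation",
    "PHYSIOLOGICAL_ALARMS",
    "TREATMENT_ALERTS",
    "CATEGORY_SITUATION",
    "SITUATION_CATEGORY",
    "AlertPhase",
    "AlertEvent",
    "ActiveSituation",
    "SituationState",
    "Process",
    "TraceEntry",
    "GlobalDataStore",
    "MonitorConfig",
    "load_config",
    "dump_config",
]

#: The four care categories tracked by the treatment monitor.
CATEGORIES: tuple[str, ...] = ("measurement", "medication", "hygiene", "feeding")

#: Scalar vital-sign fields of a sample (the ECG feature pair is separate).
VITAL_FIELDS: tuple[str, ...] = (
    "heart_rate",
    "body_temp",
    "blood_pressure",
    "spo2",
    "breath_rate",
)


@dataclass(frozen=True)
class EcgFeature:
    """Summary ECG features: R-peak amplitude (mV) and RR-interval variability.

    ``rr_cv`` is the coefficient of variation (SD/mean) of successive cycle
    intervals; large values indicate an irregular rhythm.  These two numbers
    stand in for "abnormal magnitudes and cyclic patterns" — no waveform-level
    processing happens in this package.
    """

    peak_amplitude: float
    rr_cv: float


@dataclass(frozen=True)
class PhysiologicalSample:
    """One timestamped multi-sensor measurement.

    All sensor fields are optional because real devices report
    asynchronously; rules only evaluate the values that are present.
    Timestamps are timezone-naive local time at second resolution.
    """

    patient_id: str
    t: datetime
    heart_rate: float | None = None
    body_temp: float | None = None
    blood_pressure: float | None = None
    spo2: float | None = None
    breath_rate: float | None = None
    ecg: EcgFeature | None = None

    def present_vitals(self) -> dict[str, float]:
        """Mapping of scalar vital name -> value for the fields that are set."""
        return {
            name: v for name in VITAL_FIELDS if (v := getattr(self, name)) is not None
        }


def validate_sample(s: PhysiologicalSample) -> list[str]:
    """Check a sample against its invariants, returning violation messages.

    Returns an empty list when the sample is valid.  Never raises: bad data
    is reported, not fatal.
    """
    problems: list[str] = []
    vitals = s.present_vitals()
    for name, v in vitals.items():
        if not math.isfinite(v):
            problems.append(f"{name} is not finite: {v!r}")
        elif v < 0:
            problems.append(f"{name} is negative: {v!r}")
    if s.spo2 is not None and math.isfinite(s.spo2) and s.spo2 > 100:
        problems.append(f"spo2 exceeds 100%: {s.spo2!r}")
    if s.ecg is not None:
        for name, v in (("peak_amplitude", s.ecg.peak_amplitude), ("rr_cv", s.ecg.rr_cv)):
            if not math.isfinite(v):
                problems.append(f"ecg.{name} is not finite: {v!r}")
            elif v < 0:
                problems.append(f"ecg.{name} is negative: {v!r}")
    if not vitals and s.ecg is None:
        problems.append("no measurements: sample carries no sensor fields")
    return problems


@dataclass(frozen=True)
class ThresholdConfig:
    """Alarm criteria for the physiological rules.

    Defaults follow the conventional adult reference ranges used by the
    knowledge rules: tachycardia above 100 bpm, bradycardia below 60 bpm,
    hyper/hypotension beyond 160/90 mmHg systolic, tachypnea above
    24 breaths/min, bradypnea below 8, hypoxia below 90% SpO2 and a
    febrile/hypothermic band outside 35–37 degC.  All comparisons made with
    these values are strict, so a reading exactly at a criterion fires
    neither the alarm nor the recovery rule (hysteresis gap).

    The ECG feature ranges (normal peak amplitude 0.5–2.5 mV, RR-interval
    CV at most 0.15) are this package's own operational defaults for the
    pluggable ECG abnormality predicate.
    """

    hr_hi: float = 100.0
    hr_lo: float = 60.0
    bp_hi: float = 160.0
    bp_lo: float = 90.0
    breath_hi: float = 24.0
    breath_lo: float = 8.0
    spo2_lo: float = 90.0
    temp_hi: float = 37.0
    temp_lo: float = 35.0
    ecg_amp_range: tuple[float, float] = (0.5, 2.5)
    ecg_rr_cv_max: float = 0.15

    def __post_init__(self) -> None:
        pairs = [
            ("hr", self.hr_lo, self.hr_hi),
            ("bp", self.bp_lo, self.bp_hi),
            ("breath", self.breath_lo, self.breath_hi),
            ("temp", self.temp_lo, self.temp_hi),
            ("ecg_amp", self.ecg_amp_range[0], self.ecg_amp_range[1]),
        ]
        for name, lo, hi in pairs:
            if not lo < hi:
                raise ValueError(f"{name}: lower criterion {lo} must be < upper {hi}")
        # normalize possible list from YAML into a tuple for hashability
        object.__setattr__(self, "ecg_amp_range", tuple(self.ecg_amp_range))


def default_thresholds() -> ThresholdConfig:
    """The package's default alarm criteria (see :class:`ThresholdConfig`)."""
    return ThresholdConfig()


@dataclass(frozen=True)
class CategoryPlan:
    """Daily requirement for one care category.

    ``required_per_day`` is the number of times the procedure must be
    performed per calendar day; ``interval`` is the maximum acceptable gap
    between consecutive occurrences.
    """

    required_per_day: int
    interval: timedelta

    def __post_init__(self) -> None:
        if self.required_per_day < 0:
            raise ValueError("required_per_day must be >= 0")
        if self.interval <= timedelta(0):
            raise ValueError("interval must be positive")


@dataclass(frozen=True)
class TreatmentPlan:
    """Per-patient daily care requirements for the four categories."""

    measurement: CategoryPlan
    medication: CategoryPlan
    hygiene: CategoryPlan
    feeding: CategoryPlan

    def for_category(self, category: str) -> CategoryPlan:
        if category not in CATEGORIES:
            raise ValueError(f"unknown care category: {category!r}")
        return getattr(self, category)

    @classmethod
    def uniform(cls, required_per_day: int, interval: timedelta) -> "TreatmentPlan":
        p = CategoryPlan(required_per_day, interval)
        return cls(p, p, p, p)


@dataclass
class CategoryCounters:
    """Running state for one care category: today's count and last care time."""

    count_today: int = 0
    last_time: datetime | None = None


@dataclass
class TreatmentCounters:
    """Per-patient running care state.

    ``count_today`` values refer to the calendar day ``day``; they reset at
    local midnight.  ``last_time`` survives midnight because the interval
    conditions are plain durations that may span days.
    """

    day: date
    categories: dict[str, CategoryCounters] = field(
        default_factory=lambda: {c: CategoryCounters() for c in CATEGORIES}
    )

    def for_category(self, category: str) -> CategoryCounters:
        if category not in CATEGORIES:
            raise ValueError(f"unknown care category: {category!r}")
        return self.categories[category]

    def copy(self) -> "TreatmentCounters":
        return TreatmentCounters(
            day=self.day,
            categories={c: replace(cc) for c, cc in self.categories.items()},
        )


class Situation(enum.Enum):
    """The eight monitored situations.

    Three physiological alarm situations (heart, cardiorespiratory, body
    temperature), four treatment alert situations (one per care category),
    and the implicit normal situation which holds whenever no physiological
    alarm is active.
    """

    NORMAL = "NORMAL"
    ABNORMAL_HEART = "ABNORMAL_HEART"
    ABNORMAL_CARDIORESPIRATORY = "ABNORMAL_CARDIORESPIRATORY"
    ABNORMAL_BODY_TEMPERATURE = "ABNORMAL_BODY_TEMPERATURE"
    IRREGULAR_MEASUREMENT = "IRREGULAR_MEASUREMENT"
    UNCHARACTERISTIC_MEDICATION = "UNCHARACTERISTIC_MEDICATION"
    HYGIENE_ALERT = "HYGIENE_ALERT"
    FEEDING_ALERT = "FEEDING_ALERT"


PHYSIOLOGICAL_ALARMS: frozenset[Situation] = frozenset(
    {
        Situation.ABNORMAL_HEART,
        Situation.ABNORMAL_CARDIORESPIRATORY,
        Situation.ABNORMAL_BODY_TEMPERATURE,
    }
)

TREATMENT_ALERTS: frozenset[Situation] = frozenset(
    {
        Situation.IRREGULAR_MEASUREMENT,
        Situation.UNCHARACTERISTIC_MEDICATION,
        Situation.HYGIENE_ALERT,
        Situation.FEEDING_ALERT,
    }
)

CATEGORY_SITUATION: dict[str, Situation] = {
    "measurement": Situation.IRREGULAR_MEASUREMENT,
    "medication": Situation.UNCHARACTERISTIC_MEDICATION,
    "hygiene": Situation.HYGIENE_ALERT,
    "feeding": Situation.FEEDING_ALERT,
}

SITUATION_CATEGORY: dict[Situation, str] = {v: k for k, v in CATEGORY_SITUATION.items()}


class AlertPhase(enum.Enum):
    RAISED = "RAISED"
    CLEARED = "CLEARED"
    REMINDER = "REMINDER"


@dataclass(frozen=True)
class AlertEvent:
    """One emitted alarm/alert/recovery/reminder notification.

    ``detail`` carries the triggering measurements or counters so the
    notification is self-contained (no need to re-read the data store).
    """

    t: datetime
    patient_id: str
    situation: Situation
    phase: AlertPhase
    detail: dict[str, Any] = field(default_factory=dict)

    def to_json_dict(self) -> dict[str, Any]:
        return {
            "t": self.t.isoformat(timespec="seconds"),
            "patient_id": self.patient_id,
            "situation": self.situation.value,
            "phase": self.phase.value,
            "detail": {k: _jsonable(v) for k, v in self.detail.items()},
        }

    @classmethod
    def from_json_dict(cls, d: Mapping[str, Any]) -> "AlertEvent":
        return cls(
            t=datetime.fromisoformat(d["t"]),
            patient_id=d["patient_id"],
            situation=Situation(d["situation"]),
            phase=AlertPhase(d["phase"]),
            detail=dict(d.get("detail", {})),
        )


def _jsonable(v: Any) -> Any:
    if isinstance(v, datetime):
        return v.isoformat(timespec="seconds")
    if isinstance(v, timedelta):
        return v.total_seconds()
    if isinstance(v, EcgFeature):
        return {"peak_amplitude": v.peak_amplitude, "rr_cv": v.rr_cv}
    return v


@dataclass
class ActiveSituation:
    entered_at: datetime
    trigger: dict[str, Any]


@dataclass
class SituationState:
    """The set of currently active (non-normal) situations.

    The normal situation is implied exactly when no physiological alarm is
    active; it is never stored explicitly.
    """

    active: dict[Situation, ActiveSituation] = field(default_factory=dict)

    def is_active(self, s: Situation) -> bool:
        return s in self.active

    def any_physiological_alarm(self) -> bool:
        return any(s in PHYSIOLOGICAL_ALARMS for s in self.active)

    def is_normal(self) -> bool:
        return not self.any_physiological_alarm()


class Process(enum.Enum):
    """The engine's current focus-of-attention phase."""

    IDLE = "IDLE"
    TREATMENT_DETERMINATION = "TREATMENT_DETERMINATION"
    PHYSIOLOGICAL_REASONING = "PHYSIOLOGICAL_REASONING"


@dataclass(frozen=True)
class TraceEntry:
    """One rule evaluation recorded in the control partition."""

    t: datetime
    rule_id: str
    fired: bool
    trigger: dict[str, Any]


@dataclass
class DomainData:
    """Domain partition of the blackboard: measurements and care state."""

    latest: dict[str, tuple[datetime, Any]] = field(default_factory=dict)
    counters: TreatmentCounters | None = None
    plan: TreatmentPlan | None = None


@dataclass
class ControlData:
    """Control partition: phase, active situations, and the firing trace."""

    current_process: Process = Process.IDLE
    situations: SituationState = field(default_factory=SituationState)
    trace: list[TraceEntry] = field(default_factory=list)


@dataclass
class GlobalDataStore:
    """Blackboard shared by all rule levels, split into two partitions.

    The domain partition holds the latest value of every sensor and the
    treatment counters/plan; the control partition holds the current
    process phase, the active situation set, and an append-only trace of
    rule firings.  Rules never read control data as if it were a
    measurement.
    """

    patient_id: str
    domain: DomainData = field(default_factory=DomainData)
    control: ControlData = field(default_factory=ControlData)
    last_event_time: datetime | None = None


# ---------------------------------------------------------------------------
# YAML configuration

@dataclass(frozen=True)
class MonitorConfig:
    """Bundle of everything the monitor needs from its config file."""

    thresholds: ThresholdConfig
    plan: TreatmentPlan
    schedule: tuple[dict[str, Any], ...] = ()  # raw {time, category, message} rows


def _plan_to_mapping(plan: TreatmentPlan) -> dict[str, Any]:
    return {
        c: {
            "required_per_day": plan.for_category(c).required_per_day,
            "interval_minutes": plan.for_category(c).interval.total_seconds() / 60.0,
        }
        for c in CATEGORIES
    }


def _plan_from_mapping(m: Mapping[str, Any]) -> TreatmentPlan:
    kwargs = {}
    for c in CATEGORIES:
        row = m[c]
        kwargs[c] = CategoryPlan(
            required_per_day=int(row["required_per_day"]),
            interval=timedelta(minutes=float(row["interval_minutes"])),
        )
    return TreatmentPlan(**kwargs)


def dump_config(cfg: MonitorConfig, path: str | Path) -> None:
    """Write a monitor configuration as YAML (thresholds, plan, schedule)."""
    t = cfg.thresholds
    doc = {
        "thresholds": {
            "hr_hi": t.hr_hi,
            "hr_lo": t.hr_lo,
            "bp_hi": t.bp_hi,
            "bp_lo": t.bp_lo,
            "breath_hi": t.breath_hi,
            "breath_lo": t.breath_lo,
            "spo2_lo": t.spo2_lo,
            "temp_hi": t.temp_hi,
            "temp_lo": t.temp_lo,
            "ecg_amp_range": list(t.ecg_amp_range),
            "ecg_rr_cv_max": t.ecg_rr_cv_max,
        },
        "plan": _plan_to_mapping(cfg.plan),
        "schedule": [dict(row) for row in cfg.schedule],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")


def load_config(path: str | Path) -> MonitorConfig:
    """Read a monitor configuration written by :func:`dump_config`."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(doc, Mapping):
        raise ValueError(f"config {path}: expected a mapping at top level")
    t = doc.get("thresholds", {})
    thresholds = ThresholdConfig(
        **{k: (tuple(v) if k == "ecg_amp_range" else v) for k, v in t.items()}
    )
    plan = _plan_from_mapping(doc["plan"])
    schedule = tuple(dict(row) for row in doc.get("schedule", []) or [])
    return MonitorConfig(thresholds=thresholds, plan=plan, schedule=schedule)
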