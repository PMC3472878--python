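"""Seeded synthetic patient simulator with ground-truth annotation.

The simulator emulates a week-scale home-monitoring deployment at the
feature level (no waveforms): each patient has stable baseline vitals with
Gaussian noise, and abnormal *episodes* are injected by driving one vital
strictly past its alarm criterion for a contiguous interval.  Care events
follow the treatment plan's daily schedule, with selected occurrences
omitted to create treatment irregularities.

Two deliberate structural choices make detection scoring crisp:

* Baseline noise is truncated to the open alarm-free region, so a false
  alarm is impossible outside an injected episode.
* Episode magnitudes default to 5% past the criterion, so every injected
  episode strictly crosses its threshold.

Ground truth (which episodes and misses were injected, and which situation
each should raise) is produced alongside the data so detection accuracy can
be scored without reference to the engine.

:func:`build_benchmark_scenario` constructs the built-in five-patient,
seven-day detection benchmark: per-patient injected counts of (3, 7, 7, 5,
3) physiological episodes and (4, 2, 7, 8, 2) treatment irregularities —
25 and 23 in total.  :func:`oracle_intervals` is an independent flat-scan
reference detector used to cross-check the inference engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

from .core import (
    CATEGORIES,
    CATEGORY_SITUATION,
    CategoryPlan,
    EcgFeature,
    PhysiologicalSample,
    Situation,
    ThresholdConfig,
    TreatmentPlan,
    default_thresholds,
)
from .treatment import CareEvent

__all__ = [
    "EPISODE_KINDS",
    "EPISODE_SITUATION",
    "PatientProfile",
    "EpisodeSpec",
    "MissedCare",
    "GroundTruth",
    "PatientScenario",
    "default_plan",
    "default_profile",
    "generate_stream",
    "generate_care_events",
    "build_benchmark_scenario",
    "BENCHMARK_PHYS_COUNTS",
    "BENCHMARK_TREAT_COUNTS",
    "oracle_intervals",
    "oracle_count",
    "write_ground_truth",
    "read_ground_truth",
]

#: Episode kinds, one per direction of each monitored criterion.
EPISODE_KINDS: tuple[str, ...] = (
    "heart_high",
    "hypoxia",
    "fever",
    "heart_low",
    "tachypnea",
    "bp_high",
    "hypothermia",
    "bradypnea",
    "bp_low",
    "ecg_abnormal",
)

#: Situation each episode kind must raise.
EPISODE_SITUATION: dict[str, Situation] = {
    "heart_high": Situation.ABNORMAL_HEART,
    "heart_low": Situation.ABNORMAL_HEART,
    "bp_high": Situation.ABNORMAL_HEART,
    "bp_low": Situation.ABNORMAL_HEART,
    "ecg_abnormal": Situation.ABNORMAL_HEART,
    "hypoxia": Situation.ABNORMAL_CARDIORESPIRATORY,
    "tachypnea": Situation.ABNORMAL_CARDIORESPIRATORY,
    "bradypnea": Situation.ABNORMAL_CARDIORESPIRATORY,
    "fever": Situation.ABNORMAL_BODY_TEMPERATURE,
    "hypothermia": Situation.ABNORMAL_BODY_TEMPERATURE,
}


def default_plan() -> TreatmentPlan:
    """The benchmark treatment plan.

    Three physiological measurements, three medication doses and three
    meals per day (one per 8-hour span), plus two hygiene procedures (one
    per 12-hour span).  Each interval is the even spacing plus a 10-minute
    grace so a fully compliant schedule never trips the elapsed-time
    condition, including across midnight.
    """
    return TreatmentPlan(
        measurement=CategoryPlan(3, timedelta(hours=8, minutes=10)),
        medication=CategoryPlan(3, timedelta(hours=8, minutes=10)),
        hygiene=CategoryPlan(2, timedelta(hours=12, minutes=10)),
        feeding=CategoryPlan(3, timedelta(hours=8, minutes=10)),
    )


@dataclass(frozen=True)
class PatientProfile:
    """Baseline vital-sign distribution and care plan for one simulated patient.

    Defaults are healthy-adult resting values: HR 72+-4 bpm, temperature
    36.5+-0.2 degC, systolic pressure 118+-6 mmHg, SpO2 97+-1 %, breath
    rate 16+-2 /min, ECG peak 1.0+-0.1 mV with RR-interval CV 0.05+-0.01.
    Vitals are sampled every ``sampling_period``.
    """

    patient_id: str
    hr_mean: float = 72.0
    hr_sd: float = 4.0
    temp_mean: float = 36.5
    temp_sd: float = 0.2
    bp_mean: float = 118.0
    bp_sd: float = 6.0
    spo2_mean: float = 97.0
    spo2_sd: float = 1.0
    breath_mean: float = 16.0
    breath_sd: float = 2.0
    ecg_amp_mean: float = 1.0
    ecg_amp_sd: float = 0.1
    ecg_rr_cv_mean: float = 0.05
    ecg_rr_cv_sd: float = 0.01
    sampling_period: timedelta = timedelta(seconds=60)
    plan: TreatmentPlan = field(default_factory=default_plan)

    def __post_init__(self) -> None:
        for name in (
            "hr_sd", "temp_sd", "bp_sd", "spo2_sd", "breath_sd",
            "ecg_amp_sd", "ecg_rr_cv_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def default_profile(patient_id: str) -> PatientProfile:
    return PatientProfile(patient_id=patient_id)


@dataclass(frozen=True)
class EpisodeSpec:
    """One injected abnormal interval.

    ``magnitude`` is how far past the relevant criterion the targeted vital
    is driven, in the vital's own units; ``None`` means the default of 5%
    of the criterion's magnitude.
    """

    kind: str
    start: datetime
    duration: timedelta
    magnitude: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in EPISODE_SITUATION:
            raise ValueError(f"unknown episode kind {self.kind!r}")
        if self.duration <= timedelta(0):
            raise ValueError("episode duration must be positive")
        if self.magnitude is not None and self.magnitude <= 0:
            raise ValueError("episode magnitude must be positive")

    @property
    def end(self) -> datetime:
        return self.start + self.duration

    @property
    def situation(self) -> Situation:
        return EPISODE_SITUATION[self.kind]


@dataclass(frozen=True)
class MissedCare:
    """One omitted scheduled care occurrence: (day index, category)."""

    day: int
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown care category: {self.category!r}")
        if self.day < 0:
            raise ValueError("day index must be >= 0")


@dataclass
class GroundTruth:
    """What was injected, and which situation each injection should raise."""

    episodes: list[tuple[EpisodeSpec, Situation]] = field(default_factory=list)
    missed_care: list[MissedCare] = field(default_factory=list)

    @property
    def physiological_count(self) -> int:
        return len(self.episodes)

    @property
    def treatment_count(self) -> int:
        return len(self.missed_care)


@dataclass
class PatientScenario:
    """Everything the monitor needs to replay one simulated patient."""

    profile: PatientProfile
    start: datetime
    end: datetime
    samples: list[PhysiologicalSample]
    care_events: list[CareEvent]
    ground_truth: GroundTruth
    seed: int


# ---------------------------------------------------------------------------
# Vital-sign stream generation

def _episode_value(kind: str, cfg: ThresholdConfig, magnitude: float | None) -> float:
    """The out-of-range value an episode pins its targeted feature to."""
    criterion = {
        "heart_high": cfg.hr_hi,
        "heart_low": cfg.hr_lo,
        "bp_high": cfg.bp_hi,
        "bp_low": cfg.bp_lo,
        "hypoxia": cfg.spo2_lo,
        "tachypnea": cfg.breath_hi,
        "bradypnea": cfg.breath_lo,
        "fever": cfg.temp_hi,
        "hypothermia": cfg.temp_lo,
        "ecg_abnormal": cfg.ecg_rr_cv_max,
    }[kind]
    if magnitude is None:
        magnitude = 0.05 * abs(criterion)
    below = kind in {"heart_low", "bp_low", "hypoxia", "bradypnea", "hypothermia"}
    return criterion - magnitude if below else criterion + magnitude


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    """Gaussian draw clipped into [lo, hi] (simple clipping, not resampling)."""
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _safe_bands(cfg: ThresholdConfig) -> dict[str, tuple[float, float]]:
    # Open alarm-free regions, shrunk by 2% of the band width so that a
    # clipped draw is strictly inside and recovery rules can always fire.
    def band(lo: float, hi: float) -> tuple[float, float]:
        m = 0.02 * (hi - lo)
        return (lo + m, hi - m)

    amp_lo, amp_hi = cfg.ecg_amp_range
    return {
        "heart_rate": band(cfg.hr_lo, cfg.hr_hi),
        "blood_pressure": band(cfg.bp_lo, cfg.bp_hi),
        "breath_rate": band(cfg.breath_lo, cfg.breath_hi),
        "body_temp": band(cfg.temp_lo, cfg.temp_hi),
        "spo2": (cfg.spo2_lo + 0.02 * (100.0 - cfg.spo2_lo), 100.0),
        "ecg_amp": band(amp_lo, amp_hi),
        "ecg_rr_cv": (0.0, 0.98 * cfg.ecg_rr_cv_max),
    }


#: Which sample field each episode kind overrides.
_EPISODE_FIELD: dict[str, str] = {
    "heart_high": "heart_rate",
    "heart_low": "heart_rate",
    "bp_high": "blood_pressure",
    "bp_low": "blood_pressure",
    "hypoxia": "spo2",
    "tachypnea": "breath_rate",
    "bradypnea": "breath_rate",
    "fever": "body_temp",
    "hypothermia": "body_temp",
    "ecg_abnormal": "ecg_rr_cv",
}


def generate_stream(
    profile: PatientProfile,
    start: datetime,
    end: datetime,
    episodes: Sequence[EpisodeSpec],
    seed: int | np.random.SeedSequence,
    cfg: ThresholdConfig | None = None,
) -> tuple[list[PhysiologicalSample], GroundTruth]:
    """Generate the patient's vital-sign samples over [start, end).

    Outside episodes every vital is baseline noise truncated to the open
    alarm-free region; inside an episode the targeted feature is pinned
    strictly past its criterion.  Identical seeds give identical streams.
    Episodes that overlap on the same situation axis are rejected.
    """
    if not start < end:
        raise ValueError(f"start {start} must precede end {end}")
    cfg = cfg if cfg is not None else default_thresholds()
    eps = sorted(episodes, key=lambda e: (e.start, e.kind))
    for e in eps:
        if e.start < start or e.end > end:
            raise ValueError(f"episode {e.kind} at {e.start} outside [{start}, {end}]")
    by_axis: dict[Situation, list[EpisodeSpec]] = {}
    for e in eps:
        by_axis.setdefault(e.situation, []).append(e)
    for axis, axis_eps in by_axis.items():
        for a, b in zip(axis_eps, axis_eps[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping episodes on {axis.value}: "
                    f"{a.kind}@{a.start} and {b.kind}@{b.start}"
                )

    rng = np.random.default_rng(seed)
    bands = _safe_bands(cfg)
    samples: list[PhysiologicalSample] = []
    t = start
    while t < end:
        values = {
            "heart_rate": _truncnorm(rng, profile.hr_mean, profile.hr_sd, *bands["heart_rate"]),
            "body_temp": _truncnorm(rng, profile.temp_mean, profile.temp_sd, *bands["body_temp"]),
            "blood_pressure": _truncnorm(rng, profile.bp_mean, profile.bp_sd, *bands["blood_pressure"]),
            "spo2": _truncnorm(rng, profile.spo2_mean, profile.spo2_sd, *bands["spo2"]),
            "breath_rate": _truncnorm(rng, profile.breath_mean, profile.breath_sd, *bands["breath_rate"]),
            "ecg_amp": _truncnorm(rng, profile.ecg_amp_mean, profile.ecg_amp_sd, *bands["ecg_amp"]),
            "ecg_rr_cv": _truncnorm(rng, profile.ecg_rr_cv_mean, profile.ecg_rr_cv_sd, *bands["ecg_rr_cv"]),
        }
        for e in eps:
            if e.start <= t < e.end:
                values[_EPISODE_FIELD[e.kind]] = _episode_value(e.kind, cfg, e.magnitude)
        samples.append(
            PhysiologicalSample(
                patient_id=profile.patient_id,
                t=t,
                heart_rate=round(values["heart_rate"], 1),
                body_temp=round(values["body_temp"], 2),
                blood_pressure=round(values["blood_pressure"], 1),
                spo2=round(values["spo2"], 1),
                breath_rate=round(values["breath_rate"], 1),
                ecg=EcgFeature(
                    peak_amplitude=round(values["ecg_amp"], 3),
                    rr_cv=round(values["ecg_rr_cv"], 4),
                ),
            )
        )
        t += profile.sampling_period

    truth = GroundTruth(episodes=[(e, e.situation) for e in eps])
    return samples, truth


# ---------------------------------------------------------------------------
# Care-event generation

# Phase of the first daily occurrence within the even spacing, per category,
# so the four categories never coincide.
_CATEGORY_PHASE: dict[str, float] = {
    "measurement": 0.125,
    "medication": 0.25,
    "hygiene": 0.25,
    "feeding": 0.5,
}


def _daily_times(category: str, k: int) -> list[timedelta]:
    """Evenly spaced times-of-day for k occurrences of a category."""
    gap = timedelta(days=1) / k
    phase = _CATEGORY_PHASE[category] * gap
    return [phase + i * gap for i in range(k)]


def generate_care_events(
    plan: TreatmentPlan,
    days: int,
    missed: Sequence[MissedCare],
    seed: int | np.random.SeedSequence,
    patient_id: str = "patient",
    start_date: date = date(2025, 1, 6),
    jitter: timedelta = timedelta(minutes=2),
) -> list[CareEvent]:
    """Scheduled care events over ``days`` days, with selected omissions.

    Compliant days place each category's ``required_per_day`` occurrences
    evenly around the clock (so consecutive occurrences — including the
    overnight gap — are closer together than the category interval) with a
    small uniform timing jitter.  A :class:`MissedCare` omits one
    occurrence, opening a gap wider than the interval so the corresponding
    alert condition holds at some point that day.
    """
    missed_set = set()
    for m in missed:
        if m.day >= days:
            raise ValueError(f"missed-care day {m.day} outside horizon of {days} days")
        if plan.for_category(m.category).required_per_day == 0:
            raise ValueError(
                f"cannot miss {m.category}: plan requires 0 per day (nothing to miss)"
            )
        missed_set.add((m.day, m.category))

    rng = np.random.default_rng(seed)
    events: list[CareEvent] = []
    for category in CATEGORIES:
        cat_plan = plan.for_category(category)
        k = cat_plan.required_per_day
        if k == 0:
            continue
        gap = timedelta(days=1) / k
        if cat_plan.interval <= gap:
            raise ValueError(
                f"{category}: interval {cat_plan.interval} must exceed the even "
                f"spacing {gap} of {k} daily occurrences, or compliant days would alert"
            )
        if 2 * gap <= cat_plan.interval:
            raise ValueError(
                f"{category}: interval {cat_plan.interval} is at least twice the even "
                f"spacing {gap}; omitting one occurrence could not trigger an alert"
            )
        # Jitter kept well under the schedule's slack so compliant gaps stay
        # below the interval and a miss's doubled gap stays above it.
        slack = (cat_plan.interval - gap) / 4
        jit = min(jitter, slack)
        miss_index = 1 if k >= 2 else 0
        for day in range(days):
            d = start_date + timedelta(days=day)
            for i, tod in enumerate(_daily_times(category, k)):
                if (day, category) in missed_set and i == miss_index:
                    continue
                # whole seconds: archives store second-resolution timestamps
                offset = timedelta(seconds=round(float(rng.uniform(-1, 1)) * jit.total_seconds()))
                events.append(
                    CareEvent(
                        patient_id=patient_id,
                        t=datetime.combine(d, time()) + tod + offset,
                        category=category,
                    )
                )
    events.sort(key=lambda e: (e.t, e.category))
    return events


# ---------------------------------------------------------------------------
# Built-in five-patient benchmark

#: Injected physiological-episode counts for the five benchmark patients.
BENCHMARK_PHYS_COUNTS: tuple[int, ...] = (3, 7, 7, 5, 3)
#: Injected treatment-irregularity counts for the five benchmark patients.
BENCHMARK_TREAT_COUNTS: tuple[int, ...] = (4, 2, 7, 8, 2)
BENCHMARK_DAYS = 7


def build_benchmark_scenario(
    seed: int,
    start: datetime = datetime(2025, 1, 6),
    cfg: ThresholdConfig | None = None,
) -> list[PatientScenario]:
    """The built-in five-patient, seven-day detection benchmark.

    Patient ``i`` receives ``BENCHMARK_PHYS_COUNTS[i]`` physiological
    episodes (one per day at 21:00, 15 minutes long, kinds cycled through
    all ten episode kinds across patients) and
    ``BENCHMARK_TREAT_COUNTS[i]`` treatment irregularities (days cycled
    round-robin, categories cycled through all four).  Ground-truth totals
    are 25 physiological episodes and 23 treatment irregularities.
    """
    cfg = cfg if cfg is not None else default_thresholds()
    end = start + timedelta(days=BENCHMARK_DAYS)
    root_ss = np.random.SeedSequence(seed)
    patient_seeds = root_ss.spawn(len(BENCHMARK_PHYS_COUNTS))

    scenarios: list[PatientScenario] = []
    kind_cursor = 0
    for i, (n_phys, n_treat) in enumerate(zip(BENCHMARK_PHYS_COUNTS, BENCHMARK_TREAT_COUNTS)):
        pid = f"patient-{i + 1}"
        profile = default_profile(pid)

        episodes = []
        for j in range(n_phys):
            kind = EPISODE_KINDS[kind_cursor % len(EPISODE_KINDS)]
            kind_cursor += 1
            episodes.append(
                EpisodeSpec(
                    kind=kind,
                    start=start + timedelta(days=j, hours=21),
                    duration=timedelta(minutes=15),
                )
            )

        missed = [
            MissedCare(day=j % BENCHMARK_DAYS, category=CATEGORIES[j % len(CATEGORIES)])
            for j in range(n_treat)
        ]

        stream_ss, care_ss = patient_seeds[i].spawn(2)
        samples, truth = generate_stream(profile, start, end, episodes, stream_ss, cfg)
        care_events = generate_care_events(
            profile.plan,
            BENCHMARK_DAYS,
            missed,
            care_ss,
            patient_id=pid,
            start_date=start.date(),
        )
        truth.missed_care = list(missed)
        scenarios.append(
            PatientScenario(
                profile=profile,
                start=start,
                end=end,
                samples=samples,
                care_events=care_events,
                ground_truth=truth,
                seed=seed,
            )
        )
    return scenarios


# ---------------------------------------------------------------------------
# Scenario configuration (YAML)

def scenarios_from_config(
    doc: Mapping[str, Any], seed: int | None = None
) -> list[PatientScenario]:
    """Build scenarios from a parsed YAML scenario document.

    Schema::

        seed: 1
        start: "2025-01-06T00:00:00"
        days: 7
        patients:
          - patient_id: p1
            episodes:
              - {kind: hypoxia, start: "2025-01-06T10:00:00", duration_minutes: 15}
            missed:
              - {day: 0, category: medication}

    ``seed`` overrides the document's seed when given.
    """
    if seed is None:
        seed = int(doc.get("seed", 0))
    start = datetime.fromisoformat(doc["start"])
    days = int(doc.get("days", 7))
    end = start + timedelta(days=days)
    root_ss = np.random.SeedSequence(seed)
    patients = doc.get("patients") or []
    seeds = root_ss.spawn(max(len(patients), 1))

    scenarios: list[PatientScenario] = []
    for i, row in enumerate(patients):
        pid = row["patient_id"]
        profile = default_profile(pid)
        episodes = [
            EpisodeSpec(
                kind=e["kind"],
                start=datetime.fromisoformat(e["start"]),
                duration=timedelta(minutes=float(e.get("duration_minutes", 15))),
                magnitude=e.get("magnitude"),
            )
            for e in row.get("episodes") or []
        ]
        missed = [
            MissedCare(day=int(m["day"]), category=m["category"])
            for m in row.get("missed") or []
        ]
        stream_ss, care_ss = seeds[i].spawn(2)
        samples, truth = generate_stream(profile, start, end, episodes, stream_ss)
        care_events = generate_care_events(
            profile.plan, days, missed, care_ss, patient_id=pid, start_date=start.date()
        )
        truth.missed_care = list(missed)
        scenarios.append(
            PatientScenario(
                profile=profile,
                start=start,
                end=end,
                samples=samples,
                care_events=care_events,
                ground_truth=truth,
                seed=seed,
            )
        )
    return scenarios


# ---------------------------------------------------------------------------
# Independent reference detector (brute-force flat scan)

def oracle_intervals(
    samples: Sequence[PhysiologicalSample],
    care_events: Sequence[CareEvent],
    cfg: ThresholdConfig,
    plan: TreatmentPlan,
    start: datetime | None = None,
    end: datetime | None = None,
    tick_interval: timedelta = timedelta(seconds=60),
) -> list[tuple[Situation, datetime, datetime | None]]:
    """Reference detection by direct per-timepoint scan.

    Re-evaluates every alarm/recovery condition at every time point with
    explicit hysteresis bookkeeping, using inline comparisons — it shares
    no code path with the rule or engine modules.  Treatment conditions are
    checked only while no physiological alarm is on, mirroring the
    engine's focus-of-attention gate.  Returns (situation, raised-at,
    cleared-at) intervals in raise order.
    """
    points: list[tuple[datetime, int, int, str, object]] = []
    for i, s in enumerate(samples):
        points.append((s.t, 1, i, "sample", s))
    for i, c in enumerate(care_events):
        points.append((c.t, 0, i, "care", c))
    if points:
        t0 = start if start is not None else min(p[0] for p in points)
        t1 = end if end is not None else max(p[0] for p in points)
    elif start is not None and end is not None:
        t0, t1 = start, end
    else:
        return []
    k, tk = 0, t0
    while tk <= t1:
        points.append((tk, 2, k, "tick", None))
        k += 1
        tk = t0 + k * tick_interval
    points.sort(key=lambda p: (p[0], p[1], p[2]))

    counts = {c: 0 for c in CATEGORIES}
    last: dict[str, datetime | None] = {c: None for c in CATEGORIES}
    day = t0.date()
    phys_on = {
        Situation.ABNORMAL_HEART: False,
        Situation.ABNORMAL_CARDIORESPIRATORY: False,
        Situation.ABNORMAL_BODY_TEMPERATURE: False,
    }
    treat_on = {c: False for c in CATEGORIES}
    raised_at: dict[object, datetime] = {}
    out: list[tuple[Situation, datetime, datetime | None]] = []
    open_idx: dict[tuple[Situation, datetime], int] = {}

    def raise_sit(sit: Situation, t: datetime) -> None:
        open_idx[(sit, t)] = len(out)
        raised_at[sit] = t
        out.append((sit, t, None))

    def clear_sit(sit: Situation, t: datetime) -> None:
        i = open_idx.pop((sit, raised_at.pop(sit)))
        s, t0_, _ = out[i]
        out[i] = (s, t0_, t)

    for t, _prio, _i, kind, payload in points:
        if t.date() > day:
            day = t.date()
            counts = {c: 0 for c in CATEGORIES}
        if kind == "care":
            c: CareEvent = payload  # type: ignore[assignment]
            counts[c.category] += 1
            last[c.category] = c.t

        # treatment determination, gated on no physiological alarm
        if not any(phys_on.values()):
            for cat in CATEGORIES:
                req = plan.for_category(cat).required_per_day
                iv = plan.for_category(cat).interval
                anchor = last[cat] if last[cat] is not None else datetime.combine(day, time())
                due = counts[cat] < req and (t - anchor) > iv
                sit = CATEGORY_SITUATION[cat]
                if treat_on[cat] and not due:
                    treat_on[cat] = False
                    clear_sit(sit, t)
                elif not treat_on[cat] and due:
                    treat_on[cat] = True
                    raise_sit(sit, t)

        if kind == "sample":
            s: PhysiologicalSample = payload  # type: ignore[assignment]
            amp_lo, amp_hi = cfg.ecg_amp_range
            ecg_bad = s.ecg is not None and (
                s.ecg.peak_amplitude < amp_lo
                or s.ecg.peak_amplitude > amp_hi
                or s.ecg.rr_cv > cfg.ecg_rr_cv_max
            )
            heart_bad = (
                (s.heart_rate is not None and (s.heart_rate > cfg.hr_hi or s.heart_rate < cfg.hr_lo))
                or (
                    s.blood_pressure is not None
                    and (s.blood_pressure > cfg.bp_hi or s.blood_pressure < cfg.bp_lo)
                )
                or ecg_bad
            )
            heart_ok = (
                s.heart_rate is not None
                and s.blood_pressure is not None
                and s.ecg is not None
                and cfg.hr_lo < s.heart_rate < cfg.hr_hi
                and cfg.bp_lo < s.blood_pressure < cfg.bp_hi
                and not ecg_bad
            )
            resp_bad = (
                s.breath_rate is not None
                and (s.breath_rate > cfg.breath_hi or s.breath_rate < cfg.breath_lo)
            ) or (s.spo2 is not None and s.spo2 < cfg.spo2_lo)
            resp_ok = (
                s.breath_rate is not None
                and s.spo2 is not None
                and cfg.breath_lo < s.breath_rate < cfg.breath_hi
                and s.spo2 > cfg.spo2_lo
            )
            temp_bad = s.body_temp is not None and (
                s.body_temp > cfg.temp_hi or s.body_temp < cfg.temp_lo
            )
            temp_ok = s.body_temp is not None and cfg.temp_lo < s.body_temp < cfg.temp_hi
            for sit, bad, ok in (
                (Situation.ABNORMAL_HEART, heart_bad, heart_ok),
                (Situation.ABNORMAL_CARDIORESPIRATORY, resp_bad, resp_ok),
                (Situation.ABNORMAL_BODY_TEMPERATURE, temp_bad, temp_ok),
            ):
                if phys_on[sit] and ok:
                    phys_on[sit] = False
                    clear_sit(sit, t)
                elif not phys_on[sit] and bad:
                    phys_on[sit] = True
                    raise_sit(sit, t)

    return out


def oracle_count(
    samples: Sequence[PhysiologicalSample],
    care_events: Sequence[CareEvent],
    cfg: ThresholdConfig,
    plan: TreatmentPlan,
    start: datetime | None = None,
    end: datetime | None = None,
    tick_interval: timedelta = timedelta(seconds=60),
) -> tuple[int, int]:
    """(physiological alarm count, treatment alert count) per the flat-scan oracle."""
    intervals = oracle_intervals(samples, care_events, cfg, plan, start, end, tick_interval)
    phys = sum(
        1
        for sit, _, _ in intervals
        if sit in (
            Situation.ABNORMAL_HEART,
            Situation.ABNORMAL_CARDIORESPIRATORY,
            Situation.ABNORMAL_BODY_TEMPERATURE,
        )
    )
    return phys, len(intervals) - phys


# ---------------------------------------------------------------------------
# Ground-truth sidecar (JSON)

def write_ground_truth(scenarios: Sequence[PatientScenario], path: str | Path) -> None:
    doc = {
        "seed": scenarios[0].seed if scenarios else None,
        "patients": [
            {
                "patient_id": sc.profile.patient_id,
                "start": sc.start.isoformat(timespec="seconds"),
                "end": sc.end.isoformat(timespec="seconds"),
                "episodes": [
                    {
                        "kind": e.kind,
                        "start": e.start.isoformat(timespec="seconds"),
                        "duration_minutes": e.duration.total_seconds() / 60.0,
                        "situation": sit.value,
                    }
                    for e, sit in sc.ground_truth.episodes
                ],
                "missed_care": [
                    {"day": m.day, "category": m.category}
                    for m in sc.ground_truth.missed_care
                ],
                "physiological_count": sc.ground_truth.physiological_count,
                "treatment_count": sc.ground_truth.treatment_count,
            }
            for sc in scenarios
        ],
        "totals": {
            "physiological": sum(sc.ground_truth.physiological_count for sc in scenarios),
            "treatment": sum(sc.ground_truth.treatment_count for sc in scenarios),
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_ground_truth(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text(encoding="utf-8"))
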