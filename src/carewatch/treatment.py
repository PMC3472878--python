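"""Treatment counters, daily resets, and the patient-facing reminder schedule.

Care events (a performed measurement, medication, hygiene or feeding
procedure) update per-category counters: how many times the procedure was
done today and when it was last done.  Counts reset at local midnight; the
last-care time deliberately survives midnight because the interval rules
compare plain durations that may span days.

The reminder schedule is a list of fixed times of day at which the patient
is prompted (e.g. "08:00 take morning medication").  Reminders are
patient-facing and distinct from the caregiver alerts raised by the
treatment rules; an acknowledged reminder does not create a care event.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, datetime, time, timedelta
from typing import Any, Iterable, Mapping, Sequence

from .core import CATEGORIES, CategoryCounters, TreatmentCounters

__all__ = [
    "CareEvent",
    "ReminderEntry",
    "ReminderSchedule",
    "Reminder",
    "record_care_event",
    "reset_daily",
    "due_reminders",
]


@dataclass(frozen=True)
class CareEvent:
    """A timestamped record that one care procedure was performed."""

    patient_id: str
    t: datetime
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown care category: {self.category!r}")


@dataclass(frozen=True)
class ReminderEntry:
    """One scheduled prompt: time of day, care category, and message text."""

    time_of_day: time
    category: str
    message: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown care category: {self.category!r}")


@dataclass(frozen=True)
class ReminderSchedule:
    """Daily schedule of patient-facing reminders."""

    entries: tuple[ReminderEntry, ...] = ()

    @classmethod
    def from_rows(cls, rows: Iterable[Mapping[str, Any]]) -> "ReminderSchedule":
        """Build from config rows of the form {time: "HH:MM", category, message}."""
        entries = []
        for row in rows:
            tod = row["time"]
            if isinstance(tod, str):
                tod = time.fromisoformat(tod)
            entries.append(
                ReminderEntry(
                    time_of_day=tod,
                    category=row["category"],
                    message=row.get("message", ""),
                )
            )
        return cls(tuple(sorted(entries, key=lambda e: (e.time_of_day, e.category))))


@dataclass(frozen=True)
class Reminder:
    """A reminder that came due inside a polling window."""

    t: datetime
    category: str
    message: str


def reset_daily(c: TreatmentCounters, day: date) -> TreatmentCounters:
    """Roll counters forward to ``day``, zeroing counts if the day changed.

    Last-care times are preserved across the roll.  A multi-day jump is a
    single reset (equivalent to resetting day by day, since intermediate
    days see no events).  Rolling backwards is an error.
    """
    if day < c.day:
        raise ValueError(f"cannot roll counters backwards from {c.day} to {day}")
    if day == c.day:
        return c
    return TreatmentCounters(
        day=day,
        categories={
            cat: CategoryCounters(count_today=0, last_time=cc.last_time)
            for cat, cc in c.categories.items()
        },
    )


def record_care_event(c: TreatmentCounters, ev: CareEvent) -> TreatmentCounters:
    """Apply one care event: roll the day if needed, bump count, set last time."""
    cc = c.for_category(ev.category)
    if cc.last_time is not None and ev.t < cc.last_time:
        raise ValueError(
            f"care event at {ev.t} precedes recorded last {ev.category} time {cc.last_time}"
        )
    c = reset_daily(c, ev.t.date())
    new_cat = replace(
        c.for_category(ev.category),
        count_today=c.for_category(ev.category).count_today + 1,
        last_time=ev.t,
    )
    categories = dict(c.categories)
    categories[ev.category] = new_cat
    return TreatmentCounters(day=c.day, categories=categories)


def due_reminders(
    sched: ReminderSchedule, t_prev: datetime, t_now: datetime
) -> list[Reminder]:
    """Reminders whose scheduled time falls in the half-open window (t_prev, t_now].

    The window may span midnight (or several days); each schedule entry is
    returned once per day it occurs in the window, in chronological order.
    """
    if not t_prev < t_now:
        raise ValueError(f"window must advance: {t_prev} !< {t_now}")
    out: list[Reminder] = []
    day = t_prev.date()
    while day <= t_now.date():
        for entry in sched.entries:
            at = datetime.combine(day, entry.time_of_day)
            if t_prev < at <= t_now:
                out.append(Reminder(t=at, category=entry.category, message=entry.message))
        day += timedelta(days=1)
    out.sort(key=lambda r: (r.t, r.category))
    return out
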