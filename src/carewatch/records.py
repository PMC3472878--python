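"""XML record archives and human-readable report rendering.

A patient's monitoring history (sensor samples plus care events) is stored
as a small XML dialect::

    <patientRecord version="1" patient="p1" created="2025-01-06T00:00:00">
      <sample t="2025-01-06T08:00:00">
        <heartRate unit="bpm">72.5</heartRate>
        <bodyTemp unit="C">36.5</bodyTemp>
        <bloodPressure unit="mmHg">118.0</bloodPressure>
        <spo2 unit="pct">97.0</spo2>
        <breathRate unit="perMin">16.0</breathRate>
        <ecg amp="1.0" rrcv="0.05"/>
      </sample>
      <careEvent t="2025-01-06T08:30:00" category="medication"/>
    </patientRecord>

Numeric values are written as Python ``repr`` decimal strings so archives
round-trip at full precision.  The reader is strict: it rejects unknown
schema versions, unknown elements, and out-of-order timestamps rather than
silently coercing anything.

The alert log, by contrast, is JSON lines (see :mod:`carewatch.engine`):
append-only streaming suits an alert sink better than a document format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import IO, Iterable

import pandas as pd
from lxml import etree

from .core import (
    CATEGORIES,
    VITAL_FIELDS,
    AlertPhase,
    EcgFeature,
    PhysiologicalSample,
    TreatmentPlan,
)
from .engine import AlertLog
from .treatment import CareEvent

__all__ = [
    "SCHEMA_VERSION",
    "ArchiveError",
    "RecordArchive",
    "write_archive",
    "read_archive",
    "render_report",
]

SCHEMA_VERSION = "1"

# field name <-> element tag, attribute order fixed for byte-stable writes
_VITAL_TAGS: tuple[tuple[str, str, str], ...] = (
    ("heart_rate", "heartRate", "bpm"),
    ("body_temp", "bodyTemp", "C"),
    ("blood_pressure", "bloodPressure", "mmHg"),
    ("spo2", "spo2", "pct"),
    ("breath_rate", "breathRate", "perMin"),
)
_TAG_TO_FIELD = {tag: (name, unit) for name, tag, unit in _VITAL_TAGS}


class ArchiveError(ValueError):
    """A record archive violated the dialect or its invariants."""


@dataclass
class RecordArchive:
    """One patient's archived samples and care events, both time-sorted."""

    patient_id: str
    samples: list[PhysiologicalSample] = field(default_factory=list)
    care_events: list[CareEvent] = field(default_factory=list)
    created_at: datetime | None = None
    schema_version: str = SCHEMA_VERSION

    def validate(self) -> None:
        for label, seq in (("sample", self.samples), ("careEvent", self.care_events)):
            bad = [
                i
                for i in range(1, len(seq))
                if seq[i].t < seq[i - 1].t
            ]
            if bad:
                raise ArchiveError(
                    f"{label} timestamps out of order at indices {bad}"
                )
        for seq in (self.samples, self.care_events):
            for item in seq:
                if item.patient_id != self.patient_id:
                    raise ArchiveError(
                        f"archive patient {self.patient_id!r} contains record "
                        f"for {item.patient_id!r}"
                    )


def _fmt(x: float) -> str:
    return repr(float(x))


def write_archive(a: RecordArchive, destination: str | Path | IO[bytes]) -> None:
    """Serialize an archive; byte-stable for identical inputs."""
    a.validate()
    root = etree.Element("patientRecord")
    root.set("version", a.schema_version)
    root.set("patient", a.patient_id)
    if a.created_at is not None:
        root.set("created", a.created_at.isoformat(timespec="seconds"))
    for s in a.samples:
        el = etree.SubElement(root, "sample")
        el.set("t", s.t.isoformat(timespec="seconds"))
        for name, tag, unit in _VITAL_TAGS:
            v = getattr(s, name)
            if v is not None:
                child = etree.SubElement(el, tag)
                child.set("unit", unit)
                child.text = _fmt(v)
        if s.ecg is not None:
            ecg = etree.SubElement(el, "ecg")
            ecg.set("amp", _fmt(s.ecg.peak_amplitude))
            ecg.set("rrcv", _fmt(s.ecg.rr_cv))
    for c in a.care_events:
        el = etree.SubElement(root, "careEvent")
        el.set("t", c.t.isoformat(timespec="seconds"))
        el.set("category", c.category)
    data = etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    if isinstance(destination, (str, Path)):
        Path(destination).write_bytes(data)
    else:
        destination.write(data)


def _parse_time(el: etree._Element, what: str) -> datetime:
    raw = el.get("t")
    if raw is None:
        raise ArchiveError(f"line {el.sourceline}: {what} missing required attribute t")
    try:
        return datetime.fromisoformat(raw)
    except ValueError as exc:
        raise ArchiveError(f"line {el.sourceline}: bad timestamp {raw!r}: {exc}") from exc


def read_archive(source: str | Path | IO[bytes]) -> RecordArchive:
    """Parse an archive, rejecting anything outside the dialect.

    Raises :class:`ArchiveError` with the offending line number for
    malformed XML, unknown schema versions or elements, and out-of-order
    timestamps.
    """
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        raise ArchiveError(f"malformed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "patientRecord":
        raise ArchiveError(f"line {root.sourceline}: expected <patientRecord>, got <{root.tag}>")
    version = root.get("version")
    if version is None:
        raise ArchiveError("patientRecord missing schema version attribute")
    if version != SCHEMA_VERSION:
        raise ArchiveError(f"unknown schema version {version!r} (supported: {SCHEMA_VERSION})")
    patient = root.get("patient")
    if not patient:
        raise ArchiveError("patientRecord missing patient attribute")
    created_raw = root.get("created")
    created_at = datetime.fromisoformat(created_raw) if created_raw else None

    samples: list[PhysiologicalSample] = []
    care_events: list[CareEvent] = []
    for el in root:
        if el.tag is etree.Comment:
            continue
        if el.tag == "sample":
            t = _parse_time(el, "sample")
            fields: dict[str, float] = {}
            ecg: EcgFeature | None = None
            for child in el:
                if child.tag is etree.Comment:
                    continue
                if child.tag == "ecg":
                    try:
                        ecg = EcgFeature(
                            peak_amplitude=float(child.get("amp")),
                            rr_cv=float(child.get("rrcv")),
                        )
                    except (TypeError, ValueError) as exc:
                        raise ArchiveError(
                            f"line {child.sourceline}: bad ecg attributes"
                        ) from exc
                elif child.tag in _TAG_TO_FIELD:
                    name, _unit = _TAG_TO_FIELD[child.tag]
                    try:
                        fields[name] = float(child.text)
                    except (TypeError, ValueError) as exc:
                        raise ArchiveError(
                            f"line {child.sourceline}: non-numeric <{child.tag}> value "
                            f"{child.text!r}"
                        ) from exc
                else:
                    raise ArchiveError(
                        f"line {child.sourceline}: unknown element <{child.tag}> in <sample>"
                    )
            samples.append(PhysiologicalSample(patient_id=patient, t=t, ecg=ecg, **fields))
        elif el.tag == "careEvent":
            t = _parse_time(el, "careEvent")
            category = el.get("category")
            if category not in CATEGORIES:
                raise ArchiveError(
                    f"line {el.sourceline}: unknown care category {category!r}"
                )
            care_events.append(CareEvent(patient_id=patient, t=t, category=category))
        else:
            raise ArchiveError(
                f"line {el.sourceline}: unknown element <{el.tag}> in <patientRecord>"
            )

    archive = RecordArchive(
        patient_id=patient,
        samples=samples,
        care_events=care_events,
        created_at=created_at,
        schema_version=version,
    )
    archive.validate()
    return archive


# ---------------------------------------------------------------------------
# Report rendering

_REPORT_UNITS = {
    "heart_rate": "bpm",
    "body_temp": "degC",
    "blood_pressure": "mmHg",
    "spo2": "%",
    "breath_rate": "/min",
}


def render_report(
    a: RecordArchive,
    log: AlertLog | None = None,
    plan: TreatmentPlan | None = None,
) -> str:
    """Plain-text summary: daily vital statistics, care counts, alert chronology.

    Formatting is deterministic so reports can be diffed between runs.
    """
    lines: list[str] = []
    lines.append(f"Patient record report: {a.patient_id}")
    lines.append(f"Samples: {len(a.samples)}   Care events: {len(a.care_events)}")
    lines.append("")

    lines.append("Daily vital signs (min / mean / max)")
    if a.samples:
        rows = [
            {"day": s.t.date(), **s.present_vitals()}
            for s in a.samples
        ]
        df = pd.DataFrame(rows)
        for day, group in df.groupby("day", sort=True):
            lines.append(f"  {day}")
            for name in VITAL_FIELDS:
                if name in group and group[name].notna().any():
                    col = group[name].dropna()
                    lines.append(
                        f"    {name:<15} {col.min():8.2f} / {col.mean():8.2f} / "
                        f"{col.max():8.2f} {_REPORT_UNITS[name]}"
                    )
    else:
        lines.append("  (no samples)")
    lines.append("")

    lines.append("Care events per day")
    if a.care_events or plan is not None:
        by_day: dict = {}
        for c in a.care_events:
            by_day.setdefault(c.t.date(), {}).setdefault(c.category, 0)
            by_day[c.t.date()][c.category] += 1
        if not by_day:
            lines.append("  (no care events)")
        for day in sorted(by_day):
            parts = []
            for cat in CATEGORIES:
                n = by_day[day].get(cat, 0)
                if plan is not None:
                    parts.append(f"{cat}={n}/{plan.for_category(cat).required_per_day}")
                else:
                    parts.append(f"{cat}={n}")
            lines.append(f"  {day}  " + "  ".join(parts))
    else:
        lines.append("  (no care events)")
    lines.append("")

    lines.append("Alert chronology")
    if log is not None and log.events:
        for ev in log.events:
            lines.append(
                f"  {ev.t.isoformat(timespec='seconds')}  {ev.phase.value:<8} "
                f"{ev.situation.value}"
            )
        raised = sum(1 for ev in log.events if ev.phase is AlertPhase.RAISED)
        cleared = sum(1 for ev in log.events if ev.phase is AlertPhase.CLEARED)
        lines.append(f"  total: {raised} raised, {cleared} cleared")
    else:
        lines.append("  (no alerts)")
    return "\n".join(lines) + "\n"
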