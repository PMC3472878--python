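from __future__ import annotations

from datetime import datetime, timedelta

import pytest

from carewatch.core import (
    CategoryPlan,
    EcgFeature,
    PhysiologicalSample,
    ThresholdConfig,
    TreatmentPlan,
    default_thresholds,
)

NOMINAL = dict(
    heart_rate=72.0,
    body_temp=36.5,
    blood_pressure=120.0,
    spo2=97.0,
    breath_rate=16.0,
)

T0 = datetime(2025, 1, 6, 8, 0, 0)


def make_sample(t: datetime = T0, patient_id: str = "p1", ecg: str | EcgFeature | None = "normal", **overrides):
    """A nominal sample with selected fields overridden (None removes a field)."""
    fields = {**NOMINAL, **overrides}
    if ecg == "normal":
        ecg = EcgFeature(peak_amplitude=1.0, rr_cv=0.05)
    return PhysiologicalSample(patient_id=patient_id, t=t, ecg=ecg, **fields)


@pytest.fixture
def cfg() -> ThresholdConfig:
    return default_thresholds()


def random_scenario(seed: int, horizon_hours: int = 24, sampling_minutes: int = 5):
    """A randomized one-patient scenario for engine-vs-oracle equivalence checks.

    Episodes are placed in disjoint time slots (so same-axis overlap cannot
    occur) with random kinds, durations and magnitudes; each care category
    independently may have one omitted occurrence.  Returns
    (samples, care_events, plan, ground_truth).
    """
    import numpy as np

    from carewatch.core import CATEGORIES
    from carewatch.simulate import (
        EPISODE_KINDS,
        EpisodeSpec,
        MissedCare,
        PatientProfile,
        default_plan,
        generate_care_events,
        generate_stream,
    )

    rng = np.random.default_rng(seed)
    start = datetime(2025, 1, 6)
    end = start + timedelta(hours=horizon_hours)
    profile = PatientProfile(
        patient_id=f"rand-{seed}", sampling_period=timedelta(minutes=sampling_minutes)
    )
    n_ep = int(rng.integers(0, 4))
    slot = (end - start) / 4
    episodes = []
    for j in range(n_ep):
        kind = EPISODE_KINDS[int(rng.integers(0, len(EPISODE_KINDS)))]
        offset = timedelta(minutes=float(rng.uniform(5, 60)))
        episodes.append(
            EpisodeSpec(
                kind=kind,
                start=start + j * slot + offset,
                duration=timedelta(minutes=float(rng.uniform(5, 45))),
                magnitude=None if rng.random() < 0.5 else float(rng.uniform(0.5, 3.0)),
            )
        )
    days = max(1, horizon_hours // 24)
    missed = [
        MissedCare(day=int(rng.integers(0, days)), category=c)
        for c in CATEGORIES
        if rng.random() < 0.4
    ]
    plan = default_plan()
    samples, truth = generate_stream(profile, start, end, episodes, seed=rng.integers(2**31))
    care = generate_care_events(
        plan, days, missed, seed=rng.integers(2**31), patient_id=profile.patient_id,
        start_date=start.date(),
    )
    truth.missed_care = missed
    return samples, care, plan, truth


@pytest.fixture
def small_plan() -> TreatmentPlan:
    """A compact plan for fast engine tests: tight daily requirements."""
    return TreatmentPlan(
        measurement=CategoryPlan(2, timedelta(hours=4)),
        medication=CategoryPlan(3, timedelta(hours=4)),
        hygiene=CategoryPlan(1, timedelta(hours=25)),
        feeding=CategoryPlan(3, timedelta(hours=5)),
    )
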