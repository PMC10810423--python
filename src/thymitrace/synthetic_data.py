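"""Synthetic tracer-kinetics cohorts: dosing schedules, urinary
enrichment curves, spontaneous-void sampling, IRMS measurement noise, and
the CSV log files the ingest layer reads.

The enrichment mechanism is a Bateman superposition — one-compartment
first-order absorption (ka) and elimination (ke) per oral dose::

    E(t) = baseline + Σ_{doses i ≤ t} A · (e^{−ke (t−tᵢ)} − e^{−ka (t−tᵢ)})

the simplest model producing the observed rise–peak–decay sawtooth with a
closed-form single-dose peak time ``t_max = ln(ka/ke)/(ka − ke)`` that
parameter-recovery tests can target.  Voids follow a gamma renewal
process (shape 2) truncated at 15 minutes — positive, overdispersed
intervals consistent with infants voiding up to about once per hour —
and only a fraction of voids yields a usable sample (cotton balls dry
out or are missed), calibrated so a patient contributes roughly 19
samples over the five-day labeling window.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from thymitrace.study_ingest import DoseEvent, PatientRecord, VoidSample
from thymitrace.isotope_conversion import convert

__all__ = [
    "TracerKineticsParams",
    "VoidProcessParams",
    "bateman_tmax",
    "enrichment_curve",
    "simulate_patient",
    "simulate_cohort",
    "write_cohort_csvs",
    "write_reference_count_fixture",
]

_STUDY_T0 = datetime(2016, 9, 6, 8, 0)


@dataclass(frozen=True)
class TracerKineticsParams:
    """Ground-truth kinetics of the generator.

    ka, ke
        Absorption and elimination rates, /hr (ka > ke > 0).  Defaults
        put the analytic single-dose peak near 6.3 h post-dose.
    amplitude
        Per-dose scale of atom-percent excess; the default gives a
        fitted peak of roughly 2 % under once-daily dosing.
    baseline
        Natural-abundance atom percent (0.37).
    noise_sd
        IRMS measurement noise, atom %.
    """

    ka: float = 0.30
    ke: float = 0.07
    amplitude: float = 2.5
    baseline: float = 0.37
    n_doses: int = 5
    dose_interval: float = 24.0
    dose_jitter_sd: float = 0.5
    noise_sd: float = 0.1
    ascertainment_lag: float = 0.0

    def __post_init__(self) -> None:
        if not (self.ka > 0 and self.ke > 0):
            raise ValueError("rates must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")


@dataclass(frozen=True)
class VoidProcessParams:
    """Spontaneous-void and collection process.

    Gamma(shape, mean/shape) renewal intervals truncated at
    ``min_interval``; each void is lost (dried or missed cotton ball)
    with probability ``collection_loss_prob``.  The default loss rate of
    0.7 over a mean 2 h void interval yields ≈ 18–19 collected samples
    per patient across the 5-day window, matching typical diaper-based
    collection.
    """

    mean_interval: float = 2.0
    shape: float = 2.0
    min_interval: float = 0.25
    collection_loss_prob: float = 0.7
    volume_range: tuple[float, float] = (0.5, 1.5)
    dried_mass_range: tuple[float, float] = (0.10, 6.03)

    def __post_init__(self) -> None:
        if self.mean_interval <= 0:
            raise ValueError("mean_interval must be positive")
        if not (0.0 <= self.collection_loss_prob < 1.0):
            raise ValueError("loss probability must be in [0, 1)")


def bateman_tmax(params: TracerKineticsParams) -> float:
    """Closed-form single-dose time of maximum: ln(ka/ke)/(ka − ke)."""
    if params.ka == params.ke:
        return 1.0 / params.ke
    return math.log(params.ka / params.ke) / (params.ka - params.ke)


def enrichment_curve(
    t: float | np.ndarray,
    params: TracerKineticsParams,
    dose_times: Sequence[float] | None = None,
) -> np.ndarray:
    """Urinary atom-percent enrichment at hours ``t`` since the first dose.

    Doses default to ``0, interval, 2·interval, …``.  Equal rates fall
    back to the confluent limit ``A · ke · Δt · e^{−ke Δt}``.
    """
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(tt < 0):
        raise ValueError("t must be non-negative")
    if dose_times is None:
        dose_times = [i * params.dose_interval for i in range(params.n_doses)]
    out = np.full_like(tt, params.baseline)
    for d in dose_times:
        dt = tt - d - params.ascertainment_lag
        m = dt >= 0
        if params.ka == params.ke:
            out[m] += params.amplitude * params.ke * dt[m] * np.exp(-params.ke * dt[m])
        else:
            out[m] += params.amplitude * (
                np.exp(-params.ke * dt[m]) - np.exp(-params.ka * dt[m])
            )
    return out


@dataclass
class PatientTruth:
    """Generator ground truth kept alongside each simulated patient."""

    patient_id: str
    ka: float
    ke: float
    amplitude: float
    baseline: float
    noise_sd: float
    t_max: float
    dose_times_h: list[float]
    n_voids: int
    n_collected: int


def simulate_patient(
    kinetics: TracerKineticsParams,
    voids: VoidProcessParams,
    seed: int | np.random.Generator,
    patient_id: str = "SIM001",
    group: str = "ToF",
    setting: str = "home",
    age_days: float = 90.0,
    weight_kg: float = 4.5,
    start: datetime = _STUDY_T0,
) -> tuple[PatientRecord, PatientTruth]:
    """Simulate one patient's dosing, voiding, and IRMS measurements.

    Dose times get Gaussian jitter around the once-daily schedule; voids
    run from the first dose to 24 h after the last; each collected sample
    carries curve value + Gaussian IRMS noise.  The same seed reproduces
    the identical record.
    """
    rng = np.random.default_rng(seed)
    jitter = rng.normal(0.0, kinetics.dose_jitter_sd, kinetics.n_doses)
    dose_h = np.sort(
        np.maximum(np.arange(kinetics.n_doses) * kinetics.dose_interval + jitter, 0.0)
    )
    dose_h[0] = 0.0  # clock starts at the first administration
    t_end = dose_h[-1] + 24.0

    void_times: list[float] = []
    t = 0.0
    while True:
        t += max(rng.gamma(voids.shape, voids.mean_interval / voids.shape),
                 voids.min_interval)
        if t >= t_end:
            break
        void_times.append(t)
    n_voids = len(void_times)

    collected = [h for h in void_times if rng.random() >= voids.collection_loss_prob]
    values = enrichment_curve(np.array(collected), kinetics, dose_times=list(dose_h))
    noise = rng.normal(0.0, kinetics.noise_sd, len(collected))
    atom_pct = np.maximum(values + noise, 0.02)

    doses = [
        DoseEvent(
            patient_id=patient_id,
            timestamp=_round_minute(start + timedelta(hours=float(h))),
            dose_mg_per_kg=50.0,
            sequence_index=i + 1,
        )
        for i, h in enumerate(dose_h)
    ]
    samples = []
    for j, (h, ap) in enumerate(zip(collected, atom_pct), start=1):
        samples.append(
            VoidSample(
                patient_id=patient_id,
                sample_id=f"{patient_id}-{j:03d}",
                collection_time=_round_minute(start + timedelta(hours=float(h))),
                time_source="bag",
                time_resolution="minute",
                volume_ml=float(rng.uniform(*voids.volume_range)),
                dried_mass_mg=float(rng.uniform(*voids.dried_mass_range)),
                enrichment=convert(atom_percent=float(ap)),
            )
        )
    record = PatientRecord(
        patient_id=patient_id,
        group=group,  # type: ignore[arg-type]
        age_days=age_days,
        weight_kg=weight_kg,
        setting=setting,  # type: ignore[arg-type]
        doses=doses,
        samples=samples,
    )
    truth = PatientTruth(
        patient_id=patient_id,
        ka=kinetics.ka,
        ke=kinetics.ke,
        amplitude=kinetics.amplitude,
        baseline=kinetics.baseline,
        noise_sd=kinetics.noise_sd,
        t_max=bateman_tmax(kinetics),
        dose_times_h=[float(h) for h in dose_h],
        n_voids=n_voids,
        n_collected=len(collected),
    )
    return record, truth


def _round_minute(dt: datetime) -> datetime:
    return dt.replace(second=0, microsecond=0)


@dataclass
class CohortSpec:
    """Group-level configuration of a simulated cohort."""

    n_tof: int = 5
    n_hf: int = 5
    tof_kinetics: TracerKineticsParams = field(default_factory=TracerKineticsParams)
    hf_kinetics: TracerKineticsParams = field(default_factory=TracerKineticsParams)
    voids: VoidProcessParams = field(default_factory=VoidProcessParams)


def simulate_cohort(
    n_tof: int = 5,
    n_hf: int = 5,
    seed: int = 0,
    tof_kinetics: TracerKineticsParams | None = None,
    hf_kinetics: TracerKineticsParams | None = None,
    voids: VoidProcessParams | None = None,
) -> tuple[list[PatientRecord], list[PatientTruth]]:
    """Simulate a two-group cohort in memory.

    ToF patients label at home with group-typical ages/weights; HF
    patients label in hospital.  Group kinetics may differ (e.g. an
    amplitude offset) via the per-group parameter objects.
    """
    if n_tof < 1 or n_hf < 1:
        raise ValueError("need at least one patient per group")
    tof_kinetics = tof_kinetics or TracerKineticsParams()
    hf_kinetics = hf_kinetics or TracerKineticsParams()
    voids = voids or VoidProcessParams()
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    truths: list[PatientTruth] = []
    for i in range(n_tof):
        rec, tr = simulate_patient(
            tof_kinetics,
            voids,
            rng,
            patient_id=f"T{i + 1:03d}",
            group="ToF",
            setting="home",
            age_days=float(np.clip(rng.normal(70, 45), 14, 365)),
            weight_kg=float(np.clip(rng.normal(4.4, 0.8), 2.0, 8.0)),
        )
        records.append(rec)
        truths.append(tr)
    for i in range(n_hf):
        rec, tr = simulate_patient(
            hf_kinetics,
            voids,
            rng,
            patient_id=f"H{i + 1:03d}",
            group="HF",
            setting="hospital",
            age_days=float(np.clip(rng.normal(121, 50), 14, 365)),
            weight_kg=float(np.clip(rng.normal(5.4, 1.0), 2.0, 9.0)),
        )
        records.append(rec)
        truths.append(tr)
    return records, truths


def write_cohort_csvs(
    records: Sequence[PatientRecord],
    truths: Sequence[PatientTruth] | None,
    outdir: str | Path,
    seed: int | None = None,
    control_batches: bool = True,
) -> dict[str, Path]:
    """Write a cohort as the CSV dialects the ingest layer reads.

    Produces ``dose_log.csv``, ``void_log.csv``, ``irms.csv`` (with
    glycine/peptone control rows when requested), ``metadata.csv`` and a
    ``manifest.json`` of ground-truth parameters for recovery tests.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed if seed is not None else 0)

    dose_rows, void_rows, irms_rows, meta_rows = [], [], [], []
    for rec in records:
        meta_rows.append(
            dict(
                patient_id=rec.patient_id, group=rec.group,
                diagnosis=rec.diagnosis or rec.group,
                age_days=rec.age_days, weight_kg=rec.weight_kg,
                setting=rec.setting,
            )
        )
        for d in rec.doses:
            dose_rows.append(
                dict(
                    patient_id=rec.patient_id,
                    date=d.timestamp.strftime("%Y-%m-%d"),
                    time=d.timestamp.strftime("%H:%M"),
                    dose_mg_per_kg=d.dose_mg_per_kg,
                    notes="",
                )
            )
        for s in rec.samples:
            void_rows.append(
                dict(
                    patient_id=rec.patient_id,
                    sample_id=s.sample_id,
                    bag_date=s.collection_time.strftime("%Y-%m-%d"),
                    bag_time=s.collection_time.strftime("%H:%M"),
                    log_date=s.collection_time.strftime("%Y-%m-%d"),
                    log_hour=s.collection_time.hour,
                    volume_ml="" if s.volume_ml is None else round(s.volume_ml, 2),
                )
            )
            irms_rows.append(
                dict(
                    sample_id=s.sample_id,
                    batch_id="B1",
                    material="sample",
                    dried_mass_mg="" if s.dried_mass_mg is None
                    else round(s.dried_mass_mg, 3),
                    delta15N_permil="",
                    atom_percent=round(s.enrichment.atom_percent, 6)
                    if s.enrichment is not None
                    else "",
                    run_order=len(irms_rows) + 1,
                )
            )
    if control_batches:
        for material, n_runs in (("glycine", 10), ("peptone", 6)):
            for _ in range(n_runs):
                irms_rows.append(
                    dict(
                        sample_id=f"CTRL-{material}-{len(irms_rows)}",
                        batch_id="B1",
                        material=material,
                        dried_mass_mg=round(float(rng.uniform(1.0, 4.0)), 3),
                        delta15N_permil="",
                        atom_percent=round(0.371 + float(rng.normal(0, 0.001)), 6),
                        run_order=len(irms_rows) + 1,
                    )
                )

    paths = {
        "dose_log": outdir / "dose_log.csv",
        "void_log": outdir / "void_log.csv",
        "irms": outdir / "irms.csv",
        "metadata": outdir / "metadata.csv",
        "manifest": outdir / "manifest.json",
    }
    pd.DataFrame(dose_rows).to_csv(paths["dose_log"], index=False)
    pd.DataFrame(
        void_rows,
        columns=["patient_id", "sample_id", "bag_date", "bag_time",
                 "log_date", "log_hour", "volume_ml"],
    ).to_csv(paths["void_log"], index=False)
    pd.DataFrame(irms_rows).to_csv(paths["irms"], index=False)
    pd.DataFrame(meta_rows).to_csv(paths["metadata"], index=False)

    manifest = {
        "seed": seed,
        "n_patients": len(records),
        "n_samples": int(sum(len(r.samples) for r in records)),
        "patients": [asdict(t) for t in truths] if truths is not None else [],
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths


def write_reference_count_fixture(outdir: str | Path) -> dict[str, Path]:
    """Write a deterministic cohort whose per-patient sample counts match
    the reference study tables (262 samples across 18 recruited patients).

    Patients recorded in the study as lacking usable administration times
    get no dose-log rows, so the inclusion stage reproduces the study's
    analyzable subset; everyone else doses daily at 09:00 with voids
    spread evenly over the five-day window.  Enrichment values are the
    noiseless generator curve, so the fixture is fully deterministic.
    """
    from thymitrace.reference import REFERENCE_PATIENTS

    no_dose_times = {"M002", "M007", "M011"}  # returned samples but not times
    params = TracerKineticsParams()
    records: list[PatientRecord] = []
    for p in REFERENCE_PATIENTS:
        start = _STUDY_T0.replace(hour=9, minute=0)
        doses = []
        if p["patient_id"] not in no_dose_times:
            doses = [
                DoseEvent(
                    patient_id=p["patient_id"],
                    timestamp=start + timedelta(hours=24.0 * i),
                    sequence_index=i + 1,
                )
                for i in range(5)
            ]
        n = int(p["n_samples"])
        samples = []
        if n > 0:
            hours = np.linspace(0.5, 24.0 * 4 + 23.5, n)
            values = enrichment_curve(hours, params)
            for j, (h, ap) in enumerate(zip(hours, values), start=1):
                samples.append(
                    VoidSample(
                        patient_id=p["patient_id"],
                        sample_id=f"{p['patient_id']}-{j:03d}",
                        collection_time=_round_minute(
                            start + timedelta(hours=float(h))
                        ),
                        volume_ml=1.1,
                        dried_mass_mg=2.0,
                        enrichment=convert(atom_percent=float(ap)),
                    )
                )
        records.append(
            PatientRecord(
                patient_id=p["patient_id"],
                group=p["group"],
                age_days=float(p["age_days"]),
                weight_kg=float(p["weight_kg"]),
                setting=p["setting"],
                diagnosis=p["diagnosis"],
                doses=doses,
                samples=samples,
            )
        )
    return write_cohort_csvs(records, None, outdir, seed=0, control_batches=False)
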