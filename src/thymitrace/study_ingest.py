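"""Ingest of dose logs, void logs, IRMS batch results, and cohort
metadata; timestamp reconciliation; inclusion rules; and normalization of
collection times to hours since the most recent preceding dose.

File dialects (CSV, UTF-8, header row required)
-----------------------------------------------
dose log
    ``patient_id, date (YYYY-MM-DD), time (HH:MM), dose_mg_per_kg, notes``
void log
    ``patient_id, sample_id, bag_date, bag_time, log_date, log_hour,
    volume_ml`` — bag entries carry minute resolution, paper-log entries
    are approximated to the hour by caregivers.
IRMS batch
    ``sample_id, batch_id, material (sample|glycine|peptone|standard),
    dried_mass_mg, delta15N_permil, atom_percent, run_order`` with exactly
    one of the two value columns populated per row.
metadata
    ``patient_id, group (ToF|HF), diagnosis, age_days, weight_kg,
    setting (home|hospital)``
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from thymitrace.isotope_conversion import IsotopeValue, convert

__all__ = [
    "CohortConfig",
    "DoseEvent",
    "ExclusionRecord",
    "GapMarker",
    "NormalizedSample",
    "NormalizationDetail",
    "PatientRecord",
    "VoidSample",
    "apply_inclusion",
    "exclusions_to_frame",
    "flag_gaps",
    "normalize_times",
    "parse_logs",
]


@dataclass
class CohortConfig:
    """Analysis-wide knobs.

    baseline_atom_percent
        Natural-abundance ¹⁵N baseline in urine, atom % (0.37 by default).
    window_hours
        Samples later than this after the most recent dose are excluded
        from fitting (collection stopped 24 h after the last dose).
    min_samples_for_fit
        Minimum number of normalized samples for a patient to enter
        polynomial fitting.
    gap_break_hours
        Consecutive collections further apart than this break the plotted
        trend line.
    ci_level
        Confidence level of the fitted band.
    degree
        Polynomial degree used for patient summaries.
    band_method
        ``"t"`` for a t-quantile pointwise band, ``"2se"`` for a fixed
        ±2·SE band.
    """

    baseline_atom_percent: float = 0.37
    window_hours: float = 24.0
    min_samples_for_fit: int = 9
    gap_break_hours: float = 24.0
    ci_level: float = 0.95
    degree: int = 3
    plateau_epsilon: float = 0.01
    band_method: Literal["t", "2se"] = "t"

    def __post_init__(self) -> None:
        if self.baseline_atom_percent <= 0:
            raise ValueError("baseline must be positive")
        if self.window_hours <= 0:
            raise ValueError("window_hours must be positive")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class DoseEvent:
    patient_id: str
    timestamp: datetime
    dose_mg_per_kg: float = 50.0
    sequence_index: int = 1


@dataclass
class VoidSample:
    patient_id: str
    sample_id: str
    collection_time: datetime
    time_source: Literal["bag", "log", "reconciled"] = "bag"
    time_resolution: Literal["minute", "hour"] = "minute"
    volume_ml: float | None = None
    dried_mass_mg: float | None = None
    enrichment: IsotopeValue | None = None


@dataclass
class PatientRecord:
    patient_id: str
    group: Literal["ToF", "HF"]
    age_days: float
    weight_kg: float
    setting: Literal["home", "hospital", "unknown"]
    doses: list[DoseEvent] = field(default_factory=list)
    samples: list[VoidSample] = field(default_factory=list)
    diagnosis: str = ""

    def __post_init__(self) -> None:
        self.samples.sort(key=lambda s: s.collection_time)
        self.doses.sort(key=lambda d: d.timestamp)


@dataclass(frozen=True)
class NormalizedSample:
    patient_id: str
    dose_index: int
    time_since_dose: float
    atom_percent: float


@dataclass(frozen=True)
class ExclusionRecord:
    patient_id: str
    sample_id: str | None
    reason_code: str
    detail: str = ""


class GapMarker(NamedTuple):
    """A break between consecutive collections more than the gap limit apart."""

    index_before: int
    spacing_hours: float


def exclusions_to_frame(exclusions: Iterable[ExclusionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "sample_id": e.sample_id,
                "reason_code": e.reason_code,
                "detail": e.detail,
            }
            for e in exclusions
        ],
        columns=["patient_id", "sample_id", "reason_code", "detail"],
    )


def _combine(date_str: str, time_str: str) -> datetime:
    return datetime.strptime(f"{date_str.strip()} {time_str.strip()}", "%Y-%m-%d %H:%M")


def _reconcile_void_time(row: pd.Series) -> tuple[datetime, str, str] | None:
    """Pick the collection time from bag vs paper-log entries.

    Bag entries carry minutes, paper logs only the hour; when both exist
    and disagree the minute-resolution bag time wins and the sample is
    marked ``reconciled``.  Returns None when no usable time exists.
    """
    bag = None
    if _present(row.get("bag_date")) and _present(row.get("bag_time")):
        bag = _combine(str(row["bag_date"]), str(row["bag_time"]))
    log = None
    if _present(row.get("log_date")) and _present(row.get("log_hour")):
        hour = int(float(row["log_hour"]))
        log = datetime.strptime(str(row["log_date"]).strip(), "%Y-%m-%d") + timedelta(
            hours=hour
        )
    if bag is not None and log is not None:
        if bag != log:
            return bag, "reconciled", "minute"
        return bag, "bag", "minute"
    if bag is not None:
        return bag, "bag", "minute"
    if log is not None:
        # hour-resolution entries are read as the top of the hour
        return log, "log", "hour"
    return None


def _present(value: object) -> bool:
    if value is None:
        return False
    if isinstance(value, float) and math.isnan(value):
        return False
    return str(value).strip() not in ("", "nan", "NaN")


def parse_logs(
    dose_csv: str | Path,
    void_csv: str | Path,
    irms_csv: str | Path,
    metadata_csv: str | Path,
) -> tuple[list[PatientRecord], list[ExclusionRecord]]:
    """Parse the four study files into patient records.

    Each void is joined to at most one IRMS sample row by ``sample_id``;
    duplicate sample ids in the IRMS file and samples referencing unknown
    patients are hard errors.  Voids timestamped before the patient's
    study start (midnight of the first dose day) are dropped and logged.
    """
    meta = pd.read_csv(metadata_csv, dtype=str)
    doses_df = pd.read_csv(dose_csv, dtype=str)
    voids_df = pd.read_csv(void_csv, dtype=str)
    irms_df = pd.read_csv(irms_csv, dtype=str)

    sample_rows = irms_df[irms_df["material"].str.strip() == "sample"].copy()
    dup = sample_rows["sample_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate sample_id in IRMS file: {sorted(sample_rows['sample_id'][dup])}"
        )
    irms_by_id: dict[str, tuple[IsotopeValue, float | None]] = {}
    for _, row in sample_rows.iterrows():
        has_delta = _present(row.get("delta15N_permil"))
        has_ap = _present(row.get("atom_percent"))
        if has_delta == has_ap:
            raise ValueError(
                f"IRMS row {row['sample_id']}: exactly one of delta15N_permil "
                "and atom_percent must be populated"
            )
        if has_delta:
            iv = convert(delta_air=float(row["delta15N_permil"]))
        else:
            iv = convert(atom_percent=float(row["atom_percent"]))
        mass = float(row["dried_mass_mg"]) if _present(row.get("dried_mass_mg")) else None
        irms_by_id[str(row["sample_id"]).strip()] = (iv, mass)

    known_patients = set(meta["patient_id"].str.strip())
    bad = set(voids_df["patient_id"].str.strip()) - known_patients
    if bad:
        raise ValueError(f"void log references unknown patients: {sorted(bad)}")

    doses_by_patient: dict[str, list[DoseEvent]] = {}
    for pid, grp in doses_df.groupby(doses_df["patient_id"].str.strip()):
        events = [
            DoseEvent(
                patient_id=pid,
                timestamp=_combine(str(r["date"]), str(r["time"])),
                dose_mg_per_kg=float(r["dose_mg_per_kg"])
                if _present(r.get("dose_mg_per_kg"))
                else 50.0,
            )
            for _, r in grp.iterrows()
        ]
        events.sort(key=lambda e: e.timestamp)
        for i, e in enumerate(events, start=1):
            e.sequence_index = i
        doses_by_patient[pid] = events

    exclusions: list[ExclusionRecord] = []
    samples_by_patient: dict[str, list[VoidSample]] = {}
    for _, row in voids_df.iterrows():
        pid = str(row["patient_id"]).strip()
        sid = str(row["sample_id"]).strip()
        picked = _reconcile_void_time(row)
        if picked is None:
            exclusions.append(
                ExclusionRecord(pid, sid, "missing_collection_time", "no usable time")
            )
            continue
        when, source, resolution = picked
        doses = doses_by_patient.get(pid)
        if doses:
            study_start = doses[0].timestamp.replace(hour=0, minute=0)
            if when < study_start:
                exclusions.append(
                    ExclusionRecord(
                        pid,
                        sid,
                        "before_study_start",
                        f"collection {when.isoformat()} precedes study start "
                        f"{study_start.isoformat()}",
                    )
                )
                continue
        iv, mass = irms_by_id.get(sid, (None, None))
        samples_by_patient.setdefault(pid, []).append(
            VoidSample(
                patient_id=pid,
                sample_id=sid,
                collection_time=when,
                time_source=source,
                time_resolution=resolution,
                volume_ml=float(row["volume_ml"]) if _present(row.get("volume_ml")) else None,
                dried_mass_mg=mass,
                enrichment=iv,
            )
        )

    records = []
    for _, m in meta.iterrows():
        pid = str(m["patient_id"]).strip()
        records.append(
            PatientRecord(
                patient_id=pid,
                group=str(m["group"]).strip(),  # type: ignore[arg-type]
                age_days=float(m["age_days"]),
                weight_kg=float(m["weight_kg"]),
                setting=str(m["setting"]).strip(),  # type: ignore[arg-type]
                diagnosis=str(m.get("diagnosis", "") or ""),
                doses=doses_by_patient.get(pid, []),
                samples=samples_by_patient.get(pid, []),
            )
        )
    return records, exclusions


@dataclass
class NormalizationDetail:
    """Dose-relative samples plus what fell outside the overlay."""

    samples: list[NormalizedSample]
    baseline_pool: list[VoidSample]
    dropped: list[ExclusionRecord]


def normalize_times(
    record: PatientRecord,
    config: CohortConfig | None = None,
    *,
    details: bool = False,
) -> list[NormalizedSample] | NormalizationDetail:
    """Re-index samples to hours elapsed since the most recent dose.

    Each sample with an enrichment value is assigned to the latest dose
    whose time is ≤ the collection time (a sample exactly at a dose time
    belongs to that dose, at time 0).  Samples before the first dose go
    to the baseline pool; samples more than ``window_hours`` after their
    dose are dropped with a logged reason.
    """
    config = config or CohortConfig()
    if not record.doses:
        raise ValueError(f"patient {record.patient_id} has no recorded doses")
    dose_times = [d.timestamp for d in record.doses]
    out: list[NormalizedSample] = []
    baseline: list[VoidSample] = []
    dropped: list[ExclusionRecord] = []
    for s in record.samples:
        if s.enrichment is None:
            dropped.append(
                ExclusionRecord(
                    record.patient_id, s.sample_id, "no_irms_result", ""
                )
            )
            continue
        if s.collection_time < dose_times[0]:
            baseline.append(s)
            continue
        idx = int(np.searchsorted(
            np.array(dose_times, dtype="datetime64[s]"),
            np.datetime64(s.collection_time, "s"),
            side="right",
        )) - 1
        dt_hours = (s.collection_time - dose_times[idx]).total_seconds() / 3600.0
        if dt_hours > config.window_hours:
            dropped.append(
                ExclusionRecord(
                    record.patient_id,
                    s.sample_id,
                    "outside_window",
                    f"{dt_hours:.2f} h after dose {idx + 1}",
                )
            )
            continue
        out.append(
            NormalizedSample(
                patient_id=record.patient_id,
                dose_index=idx + 1,
                time_since_dose=dt_hours,
                atom_percent=s.enrichment.atom_percent,
            )
        )
    if details:
        return NormalizationDetail(out, baseline, dropped)
    return out


class InclusionResult(NamedTuple):
    analyzable: list[PatientRecord]
    fit_eligible: list[PatientRecord]
    exclusions: list[ExclusionRecord]


def apply_inclusion(
    cohort: Sequence[PatientRecord], config: CohortConfig | None = None
) -> InclusionResult:
    """Split a cohort into analyzable and fit-eligible subsets.

    Analyzable patients have recorded dose times and at least one timed
    sample; fit-eligible patients additionally have at least
    ``min_samples_for_fit`` in-window normalized samples.  Every
    exclusion carries a machine-readable reason code.
    """
    config = config or CohortConfig()
    analyzable: list[PatientRecord] = []
    fit_eligible: list[PatientRecord] = []
    exclusions: list[ExclusionRecord] = []
    for rec in cohort:
        if not rec.doses:
            exclusions.append(
                ExclusionRecord(
                    rec.patient_id, None, "missing_times",
                    "no recorded administration times",
                )
            )
            continue
        if not rec.samples:
            exclusions.append(
                ExclusionRecord(rec.patient_id, None, "no_samples", "no timed samples")
            )
            continue
        analyzable.append(rec)
        normalized = normalize_times(rec, config)
        assert isinstance(normalized, list)
        if len(normalized) >= config.min_samples_for_fit:
            fit_eligible.append(rec)
        else:
            exclusions.append(
                ExclusionRecord(
                    rec.patient_id,
                    None,
                    "insufficient_samples_for_fit",
                    f"{len(normalized)} normalized samples "
                    f"< {config.min_samples_for_fit}",
                )
            )
    return InclusionResult(analyzable, fit_eligible, exclusions)


def flag_gaps(
    times_hours: Sequence[float],
    config: CohortConfig | None = None,
) -> list[GapMarker]:
    """Mark consecutive collections spaced more than the gap limit apart.

    ``times_hours`` must be sorted; markers are used only to break trend
    lines in plots and report segmentation.
    """
    config = config or CohortConfig()
    t = np.asarray(times_hours, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted")
    markers = []
    for i, gap in enumerate(np.diff(t)):
        if gap > config.gap_break_hours:
            markers.append(GapMarker(index_before=i, spacing_hours=float(gap)))
    return markers
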