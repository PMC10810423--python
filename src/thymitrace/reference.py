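"""Published cohort characteristics and group summary statistics for the
infant oral ¹⁵N-thymidine elimination study that this package analyzes.

These constants are desk-check inputs: per-patient demographics and urine
sample counts for the recruited tetralogy-of-Fallot (ToF) and
heart-failure (HF) infants, and the printed group summaries (mean ± SEM,
n) of the kinetic read-outs.  They let the statistical layer be
recomputed without access to any raw patient data.
"""

from __future__ import annotations

import pandas as pd

from thymitrace.group_stats import GroupSummary

__all__ = [
    "GROUP_SUMMARIES",
    "IN_HOSPITAL_TABLE",
    "NATURAL_BASELINE_PERCENT",
    "REFERENCE_PATIENTS",
    "reference_cohort_frame",
    "reference_summary_frame",
]

#: Natural-abundance ¹⁵N/¹⁴N baseline in unlabeled urine, percent.
NATURAL_BASELINE_PERCENT = 0.37

#: Recruited patients: id, sex, group, diagnosis, age at label
#: administration (days), body weight (kg), number of urine samples
#: collected, administration setting, and whether the patient met the
#: criteria for the systematic analysis.  Ages printed as months+days are
#: converted at 30 days/month.
REFERENCE_PATIENTS: list[dict] = [
    # ToF group
    dict(patient_id="M002", sex="F", group="ToF", diagnosis="ToF", age_days=23,
         weight_kg=3.030, n_samples=22, setting="home", included=False),
    dict(patient_id="M001", sex="M", group="ToF", diagnosis="ToF", age_days=24,
         weight_kg=4.120, n_samples=32, setting="home", included=True),
    dict(patient_id="M018", sex="M", group="ToF", diagnosis="ToF", age_days=26,
         weight_kg=3.520, n_samples=32, setting="home", included=True),
    dict(patient_id="M003", sex="M", group="ToF", diagnosis="ToF", age_days=31,
         weight_kg=3.800, n_samples=0, setting="home", included=False),
    dict(patient_id="M006", sex="M", group="ToF", diagnosis="ToF/DORV", age_days=44,
         weight_kg=2.580, n_samples=0, setting="hospital", included=False),
    dict(patient_id="M010", sex="M", group="ToF", diagnosis="ToF", age_days=55,
         weight_kg=5.220, n_samples=6, setting="home", included=True),
    dict(patient_id="M014", sex="M", group="ToF", diagnosis="ToF", age_days=66,
         weight_kg=2.200, n_samples=8, setting="hospital", included=True),
    dict(patient_id="M004", sex="F", group="ToF", diagnosis="ToF", age_days=73,
         weight_kg=3.090, n_samples=0, setting="hospital", included=False),
    dict(patient_id="M007", sex="M", group="ToF", diagnosis="ToF", age_days=87,
         weight_kg=3.350, n_samples=9, setting="home", included=False),
    dict(patient_id="M011", sex="M", group="ToF", diagnosis="ToF", age_days=92,
         weight_kg=5.050, n_samples=25, setting="unknown", included=False),
    dict(patient_id="M013", sex="M", group="ToF", diagnosis="ToF", age_days=93,
         weight_kg=4.450, n_samples=13, setting="home", included=True),
    dict(patient_id="M005", sex="F", group="ToF", diagnosis="ToF", age_days=126,
         weight_kg=5.200, n_samples=0, setting="hospital", included=False),
    dict(patient_id="M012", sex="F", group="ToF", diagnosis="ToF", age_days=151,
         weight_kg=4.900, n_samples=21, setting="home", included=True),
    # HF group (dilated cardiomyopathy / hypoplastic left heart syndrome)
    dict(patient_id="M019", sex="M", group="HF", diagnosis="HLHS", age_days=62,
         weight_kg=3.490, n_samples=18, setting="hospital", included=True),
    dict(patient_id="M016", sex="F", group="HF", diagnosis="DCM", age_days=76,
         weight_kg=5.500, n_samples=18, setting="hospital", included=True),
    dict(patient_id="M009", sex="M", group="HF", diagnosis="DCM", age_days=116,
         weight_kg=6.170, n_samples=19, setting="hospital", included=True),
    dict(patient_id="M017", sex="M", group="HF", diagnosis="DCM", age_days=141,
         weight_kg=5.600, n_samples=18, setting="hospital", included=True),
    dict(patient_id="M008", sex="F", group="HF", diagnosis="DCM", age_days=211,
         weight_kg=6.360, n_samples=21, setting="hospital", included=True),
]

#: Printed group summaries (mean, SEM, n) of the study read-outs.
GROUP_SUMMARIES: dict[str, tuple[GroupSummary, GroupSummary]] = {
    "mean_enrichment": (
        GroupSummary("ToF", 6, 1.193, 0.092),
        GroupSummary("HF", 5, 1.590, 0.185),
    ),
    "peak_enrichment": (
        GroupSummary("ToF", 5, 2.194, 0.299),
        GroupSummary("HF", 5, 2.459, 0.361),
    ),
    "time_to_peak": (
        GroupSummary("ToF", 5, 6.302, 1.017),
        GroupSummary("HF", 5, 7.475, 1.976),
    ),
    "labeling_period": (
        GroupSummary("ToF", 5, 18.540, 1.686),
        GroupSummary("HF", 5, 18.190, 1.751),
    ),
    "age_days": (
        GroupSummary("ToF", 5, 70.0, 24.0),
        GroupSummary("HF", 5, 121.0, 26.0),
    ),
    "weight_kg": (
        GroupSummary("ToF", 5, 4.442, 0.297),
        GroupSummary("HF", 5, 5.424, 0.510),
    ),
}

#: In-hospital administration counts (ToF 1/5 vs HF 5/5) as a 2×2 table
#: (a, b, c, d) = (ToF hospital, ToF home, HF hospital, HF home).
IN_HOSPITAL_TABLE: tuple[int, int, int, int] = (1, 4, 5, 0)

_MEASURE_LABELS = {
    "mean_enrichment": "Mean 15N/14N atomic ratio (%)",
    "peak_enrichment": "Peak 15N/14N atomic ratio (%)",
    "time_to_peak": "Time to peak (hours)",
    "labeling_period": "Labeling period (hours)",
    "age_days": "Mean age at administration (days)",
    "weight_kg": "Mean weight at administration (kg)",
}


def reference_cohort_frame() -> pd.DataFrame:
    """Per-patient reference cohort table as a DataFrame."""
    return pd.DataFrame(REFERENCE_PATIENTS)


def reference_summary_frame() -> pd.DataFrame:
    """Summary-statistics table in the layout ``comparison_from_summaries``
    consumes: Welch rows from the printed mean ± SEM summaries plus the
    in-hospital Fisher row."""
    rows = []
    a, b, c, d = IN_HOSPITAL_TABLE
    rows.append(
        dict(measure="Administration in hospital", test="fisher",
             a=a, b=b, c=c, d=d)
    )
    for key, (g1, g2) in GROUP_SUMMARIES.items():
        rows.append(
            dict(
                measure=_MEASURE_LABELS[key],
                test="welch",
                g1_n=g1.n, g1_mean=g1.mean, g1_sem=g1.sem,
                g2_n=g2.n, g2_mean=g2.mean, g2_sem=g2.sem,
            )
        )
    return pd.DataFrame(rows)
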