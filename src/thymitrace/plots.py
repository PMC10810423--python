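"""Optional figures: per-patient enrichment time courses and pooled
dose-relative overlays with fitted curve, confidence band, baseline line,
and dose arrows.  Figures are never load-bearing for analysis outputs."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from thymitrace.enrichment_kinetics import ConfidenceBand
from thymitrace.study_ingest import (
    CohortConfig,
    NormalizedSample,
    PatientRecord,
    flag_gaps,
)

__all__ = ["plot_patient_timecourse", "plot_dose_overlay"]


def plot_patient_timecourse(
    record: PatientRecord,
    path: str | Path,
    config: CohortConfig | None = None,
) -> Path:
    """Chronological enrichment with dose arrows and gap-broken trend line."""
    config = config or CohortConfig()
    samples = [s for s in record.samples if s.enrichment is not None]
    if not samples:
        raise ValueError(f"patient {record.patient_id} has no measured samples")
    t0 = record.doses[0].timestamp if record.doses else samples[0].collection_time
    hours = np.array(
        [(s.collection_time - t0).total_seconds() / 3600 for s in samples]
    )
    vals = np.array([s.enrichment.atom_percent for s in samples])
    gaps = {g.index_before for g in flag_gaps(hours, config)}

    fig, ax = plt.subplots(figsize=(7, 3.5))
    start = 0
    for i in range(len(hours)):
        if i in gaps:
            ax.plot(hours[start : i + 1], vals[start : i + 1], "k-", lw=1)
            start = i + 1
    ax.plot(hours[start:], vals[start:], "k-", lw=1)
    ax.plot(hours, vals, "ko", ms=3)
    for d in record.doses:
        x = (d.timestamp - t0).total_seconds() / 3600
        ax.annotate(
            "", xy=(x, ax.get_ylim()[1] * 0.95), xytext=(x, ax.get_ylim()[1]),
            arrowprops=dict(arrowstyle="->", color="green"),
        )
        ax.axvline(x, color="green", ls=":", lw=0.6)
    ax.axhline(config.baseline_atom_percent, color="red", ls=":", lw=1)
    ax.set_xlabel("time since first dose (h)")
    ax.set_ylabel("$^{15}$N/$^{14}$N (%)")
    ax.set_title(record.patient_id)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_dose_overlay(
    samples: Sequence[NormalizedSample],
    band: ConfidenceBand,
    path: str | Path,
    baseline: float = 0.37,
    title: str = "",
) -> Path:
    """Dose-relative overlay with fitted curve and confidence band."""
    t = np.array([s.time_since_dose for s in samples])
    y = np.array([s.atom_percent for s in samples])
    dose_idx = np.array([s.dose_index for s in samples])

    fig, ax = plt.subplots(figsize=(5.5, 4))
    for k in np.unique(dose_idx):
        m = dose_idx == k
        ax.plot(t[m], y[m], "o", ms=3, label=f"dose {k}")
    ax.plot(band.grid, band.mean, "b-", lw=1.5)
    ax.plot(band.grid, band.lower, "b--", lw=1)
    ax.plot(band.grid, band.upper, "b--", lw=1)
    ax.axhline(baseline, color="red", ls=":", lw=1)
    ax.set_xlabel("time since dose (h)")
    ax.set_ylabel("$^{15}$N/$^{14}$N (%)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
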