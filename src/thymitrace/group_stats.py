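"""Between-group inference: Welch's unequal-variance t-test (from raw
values or printed mean ± SEM summaries), the two-sided Fisher exact test,
fold changes over the natural-abundance baseline, and the group
comparison report.

Welch's statistic from group summaries (mean mᵢ, standard error sᵢ, nᵢ)::

    t  = (m₁ − m₂) / √(s₁² + s₂²)
    df = (s₁² + s₂²)² / (s₁⁴/(n₁−1) + s₂⁴/(n₂−1))   (Welch–Satterthwaite)

with a two-tailed p from the t distribution.  All p-values are kept at
full precision internally and rounded (3 decimals) only in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from thymitrace.enrichment_kinetics import KineticsSummary
from thymitrace.study_ingest import PatientRecord

__all__ = [
    "ContingencyTable2x2",
    "GroupSummary",
    "WelchResult",
    "build_comparison_table",
    "comparison_from_summaries",
    "fisher_exact_two_sided",
    "fold_change",
    "welch_from_raw",
    "welch_from_summary",
]


@dataclass(frozen=True)
class GroupSummary:
    """One group's printed summary: label, n, mean, SEM."""

    label: str
    n: int
    mean: float
    sem: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sem < 0:
            raise ValueError("SEM must be non-negative")


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    df: float
    p_two_tailed: float
    degenerate: bool = False


def welch_from_summary(g1: GroupSummary, g2: GroupSummary) -> WelchResult:
    """Welch's unpaired t-test from mean ± SEM summaries."""
    if not (math.isfinite(g1.sem) and math.isfinite(g2.sem)):
        raise ValueError("SEMs must be finite")
    v1, v2 = g1.sem**2, g2.sem**2
    if v1 + v2 == 0.0:
        if g1.mean == g2.mean:
            return WelchResult(0.0, float("inf"), 1.0, degenerate=True)
        return WelchResult(math.inf, float("inf"), 0.0, degenerate=True)
    t = (g1.mean - g2.mean) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(t_statistic=t, df=df, p_two_tailed=p)


def welch_from_raw(
    x1: Sequence[float] | np.ndarray, x2: Sequence[float] | np.ndarray
) -> WelchResult:
    """Welch's unpaired t-test from raw per-patient values.

    Identical to :func:`welch_from_summary` applied to
    ``(mean, sd/√n, n)`` of each sample.
    """
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    g1 = _summarize("x1", a)
    g2 = _summarize("x2", b)
    return welch_from_summary(g1, g2)


def _summarize(label: str, x: np.ndarray) -> GroupSummary:
    n = len(x)
    sem = float(np.std(x, ddof=1) / math.sqrt(n))
    return GroupSummary(label=label, n=n, mean=float(np.mean(x)), sem=sem)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2×2 counts; rows are groups, columns are outcome categories."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("group1", "group2")
    col_labels: tuple[str, str] = ("yes", "no")

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in counts) or not all(
            isinstance(x, (int, np.integer)) for x in counts
        ):
            raise ValueError("counts must be non-negative integers")
        if sum(counts) < 1:
            raise ValueError("table must have at least one observation")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact_two_sided(table: ContingencyTable2x2 | np.ndarray) -> float:
    """Two-sided Fisher exact p by the point-probability-sum rule.

    Conditional on fixed margins, sums the hypergeometric mass of every
    table whose point probability does not exceed the observed table's
    (with the customary small numerical slack).  A zero margin means no
    variation, hence p = 1.
    """
    arr = table.as_array() if isinstance(table, ContingencyTable2x2) else np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    row = arr.sum(axis=1)
    col = arr.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def fold_change(mean_enrichment: float, baseline: float) -> float:
    """Fold change of a mean enrichment over baseline, to 1 decimal."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return round(mean_enrichment / baseline, 1)


_KINETIC_ROWS = (
    ("Peak 15N/14N atomic ratio (%)", "peak_value"),
    ("Time to peak (hours)", "time_to_peak"),
    ("Labeling period (hours)", "labeling_period"),
)


def _welch_row(
    measure: str, x1: np.ndarray, x2: np.ndarray
) -> dict[str, object]:
    if len(x1) >= 2 and len(x2) >= 2:
        res = welch_from_raw(x1, x2)
        p: float | None = res.p_two_tailed
    else:
        p = None
    return {
        "measure": measure,
        "group1": _fmt_mean_sem(x1),
        "group2": _fmt_mean_sem(x2),
        "p_value": round(p, 3) if p is not None else None,
        "significant": (p is not None and p < 0.05),
    }


def _fmt_mean_sem(x: np.ndarray) -> str:
    if len(x) == 0:
        return "-"
    if len(x) == 1:
        return f"{x[0]:.3f}"
    sem = np.std(x, ddof=1) / math.sqrt(len(x))
    return f"{np.mean(x):.3f} ± {sem:.3f}"


def build_comparison_table(
    analyzable: Sequence[PatientRecord],
    summaries: Sequence[KineticsSummary],
    group_labels: tuple[str, str] = ("ToF", "HF"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Build the two-group comparison report.

    Demographic rows (n analyzed, in-hospital administration with a
    Fisher exact p, age, weight) come from the analyzable patients;
    kinetic rows (peak, time-to-peak, labeling period) come from the
    fit-eligible patients' kinetics summaries, each compared by Welch's
    t-test.  p-values are rounded to 3 decimals at this reporting layer
    only.
    """
    g1, g2 = group_labels
    rec1 = [r for r in analyzable if r.group == g1]
    rec2 = [r for r in analyzable if r.group == g2]
    if not rec1 or not rec2:
        raise ValueError("both groups must be non-empty")
    by_id = {r.patient_id: r for r in analyzable}
    sum1 = [s for s in summaries if by_id.get(s.patient_id, None) and by_id[s.patient_id].group == g1]
    sum2 = [s for s in summaries if by_id.get(s.patient_id, None) and by_id[s.patient_id].group == g2]

    rows: list[dict[str, object]] = []
    rows.append(
        {
            "measure": "Number of patients analyzed",
            "group1": str(len(rec1)),
            "group2": str(len(rec2)),
            "p_value": None,
            "significant": False,
        }
    )
    h1 = sum(r.setting == "hospital" for r in rec1)
    h2 = sum(r.setting == "hospital" for r in rec2)
    tab = ContingencyTable2x2(
        a=h1, b=len(rec1) - h1, c=h2, d=len(rec2) - h2,
        row_labels=(g1, g2), col_labels=("hospital", "home"),
    )
    p_fisher = fisher_exact_two_sided(tab)
    rows.append(
        {
            "measure": "Administration in hospital",
            "group1": f"{h1} ({100 * h1 / len(rec1):.0f}%)",
            "group2": f"{h2} ({100 * h2 / len(rec2):.0f}%)",
            "p_value": round(p_fisher, 3),
            "significant": p_fisher < alpha,
        }
    )
    rows.append(
        _welch_row(
            "Mean age at administration (days)",
            np.array([r.age_days for r in rec1], dtype=float),
            np.array([r.age_days for r in rec2], dtype=float),
        )
    )
    rows.append(
        _welch_row(
            "Mean weight at administration (kg)",
            np.array([r.weight_kg for r in rec1], dtype=float),
            np.array([r.weight_kg for r in rec2], dtype=float),
        )
    )
    for measure, attr in _KINETIC_ROWS:
        rows.append(
            _welch_row(
                measure,
                np.array([getattr(s, attr) for s in sum1], dtype=float),
                np.array([getattr(s, attr) for s in sum2], dtype=float),
            )
        )
    df = pd.DataFrame(rows)
    df.attrs["group_labels"] = group_labels
    df.attrs["alpha"] = alpha
    return df


def comparison_from_summaries(summaries: pd.DataFrame) -> pd.DataFrame:
    """Compute the comparison p column from summary statistics alone.

    ``summaries`` has one row per measure with columns ``measure, test``
    plus either ``g1_n, g1_mean, g1_sem, g2_n, g2_mean, g2_sem`` (for
    ``test == "welch"``) or integer counts ``a, b, c, d`` (for
    ``test == "fisher"``).  No raw data are needed.
    """
    required = {"measure", "test"}
    if not required.issubset(summaries.columns):
        raise ValueError(f"summaries must have columns {sorted(required)}")
    rows = []
    for _, r in summaries.iterrows():
        kind = str(r["test"]).strip().lower()
        if kind == "welch":
            try:
                g1 = GroupSummary("g1", int(r["g1_n"]), float(r["g1_mean"]), float(r["g1_sem"]))
                g2 = GroupSummary("g2", int(r["g2_n"]), float(r["g2_mean"]), float(r["g2_sem"]))
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"malformed welch row {r['measure']!r}: {exc}") from exc
            p = welch_from_summary(g1, g2).p_two_tailed
            desc1 = f"{g1.mean} ± {g1.sem} (n={g1.n})"
            desc2 = f"{g2.mean} ± {g2.sem} (n={g2.n})"
        elif kind == "fisher":
            try:
                tab = ContingencyTable2x2(int(r["a"]), int(r["b"]), int(r["c"]), int(r["d"]))
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"malformed fisher row {r['measure']!r}: {exc}") from exc
            p = fisher_exact_two_sided(tab)
            desc1 = f"{tab.a}/{tab.a + tab.b}"
            desc2 = f"{tab.c}/{tab.c + tab.d}"
        else:
            raise ValueError(f"unknown test kind {kind!r} in row {r['measure']!r}")
        rows.append(
            {
                "measure": r["measure"],
                "group1": desc1,
                "group2": desc2,
                "p_value": round(p, 3),
                "significant": p < 0.05,
            }
        )
    return pd.DataFrame(rows)
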