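"""Centered polynomial regression of dose-relative ¹⁵N enrichment,
degree selection, pointwise confidence bands, derivative-root extrema,
and the labeling-period statistic.

The working model for one patient pools all in-window samples across
doses and fits an ordinary-least-squares polynomial in the centered time
``u = t − t̄`` (centering removes the near-collinearity of raw-power
regressors on a 0–24 h support).  Peak and minimum enrichment are read
off the fitted curve at the real roots of its first derivative, and the
labeling period is the length of time over which the lower confidence
band stays above the natural-abundance baseline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as P
from scipy import stats

from thymitrace.study_ingest import CohortConfig, NormalizedSample

__all__ = [
    "CenteredPolynomialFit",
    "ConfidenceBand",
    "Extrema",
    "KineticsSummary",
    "SingularFitError",
    "ExtrapolationWarning",
    "confidence_band",
    "find_extrema",
    "fit_centered_polynomial",
    "labeling_period",
    "select_degree",
    "summarize_patient",
]


class SingularFitError(np.linalg.LinAlgError):
    """Design matrix is rank deficient (too few distinct times)."""


class ExtrapolationWarning(UserWarning):
    """Band requested far outside the observed time support."""


@dataclass
class CenteredPolynomialFit:
    """OLS polynomial fit in centered time.

    ``coefficients[k]`` multiplies ``(t − center)**k``; the covariance is
    ``residual_variance · (XᵀX)⁻¹`` on the centered basis.  Fitted values
    are invariant to the centering choice.
    """

    degree: int
    center: float
    coefficients: np.ndarray
    coefficient_covariance: np.ndarray
    residual_variance: float
    dof: int
    r_squared: float
    n_obs: int
    t_min: float
    t_max: float

    def predict(self, t: float | np.ndarray) -> np.ndarray:
        return P.polyval(np.asarray(t, dtype=float) - self.center, self.coefficients)

    def se_mean(self, t: float | np.ndarray) -> np.ndarray:
        """Standard error of the fitted mean at time(s) t."""
        u = np.atleast_1d(np.asarray(t, dtype=float)) - self.center
        X = np.vander(u, self.degree + 1, increasing=True)
        var = np.einsum("ij,jk,ik->i", X, self.coefficient_covariance, X)
        return np.sqrt(np.maximum(var, 0.0))


def fit_centered_polynomial(
    times: Sequence[float] | np.ndarray,
    values: Sequence[float] | np.ndarray,
    degree: int,
) -> CenteredPolynomialFit:
    """Fit ``y = Σ bₖ (t − t̄)ᵏ`` by ordinary least squares.

    Requires ``n ≥ degree + 2`` so at least one residual degree of
    freedom remains, and at least ``degree + 1`` distinct times.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D and equal length")
    n = len(t)
    if n < degree + 2:
        raise ValueError(f"need at least degree+2={degree + 2} points, got {n}")
    if np.all(t == t[0]):
        raise SingularFitError("all times identical")
    center = float(t.mean())
    X = np.vander(t - center, degree + 1, increasing=True)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < degree + 1:
        raise SingularFitError(
            f"design rank {rank} < {degree + 1}; need more distinct times"
        )
    resid = y - X @ beta
    dof = n - (degree + 1)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    s2 = ss_res / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    return CenteredPolynomialFit(
        degree=degree,
        center=center,
        coefficients=beta,
        coefficient_covariance=cov,
        residual_variance=s2,
        dof=dof,
        r_squared=max(min(r2, 1.0), 0.0),
        n_obs=n,
        t_min=float(t.min()),
        t_max=float(t.max()),
    )


def select_degree(
    times: Sequence[float] | np.ndarray,
    values: Sequence[float] | np.ndarray,
    candidate_degrees: Sequence[int] = (1, 2, 3, 4, 5, 6),
    plateau_epsilon: float = 0.01,
) -> tuple[int, pd.DataFrame]:
    """Pick the lowest degree at which R² plateaus.

    Returns the smallest candidate ``d`` whose successor gains less than
    ``plateau_epsilon`` in R² (else the largest candidate), together with
    the full R²-per-degree table.
    """
    if plateau_epsilon <= 0:
        raise ValueError("plateau_epsilon must be positive")
    degrees = sorted(candidate_degrees)
    r2 = {d: fit_centered_polynomial(times, values, d).r_squared for d in degrees}
    table = pd.DataFrame(
        {"degree": degrees, "r_squared": [r2[d] for d in degrees]}
    )
    for d, d_next in zip(degrees, degrees[1:]):
        if r2[d_next] - r2[d] < plateau_epsilon:
            return d, table
    return degrees[-1], table


@dataclass
class ConfidenceBand:
    """Pointwise confidence band for the fitted mean curve."""

    grid: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    fit: CenteredPolynomialFit
    critical: float

    def lower_at(self, t: float | np.ndarray) -> np.ndarray:
        """Continuous lower band, evaluable between grid points."""
        return self.fit.predict(t) - self.critical * self.fit.se_mean(t)

    def upper_at(self, t: float | np.ndarray) -> np.ndarray:
        return self.fit.predict(t) + self.critical * self.fit.se_mean(t)


def confidence_band(
    fit: CenteredPolynomialFit,
    grid: Sequence[float] | np.ndarray,
    level: float = 0.95,
    method: str = "t",
) -> ConfidenceBand:
    """Pointwise band ŷ(t) ± crit · SE(ŷ(t)) for the fitted mean.

    ``method="t"`` uses the t quantile at the fit's residual degrees of
    freedom; ``method="2se"`` uses a fixed multiplier of 2 (the "mean ±
    2 SD" presentation style of curve-fitting software).
    """
    if fit.dof < 1:
        raise ValueError("fit has no residual degrees of freedom")
    g = np.asarray(grid, dtype=float)
    span = fit.t_max - fit.t_min
    if g.min() < fit.t_min - span or g.max() > fit.t_max + span:
        warnings.warn(
            "band grid extends far beyond the observed time support",
            ExtrapolationWarning,
            stacklevel=2,
        )
    if method == "t":
        crit = float(stats.t.ppf(0.5 + level / 2.0, fit.dof))
    elif method == "2se":
        crit = 2.0
    else:
        raise ValueError(f"unknown band method {method!r}")
    mean = fit.predict(g)
    half = crit * fit.se_mean(g)
    return ConfidenceBand(
        grid=g,
        mean=mean,
        lower=mean - half,
        upper=mean + half,
        level=level,
        fit=fit,
        critical=crit,
    )


@dataclass(frozen=True)
class Extrema:
    time_of_max: float
    max_value: float
    time_of_min: float
    min_value: float


def find_extrema(
    fit: CenteredPolynomialFit, support: tuple[float, float]
) -> Extrema:
    """Locate the fitted curve's extrema on a closed support.

    Real roots of the first derivative inside the open support are
    candidate interior extrema; the endpoints are always candidates
    (cubic tails outside the data are artifacts, so the search never
    leaves the support).  The max/min are the extreme fitted values over
    the candidate set.
    """
    lo, hi = float(support[0]), float(support[1])
    if not hi > lo:
        raise ValueError("support must be non-degenerate")
    deriv = P.polyder(fit.coefficients)
    candidates = [lo, hi]
    if len(deriv) > 1 and np.any(deriv[1:] != 0):
        roots = np.roots(deriv[::-1])
        for r in roots:
            if abs(r.imag) < 1e-9:
                t = float(r.real) + fit.center
                if lo < t < hi:
                    candidates.append(t)
    elif len(deriv) == 1 and deriv[0] != 0:
        pass  # linear fit: monotone, endpoints only
    cand = np.array(sorted(set(candidates)))
    vals = fit.predict(cand)
    i_max, i_min = int(np.argmax(vals)), int(np.argmin(vals))
    return Extrema(
        time_of_max=float(cand[i_max]),
        max_value=float(vals[i_max]),
        time_of_min=float(cand[i_min]),
        min_value=float(vals[i_min]),
    )


def _crossing_interval(
    lower: Callable[[float | np.ndarray], float | np.ndarray],
    baseline: float,
    time_of_min: float,
    t_end: float,
    step: float = 0.01,
    tol: float = 1e-3,
) -> tuple[float, float, bool]:
    """Locate the above-baseline interval of a continuous lower band.

    Scans [0, t_end] at ``step`` to bracket sign changes of
    ``lower(t) − baseline``, then bisects each bracket to ``tol`` hours.
    Returns ``(start, end, never_above)``.
    """

    def f(t: float) -> float:
        return float(np.atleast_1d(lower(t))[0]) - baseline

    grid = np.arange(0.0, t_end + step / 2, step)
    vals = np.asarray(lower(grid), dtype=float) - baseline
    above = vals > 0

    def bisect(a: float, b: float) -> float:
        fa = f(a)
        while b - a > tol:
            m = 0.5 * (a + b)
            if (f(m) > 0) == (fa > 0):
                a = m
                fa = f(a)
            else:
                b = m
        return 0.5 * (a + b)

    if not above.any():
        return 0.0, 0.0, True
    if above[0]:
        start = 0.0
        i0 = 0
    else:
        i0 = int(above.argmax())
        start = bisect(grid[i0 - 1], grid[i0])
    # first downcrossing after the start
    end = None
    for i in range(i0 + 1, len(grid)):
        if not above[i] and above[i - 1]:
            end = bisect(grid[i - 1], grid[i])
            break
    if end is None:
        # stayed above until the end of the labeling day
        end = float(time_of_min)
    return start, end, False


def labeling_period(
    band: ConfidenceBand,
    baseline: float,
    time_of_min: float,
) -> float:
    """Duration over which the lower confidence band exceeds the baseline.

    The labeling interval starts at 0 h if the lower band is already
    above the baseline there, otherwise at the first upcrossing; it ends
    at the first subsequent downcrossing, or — if the band stays above
    baseline throughout — at the time of minimum fitted enrichment.
    Crossings are found by bisection on the continuous band (0.01 h
    bracketing grid, 10⁻³ h tolerance).  A band entirely below baseline
    yields 0.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    t_end = float(np.max(band.grid))
    start, end, never = _crossing_interval(
        lambda t: band.lower_at(t), baseline, time_of_min, t_end
    )
    if never:
        return 0.0
    return max(end - start, 0.0)


@dataclass
class KineticsSummary:
    """Per-patient kinetic read-outs from the pooled dose-relative fit."""

    patient_id: str
    peak_value: float
    time_to_peak: float
    min_value: float
    time_of_min: float
    labeling_period: float
    r_squared: float
    degree_used: int
    n_samples: int
    never_above_baseline: bool = False


def summarize_patient(
    samples: Iterable[NormalizedSample],
    config: CohortConfig | None = None,
    patient_id: str | None = None,
) -> KineticsSummary:
    """Fit one patient's pooled dose-relative samples and summarize.

    All in-window samples across doses are pooled (up to five overlaid
    dose datasets per patient), fitted with a centered polynomial of
    ``config.degree`` (3 by default, the same model for every patient),
    and the band, extrema, and labeling period are computed on the
    observed support ``[0, min(window, max time)]``.
    """
    config = config or CohortConfig()
    samp = list(samples)
    if not samp:
        raise ValueError("no samples to summarize")
    pid = patient_id or samp[0].patient_id
    t = np.array([s.time_since_dose for s in samp])
    y = np.array([s.atom_percent for s in samp])
    fit = fit_centered_polynomial(t, y, config.degree)
    t_hi = float(min(config.window_hours, t.max()))
    grid = np.linspace(0.0, t_hi, 481)
    band = confidence_band(fit, grid, level=config.ci_level, method=config.band_method)
    ext = find_extrema(fit, (0.0, t_hi))
    period = labeling_period(band, config.baseline_atom_percent, ext.time_of_min)
    never = bool(
        np.all(band.lower_at(grid) <= config.baseline_atom_percent)
    )
    return KineticsSummary(
        patient_id=pid,
        peak_value=ext.max_value,
        time_to_peak=ext.time_of_max,
        min_value=ext.min_value,
        time_of_min=ext.time_of_min,
        labeling_period=period,
        r_squared=fit.r_squared,
        degree_used=config.degree,
        n_samples=len(samp),
        never_above_baseline=never,
    )
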