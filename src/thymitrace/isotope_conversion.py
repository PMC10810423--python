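"""Conversions between δ¹⁵N, isotope ratio, and atom percent, plus IRMS
data-reduction steps (two-point normalization, size-series blank
correction, and batch quality control of control materials).

Notation
--------
``R = ¹⁵N/¹⁴N`` is the dimensionless isotope ratio.  Delta notation
expresses a sample ratio relative to atmospheric N₂::

    δ¹⁵N_AIR = (R_sample / R_AIR − 1) × 1000  (‰)

and atom percent is the share of nitrogen atoms that are ¹⁵N::

    atom% = 100 · R / (1 + R)

The atmospheric reference ratio ``R_AIR = 0.003676`` is authoritative for
all δ conversions here; the rounded reciprocal convention ``¹⁴N/¹⁵N =
272.0`` is retained separately because the 0.37 % natural-abundance
baseline is conventionally quoted from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AIR",
    "STANDARDS",
    "BatchQC",
    "CalibrationStandard",
    "IsotopeDomainError",
    "DegenerateCalibrationError",
    "InsufficientSeriesError",
    "IsotopeValue",
    "ReferenceConstants",
    "batch_qc_summary",
    "blank_correct_size_series",
    "convert",
    "fit_blank_series",
    "two_point_normalize",
]


class IsotopeDomainError(ValueError):
    """Input lies outside the physical domain of an isotope representation."""


class DegenerateCalibrationError(ValueError):
    """Two-point normalization standards share the same known value."""


class InsufficientSeriesError(ValueError):
    """Blank-correction size series has too few distinct masses."""


@dataclass(frozen=True)
class ReferenceConstants:
    """Reference ratios for atmospheric N₂.

    ``r_air`` (¹⁵N/¹⁴N = 0.003676) and ``inverse_ratio_air``
    (¹⁴N/¹⁵N = 272.0) are two published roundings of the same quantity
    and agree only to ~4 significant figures; ``r_air`` is used for all
    δ arithmetic.
    """

    r_air: float = 0.003676
    inverse_ratio_air: float = 272.0

    def __post_init__(self) -> None:
        if self.r_air <= 0:
            raise IsotopeDomainError("r_air must be positive")
        if abs(1.0 / self.inverse_ratio_air - self.r_air) / self.r_air >= 1e-3:
            raise IsotopeDomainError(
                "r_air and inverse_ratio_air disagree beyond rounding"
            )


AIR = ReferenceConstants()


@dataclass(frozen=True)
class IsotopeValue:
    """One ¹⁵N measurement carried in all three equivalent representations."""

    delta_air: float
    ratio: float
    atom_percent: float

    def __post_init__(self) -> None:
        if not (0.0 < self.atom_percent < 100.0):
            raise IsotopeDomainError(
                f"atom_percent {self.atom_percent!r} outside (0, 100)"
            )
        if self.ratio <= 0:
            raise IsotopeDomainError(f"ratio {self.ratio!r} must be positive")


def convert(
    *,
    delta_air: float | None = None,
    ratio: float | None = None,
    atom_percent: float | None = None,
    constants: ReferenceConstants = AIR,
) -> IsotopeValue:
    """Build an :class:`IsotopeValue` from exactly one representation.

    Parameters
    ----------
    delta_air:
        δ¹⁵N in ‰ versus atmospheric N₂ (must exceed −1000 ‰).
    ratio:
        ¹⁵N/¹⁴N, strictly positive.
    atom_percent:
        Percentage of N atoms that are ¹⁵N, in the open interval (0, 100).
    constants:
        Reference ratios; defaults to atmospheric air.

    Returns
    -------
    IsotopeValue with all three representations mutually consistent.
    """
    given = [v is not None for v in (delta_air, ratio, atom_percent)]
    if sum(given) != 1:
        raise ValueError("provide exactly one of delta_air, ratio, atom_percent")

    if delta_air is not None:
        if not math.isfinite(delta_air) or delta_air <= -1000.0:
            raise IsotopeDomainError(
                f"delta_air {delta_air!r} implies a non-positive ratio"
            )
        r = constants.r_air * (1.0 + delta_air / 1000.0)
    elif ratio is not None:
        if not math.isfinite(ratio) or ratio <= 0:
            raise IsotopeDomainError(f"ratio {ratio!r} must be positive")
        r = float(ratio)
    else:
        assert atom_percent is not None
        if not math.isfinite(atom_percent) or not (0.0 < atom_percent < 100.0):
            raise IsotopeDomainError(
                f"atom_percent {atom_percent!r} outside (0, 100)"
            )
        f = atom_percent / 100.0
        r = f / (1.0 - f)

    delta = (r / constants.r_air - 1.0) * 1000.0
    ap = 100.0 * r / (1.0 + r)
    return IsotopeValue(delta_air=delta, ratio=r, atom_percent=ap)


@dataclass
class CalibrationStandard:
    """A reference material with a known δ¹⁵N and, once run, a measured one."""

    name: str
    known_delta: float
    measured_delta: float = math.nan


#: In-house protein standards (known δ¹⁵N_AIR, ‰) used for normalization.
STANDARDS: Mapping[str, float] = {
    "casein": 6.43,
    "soy": 0.98,
    "tuna": 13.32,
}


def two_point_normalize(
    measurements: Sequence[float] | np.ndarray,
    standard_lo: CalibrationStandard,
    standard_hi: CalibrationStandard,
) -> np.ndarray:
    """Affinely map measured δ values onto the known-standard scale.

    The unique affine map sending each standard's measured δ onto its
    known δ is applied to every measurement, the usual two-point scale
    normalization of continuous-flow IRMS runs.
    """
    if standard_lo.known_delta == standard_hi.known_delta:
        raise DegenerateCalibrationError(
            "standards have identical known values; calibration line undefined"
        )
    if standard_lo.measured_delta == standard_hi.measured_delta:
        raise DegenerateCalibrationError(
            "standards have identical measured values; calibration line undefined"
        )
    x = np.asarray(measurements, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("measurements must be finite")
    slope = (standard_hi.known_delta - standard_lo.known_delta) / (
        standard_hi.measured_delta - standard_lo.measured_delta
    )
    return standard_lo.known_delta + slope * (x - standard_lo.measured_delta)


def fit_blank_series(
    series: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Fit the size-series blank model δ_meas = δ_true + c/m by OLS.

    ``series`` is a sequence of (dried mass mg, measured δ‰) pairs.
    Returns ``(delta_true, c)``.  A constant blank of ``c`` ‰·mg shifts
    small samples more than large ones, which is why the regressor is
    1/mass.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("series must be (mass, delta) pairs")
    masses, deltas = arr[:, 0], arr[:, 1]
    if np.any(masses <= 0):
        raise InsufficientSeriesError("series masses must be positive")
    if len(np.unique(masses)) < 3:
        raise InsufficientSeriesError(
            "size series needs at least 3 distinct masses"
        )
    X = np.column_stack([np.ones_like(masses), 1.0 / masses])
    beta, *_ = np.linalg.lstsq(X, deltas, rcond=None)
    return float(beta[0]), float(beta[1])


def blank_correct_size_series(
    series: Sequence[tuple[float, float]],
    samples: Sequence[tuple[float, float]],
) -> np.ndarray:
    """Blank-correct sample δ values using a glycine-style size series.

    The estimated blank term ĉ/m is subtracted from each sample's
    measured δ.  With an estimated blank of zero the output equals the
    input.
    """
    _, c_hat = fit_blank_series(series)
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("samples must be (mass, delta) pairs")
    masses, deltas = arr[:, 0], arr[:, 1]
    if np.any(masses <= 0):
        raise ValueError("sample masses must be positive")
    return deltas - c_hat / masses


#: Nominal atom-percent values of unlabeled control materials as measured
#: on the reporting scale (natural-abundance protein/amino-acid material).
CONTROL_NOMINALS: Mapping[str, float] = {
    "glycine": 0.371,
    "peptone": 0.371,
}


@dataclass
class BatchQC:
    """Per-(batch, material) control summary with a control-limit flag."""

    batch_id: str
    material: str
    mean_atom_percent: float
    sd_atom_percent: float
    n: int
    flagged: bool = field(default=False)


def batch_qc_summary(
    control_runs: Iterable[tuple[str, str, float]],
    nominals: Mapping[str, float] = CONTROL_NOMINALS,
    n_sigma: float = 3.0,
) -> list[BatchQC]:
    """Summarize control-material runs per (batch, material).

    Each group gets its mean, sample SD, and n.  A batch is flagged when
    its control mean deviates from the material's registered nominal by
    more than ``n_sigma · sd/√n`` (the standard control limit); materials
    without a registered nominal are never flagged.
    """
    rows = list(control_runs)
    if not rows:
        return []
    df = pd.DataFrame(rows, columns=["batch_id", "material", "atom_percent"])
    out: list[BatchQC] = []
    for (batch, material), grp in df.groupby(["batch_id", "material"], sort=True):
        vals = grp["atom_percent"].to_numpy(dtype=float)
        n = len(vals)
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        flagged = False
        nominal = nominals.get(str(material))
        if nominal is not None and n > 1 and sd > 1e-12:
            flagged = abs(mean - nominal) > n_sigma * sd / math.sqrt(n)
        elif nominal is not None:
            # no spread to set a limit; flag only mismatch beyond rounding
            flagged = abs(mean - nominal) > 5e-4
        out.append(
            BatchQC(
                batch_id=str(batch),
                material=str(material),
                mean_atom_percent=mean,
                sd_atom_percent=sd,
                n=n,
                flagged=flagged,
            )
        )
    return out
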