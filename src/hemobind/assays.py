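"""Erythrocyte carrier-assay arithmetic.

Hemolysis rate, drug-loading efficiency, internal-standard calibration
quantitation, and erythrocyte/plasma partition coefficients.

Control naming for hemolysis is semantic: the saline (no-lysis) control
is the *baseline* and maps to 0%, the distilled-water (complete-lysis)
control is *full lysis* and maps to 100%:

    hemolysis(%) = (OD_sample - OD_baseline) / (OD_full - OD_baseline) × 100.

The partition coefficient Ce/p is three-valued: finite (Cp > 0),
infinite (Cp = 0 with drug present in the cells — plasma below the
detection limit), or undefined (both zero, or a missing measurement).
Summaries average finite ratios only and report the counts of each kind.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .datatypes import LoadingMeasurement, ODMeasurement, PartitionRecord

__all__ = [
    "hemolysis_rate",
    "loading_efficiency",
    "CalibrationCurve",
    "CalibrationModel",
    "fit_calibration",
    "quantify",
    "RatioKind",
    "PartitionRatio",
    "partition_ratio",
    "PartitionSummary",
    "summarize_partition",
]


def hemolysis_rate(od: ODMeasurement) -> float:
    """Hemolysis rate in %, affine in sample OD between the two controls."""
    span = od.full_lysis_od - od.baseline_od
    if span <= 0:
        raise ValueError("degenerate controls: full-lysis OD must exceed baseline")
    return (od.sample_od - od.baseline_od) / span * 100.0


def loading_efficiency(m: LoadingMeasurement) -> tuple[float, bool]:
    """Loading efficiency (%) = (C_original - C_post)/C_original × 100.

    Returns ``(percent, negative_flag)``. A post-incubation concentration
    above the original one (measurement noise) gives a negative value with
    the flag set rather than an exception.
    """
    pct = (m.conc_original - m.conc_post) / m.conc_original * 100.0
    return float(pct), bool(pct < 0.0)


# ---------------------------------------------------------------------------
# internal-standard calibration y = a x + b

@dataclass(frozen=True)
class CalibrationCurve:
    """Linear calibration of peak-area ratio on concentration."""

    slope_a: float  # ratio per (μg/mL)
    intercept_b: float
    r_squared: float
    conc_range: tuple[float, float]  # μg/mL span of the standards
    n_standards: int

    def summary(self) -> str:
        return "\n".join([
            "Internal-standard calibration",
            "=============================",
            f"y = a x + b with a = {self.slope_a:.6g}, b = {self.intercept_b:.6g}",
            f"r^2 = {self.r_squared:.6f}   n = {self.n_standards}",
            f"range = [{self.conc_range[0]:.6g}, {self.conc_range[1]:.6g}] μg/mL",
        ])


class CalibrationModel:
    """OLS calibration fit from ≥ 3 standards of distinct concentration."""

    def __init__(self, standards):
        pts = [(float(c), float(y)) for c, y in standards]
        if len(pts) < 3:
            raise np.linalg.LinAlgError("need >= 3 calibration standards")
        concs = np.array([c for c, _ in pts])
        if len(np.unique(concs)) < 2:
            raise np.linalg.LinAlgError("calibration concentrations all equal")
        self.concs = concs
        self.ratios = np.array([y for _, y in pts])

    def fit(self) -> CalibrationCurve:
        res = stats.linregress(self.concs, self.ratios)
        return CalibrationCurve(slope_a=float(res.slope),
                                intercept_b=float(res.intercept),
                                r_squared=float(res.rvalue**2),
                                conc_range=(float(self.concs.min()),
                                            float(self.concs.max())),
                                n_standards=len(self.concs))


def fit_calibration(standards) -> CalibrationCurve:
    """Convenience wrapper: ``CalibrationModel(standards).fit()``."""
    return CalibrationModel(standards).fit()


def quantify(peak_area_ratio: float, curve: CalibrationCurve) -> tuple[float, bool]:
    """Invert the calibration: concentration = (y - b)/a.

    Returns ``(conc_ug_per_ml, extrapolated)``; the flag is set when the
    result lies outside the standards' concentration range.
    """
    if curve.slope_a == 0:
        raise ZeroDivisionError("degenerate calibration curve: zero slope")
    conc = (peak_area_ratio - curve.intercept_b) / curve.slope_a
    lo, hi = curve.conc_range
    tol = 1e-9 * max(abs(lo), abs(hi), 1.0)  # don't flag boundary round-off
    return float(conc), bool(conc < lo - tol or conc > hi + tol)


# ---------------------------------------------------------------------------
# erythrocyte/plasma partition

class RatioKind(str, Enum):
    FINITE = "finite"
    INFINITE = "infinite"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class PartitionRatio:
    kind: RatioKind
    value: float | None = None  # present iff finite
    missing_data: bool = False


def partition_ratio(rec: PartitionRecord) -> PartitionRatio:
    """Three-valued Ce/Cp for one record.

    0/0 is undefined (not infinite): with no drug detected in either
    compartment the ratio carries no information.
    """
    ce, cp = rec.c_erythrocyte, rec.c_plasma
    if ce is None or cp is None:
        return PartitionRatio(RatioKind.UNDEFINED, missing_data=True)
    if cp > 0:
        return PartitionRatio(RatioKind.FINITE, value=ce / cp)
    if ce > 0:
        return PartitionRatio(RatioKind.INFINITE)
    return PartitionRatio(RatioKind.UNDEFINED)


@dataclass(frozen=True)
class PartitionSummary:
    time_min: float
    mean: float | None  # over finite ratios; None when there are none
    sd: float | None  # sample SD; None when < 2 finite ratios
    n_finite: int
    n_infinite: int
    n_undefined: int

    @property
    def all_infinite(self) -> bool:
        return self.n_finite == 0 and self.n_infinite > 0


def summarize_partition(records: list[PartitionRecord],
                        time_min: float) -> PartitionSummary:
    """Summarize Ce/p at one timepoint: mean/SD of finite ratios + kind counts."""
    group = [r for r in records if r.time_min == time_min]
    if not group:
        raise ValueError(f"no partition records at t = {time_min} min")
    ratios = [partition_ratio(r) for r in group]
    finite = [r.value for r in ratios if r.kind is RatioKind.FINITE]
    n_inf = sum(r.kind is RatioKind.INFINITE for r in ratios)
    n_undef = sum(r.kind is RatioKind.UNDEFINED for r in ratios)
    mean = float(np.mean(finite)) if finite else None
    sd = float(np.std(finite, ddof=1)) if len(finite) >= 2 else None
    if mean is not None and not math.isfinite(mean):  # defensive; cannot happen
        mean = None
    return PartitionSummary(time_min=time_min, mean=mean, sd=sd,
                            n_finite=len(finite), n_infinite=n_inf,
                            n_undefined=n_undef)
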