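"""Fluorescence quenching analysis.

The Stern-Volmer model relates the ratio of unquenched to quenched
fluorescence to quencher concentration,

    F0 / F = 1 + Ksv [Q] = 1 + kq τ0 [Q],

where Ksv (L/mol) is the Stern-Volmer constant, kq = Ksv/τ0 the
bimolecular quenching rate constant and τ0 the unquenched fluorophore
lifetime. Before forming F0/F every intensity is corrected for the inner
filter effect,

    F_corr = F_obs × 10^((A_ex + A_em)/2),

which undoes attenuation by sample absorbance at the excitation and
emission wavelengths.

Mechanism diagnosis uses the temperature trend of Ksv: a complex-forming
(static) quencher shows Ksv falling with temperature, a purely collisional
(dynamic) one shows it rising; kq far above the diffusion-controlled limit
(~2×10¹⁰ L mol⁻¹ s⁻¹) independently rules out pure collision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from .datatypes import TitrationSeries, ValidationError

__all__ = [
    "DEFAULT_TAU0_S",
    "DIFFUSION_LIMIT_KQ",
    "correct_inner_filter",
    "corrected_intensities",
    "SternVolmerModel",
    "QuenchingFit",
    "Mechanism",
    "MechanismCall",
    "classify_mechanism",
]

#: Unquenched fluorophore lifetime (s) used to convert Ksv to kq.
DEFAULT_TAU0_S = 1e-8

#: Diffusion-controlled bimolecular quenching limit, L mol^-1 s^-1.
DIFFUSION_LIMIT_KQ = 2.0e10


def correct_inner_filter(f_observed, a_ex, a_em):
    """Inner-filter-corrected intensity F_obs × 10^((A_ex + A_em)/2).

    Identity when both absorbances are zero; monotone increasing in each
    absorbance. Accepts scalars or arrays.
    """
    a_ex = np.asarray(a_ex, dtype=float)
    a_em = np.asarray(a_em, dtype=float)
    f_observed = np.asarray(f_observed, dtype=float)
    if np.any(a_ex < 0) or np.any(a_em < 0):
        raise ValueError("absorbances must be >= 0")
    if np.any(f_observed < 0):
        raise ValueError("f_observed must be >= 0")
    out = f_observed * 10.0 ** ((a_ex + a_em) / 2.0)
    return out if out.ndim else float(out)


def corrected_intensities(series: TitrationSeries) -> np.ndarray:
    """Inner-filter-corrected intensity for every point of a series."""
    return correct_inner_filter(series.f_observed, series.a_ex, series.a_em)


@dataclass(frozen=True)
class QuenchingFit:
    """Results of a Stern-Volmer fit at one temperature.

    ``kq = ksv / tau0`` holds exactly by construction.
    """

    ksv: float  # L/mol
    kq: float  # L mol^-1 s^-1
    tau0: float  # s
    intercept: float
    r_corr: float
    ksv_stderr: float
    temperature: float  # K
    n_points: int
    intercept_mode: str

    def summary(self) -> str:
        lines = [
            "Stern-Volmer quenching fit",
            "==========================",
            f"temperature        {self.temperature:.6g} K",
            f"n (nonzero [Q])    {self.n_points}",
            f"intercept mode     {self.intercept_mode}",
            f"Ksv                {self.ksv:.6g} L/mol  (se {self.ksv_stderr:.3g})",
            f"intercept          {self.intercept:.6g}",
            f"tau0               {self.tau0:.6g} s",
            f"kq = Ksv/tau0      {self.kq:.6g} L mol^-1 s^-1",
            f"r                  {self.r_corr:.6f}",
        ]
        return "\n".join(lines)


class SternVolmerModel:
    """Linear Stern-Volmer model for one inner-filter-corrected titration.

    Parameters
    ----------
    series : TitrationSeries
        Titration at a single temperature, including the zero-quencher
        point that defines F0. The inner-filter correction is applied
        internally to every point (including F0) before ratios are formed.
    tau0 : float
        Unquenched lifetime in seconds; default 1e-8 s.
    intercept_mode : {"free", "fixed_at_one"}
        ``free`` fits slope and intercept by ordinary least squares;
        ``fixed_at_one`` constrains the intercept to the theoretical 1.
    """

    def __init__(self, series: TitrationSeries, tau0: float = DEFAULT_TAU0_S,
                 intercept_mode: str = "free"):
        if intercept_mode not in ("free", "fixed_at_one"):
            raise ValueError(f"unknown intercept_mode {intercept_mode!r}")
        if tau0 <= 0:
            raise ValueError("tau0 must be positive")
        self.series = series
        self.tau0 = tau0
        self.intercept_mode = intercept_mode

        f_corr = corrected_intensities(series)
        q = series.quencher_conc
        zero = q == 0
        self.f0 = float(f_corr[zero][0])
        self.q = q[~zero]
        self.f = f_corr[~zero]
        if len(self.q) < 3:
            raise ValidationError("need >= 3 nonzero-quencher points")
        if self.f0 <= 0 or np.any(self.f <= 0):
            raise ValueError("corrected intensities must be positive")
        if np.ptp(self.q) == 0:
            raise np.linalg.LinAlgError("degenerate titration: all [Q] equal")

    def fit(self) -> QuenchingFit:
        y = self.f0 / self.f
        x = self.q
        if self.intercept_mode == "free":
            res = stats.linregress(x, y)
            slope, intercept = float(res.slope), float(res.intercept)
            r = float(res.rvalue)
            stderr = float(res.stderr)
        else:
            # least squares through the theoretical intercept of 1
            slope = float(np.dot(x, y - 1.0) / np.dot(x, x))
            intercept = 1.0
            resid = y - 1.0 - slope * x
            dof = len(x) - 1
            stderr = float(np.sqrt(np.sum(resid**2) / dof / np.dot(x, x))) if dof else np.nan
            with np.errstate(invalid="ignore"):
                r = float(stats.pearsonr(x, y).statistic) if np.ptp(y) > 0 else 0.0
        return QuenchingFit(ksv=slope, kq=slope / self.tau0, tau0=self.tau0,
                            intercept=intercept, r_corr=r, ksv_stderr=stderr,
                            temperature=self.series.temperature,
                            n_points=len(x), intercept_mode=self.intercept_mode)


class Mechanism(str, Enum):
    STATIC = "static"
    DYNAMIC = "dynamic"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class MechanismCall:
    """Quenching-mechanism classification across temperatures."""

    mechanism: Mechanism
    ksv_by_temperature: tuple[tuple[float, float], ...]  # (T, ksv) ascending T
    diffusion_limit_flag: bool
    note: str = ""


def classify_mechanism(fits: list[QuenchingFit],
                       diffusion_limit: float = DIFFUSION_LIMIT_KQ) -> MechanismCall:
    """Classify quenching as static or dynamic from the Ksv(T) trend.

    Strictly decreasing Ksv with rising temperature → static (ground-state
    complex); strictly increasing → dynamic (collisional); anything else,
    including a single temperature, → indeterminate. ``diffusion_limit_flag``
    is set when even the smallest kq exceeds the diffusion-controlled limit,
    which independently argues against a purely dynamic mechanism.
    """
    fits = sorted(fits, key=lambda f: f.temperature)
    evidence = tuple((f.temperature, f.ksv) for f in fits)
    kq_min = min((f.kq for f in fits), default=np.nan)
    flag = bool(len(fits) > 0 and kq_min > diffusion_limit)
    if len(fits) < 2:
        warnings.warn("mechanism classification needs >= 2 temperatures",
                      stacklevel=2)
        return MechanismCall(Mechanism.INDETERMINATE, evidence, flag,
                             note="fewer than 2 temperatures")
    ksv = np.array([f.ksv for f in fits])
    d = np.diff(ksv)
    if np.all(d < 0):
        mech = Mechanism.STATIC
    elif np.all(d > 0):
        mech = Mechanism.DYNAMIC
    else:
        mech = Mechanism.INDETERMINATE
    return MechanismCall(mech, evidence, flag)
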