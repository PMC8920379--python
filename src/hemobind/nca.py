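"""Noncompartmental pharmacokinetic analysis (NCA).

Model-free estimation of the standard parameter set from a single
concentration-time profile: exposure (AUC0-t by the linear trapezoid,
AUC0-inf by C_last/λz extrapolation), the terminal disposition rate λz
from a log-linear regression on terminal points, the half-life
t1/2 = ln2/λz, mean residence time MRT = AUMC0-inf/AUC0-inf, apparent
clearance CL/F = dose/AUC0-inf, and C0 (i.v., log-linear back-
extrapolation through the first two points) or Cmax/Tmax (oral,
observed maximum, earliest time on ties).

λz point selection defaults to ``best_adj_r2``: every terminal suffix of
at least three positive concentrations, excluding the observed peak, is
fitted and the suffix with the highest adjusted R² wins, ties going to
the longer suffix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import PKProfile, Route

__all__ = [
    "InsufficientDataError",
    "NoTerminalPhaseError",
    "auc_trapezoid",
    "aumc_trapezoid",
    "LambdaZFit",
    "fit_lambda_z",
    "auc_to_infinity",
    "mrt",
    "c0_backextrapolate",
    "NCAResult",
    "NCA",
]


class InsufficientDataError(ValueError):
    """Too few usable observations for the requested quantity."""


class NoTerminalPhaseError(ValueError):
    """The terminal concentrations do not decline."""


def _clean(profile: PKProfile, lloq: float | None) -> tuple[np.ndarray, np.ndarray]:
    """Apply the below-quantification rule: values under the LLOQ are
    dropped before the observed peak and set to zero after the last
    value at or above it."""
    t, c = profile.times.copy(), profile.concentrations.copy()
    if lloq is None:
        return t, c
    above = c >= lloq
    if not above.any():
        raise InsufficientDataError("all concentrations below the LLOQ")
    i_peak = int(np.argmax(c))
    i_last = int(np.flatnonzero(above)[-1])
    keep = above | (np.arange(len(c)) >= i_peak)
    t, c = t[keep], c[keep]
    c[np.flatnonzero(t > profile.times[i_last])] = 0.0
    return t, c


def auc_trapezoid(profile: PKProfile) -> float:
    """AUC0-t (μg·h/mL) by the linear trapezoidal rule."""
    if len(profile) < 2:
        raise InsufficientDataError("AUC needs >= 2 timepoints")
    return float(np.trapezoid(profile.concentrations, profile.times))


def aumc_trapezoid(profile: PKProfile) -> float:
    """AUMC0-t (μg·h²/mL): linear trapezoid of t·C(t)."""
    if len(profile) < 2:
        raise InsufficientDataError("AUMC needs >= 2 timepoints")
    return float(np.trapezoid(profile.times * profile.concentrations,
                              profile.times))


@dataclass(frozen=True)
class LambdaZFit:
    lambda_z: float  # 1/h
    t_half: float  # h
    n_points: int
    r2_adj: float
    r2: float
    t_first: float  # start of the terminal window, h
    intercept: float  # ln-concentration intercept


def _adj_r2(r2: float, n: int) -> float:
    if n <= 2:
        return -np.inf
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def fit_lambda_z(profile: PKProfile, selection: str = "best_adj_r2",
                 n_points: int = 3, lloq: float | None = None) -> LambdaZFit:
    """Terminal log-linear regression.

    selection="last_n" fits the last ``n_points`` positive concentrations;
    "best_adj_r2" scans every terminal suffix of >= 3 positive points that
    excludes the observed peak and keeps the best adjusted R² (ties toward
    more points).
    """
    t, c = _clean(profile, lloq)
    pos = c > 0
    i_peak = int(np.argmax(c))
    tp, cp = t[pos], c[pos]
    # map peak index into the positive subset
    peak_in_pos = int(np.searchsorted(np.flatnonzero(pos), i_peak))
    if len(tp) < 3:
        raise InsufficientDataError("need >= 3 positive terminal concentrations")

    def fit_suffix(start: int) -> LambdaZFit | None:
        x, y = tp[start:], np.log(cp[start:])
        if len(x) < 3 or np.ptp(x) == 0:
            return None
        res = stats.linregress(x, y)
        if res.slope >= 0:
            return None
        lz = -float(res.slope)
        r2 = float(res.rvalue**2)
        return LambdaZFit(lambda_z=lz, t_half=float(np.log(2) / lz),
                          n_points=len(x), r2_adj=_adj_r2(r2, len(x)), r2=r2,
                          t_first=float(x[0]), intercept=float(res.intercept))

    if selection == "last_n":
        fit = fit_suffix(len(tp) - n_points)
        if fit is None:
            raise NoTerminalPhaseError("terminal concentrations do not decline")
        return fit
    if selection != "best_adj_r2":
        raise ValueError(f"unknown selection {selection!r}")

    first_allowed = peak_in_pos + 1 if peak_in_pos < len(tp) - 3 else peak_in_pos
    best: LambdaZFit | None = None
    for start in range(first_allowed, len(tp) - 2):
        fit = fit_suffix(start)
        if fit is None:
            continue
        if best is None or fit.r2_adj > best.r2_adj + 1e-12:
            best = fit
        elif abs(fit.r2_adj - best.r2_adj) <= 1e-12 and fit.n_points > best.n_points:
            best = fit
    if best is None:
        raise NoTerminalPhaseError("no declining terminal suffix of >= 3 points")
    return best


def auc_to_infinity(auc_0_t: float, c_last: float,
                    lambda_z: float) -> tuple[float, float]:
    """AUC0-inf = AUC0-t + C_last/λz; returns (auc_inf, extrapolated fraction)."""
    if lambda_z <= 0:
        raise ValueError("lambda_z must be positive")
    if c_last < 0:
        raise ValueError("c_last must be >= 0")
    tail = c_last / lambda_z
    auc_inf = auc_0_t + tail
    return float(auc_inf), float(tail / auc_inf) if auc_inf > 0 else 0.0


def mrt(profile: PKProfile, lambda_z: float) -> float:
    """Mean residence time AUMC0-inf / AUC0-inf, in hours."""
    if np.all(profile.concentrations == 0):
        raise InsufficientDataError("all-zero concentration profile")
    auc_t = auc_trapezoid(profile)
    aumc_t = aumc_trapezoid(profile)
    t_last = float(profile.times[-1])
    c_last = float(profile.concentrations[-1])
    auc_inf, _ = auc_to_infinity(auc_t, c_last, lambda_z)
    aumc_inf = aumc_t + t_last * c_last / lambda_z + c_last / lambda_z**2
    return float(aumc_inf / auc_inf)


def c0_backextrapolate(profile: PKProfile) -> tuple[float, bool]:
    """Back-extrapolated C0 for an i.v. bolus profile.

    Log-linear line through the first two observed points, evaluated at
    t = 0. Returns ``(c0, fallback)``; when either leading concentration
    is nonpositive the first observed concentration is returned with the
    flag set.
    """
    if profile.route is not Route.INTRAVENOUS:
        raise ValueError("C0 back-extrapolation applies to intravenous profiles")
    t, c = profile.times, profile.concentrations
    if len(t) < 2 or c[0] <= 0 or c[1] <= 0:
        return float(c[0]), True
    if c[0] == c[1]:
        return float(c[0]), False
    slope = (np.log(c[1]) - np.log(c[0])) / (t[1] - t[0])
    return float(np.exp(np.log(c[0]) - slope * t[0])), False


@dataclass(frozen=True)
class NCAResult:
    """Noncompartmental parameter set for one profile."""

    route: Route
    dose: float  # mg/kg
    c0_or_cmax: float  # μg/mL
    tmax: float | None  # h, oral only
    lambda_z: float  # 1/h
    t_half: float  # h
    auc_0_t: float  # μg·h/mL
    auc_0_inf: float  # μg·h/mL
    auc_extrap_frac: float
    mrt: float  # h
    clearance_over_f: float  # mL/h/kg
    c0_fallback: bool
    lambda_z_n_points: int
    lambda_z_r2_adj: float

    def summary(self) -> str:
        head = "C0" if self.route is Route.INTRAVENOUS else "Cmax"
        lines = [
            "Noncompartmental analysis",
            "=========================",
            f"route            {self.route.value}   dose {self.dose:.6g} mg/kg",
            f"{head:<16} {self.c0_or_cmax:.6g} μg/mL",
        ]
        if self.tmax is not None:
            lines.append(f"Tmax             {self.tmax:.6g} h")
        lines += [
            f"lambda_z         {self.lambda_z:.6g} 1/h "
            f"({self.lambda_z_n_points} pts, adj R² {self.lambda_z_r2_adj:.5f})",
            f"t1/2             {self.t_half:.6g} h",
            f"AUC0-t           {self.auc_0_t:.6g} μg·h/mL",
            f"AUC0-inf         {self.auc_0_inf:.6g} μg·h/mL "
            f"({100 * self.auc_extrap_frac:.2f}% extrapolated)",
            f"MRT              {self.mrt:.6g} h",
            f"CL/F             {self.clearance_over_f:.6g} mL/h/kg",
        ]
        return "\n".join(lines)


class NCA:
    """Noncompartmental analysis model for one concentration-time profile.

    Parameters
    ----------
    profile : PKProfile
    lambda_z_selection : {"best_adj_r2", "last_n"}
    lambda_z_n : int
        Number of points for ``last_n`` selection.
    lloq : float, optional
        Lower limit of quantification; below-LLOQ values are dropped
        before the peak and zeroed after the last quantifiable value.
    """

    def __init__(self, profile: PKProfile, lambda_z_selection: str = "best_adj_r2",
                 lambda_z_n: int = 3, lloq: float | None = None):
        self.profile = profile
        self.lambda_z_selection = lambda_z_selection
        self.lambda_z_n = lambda_z_n
        self.lloq = lloq

    def fit(self) -> NCAResult:
        profile = self.profile
        lz = fit_lambda_z(profile, self.lambda_z_selection, self.lambda_z_n,
                          self.lloq)
        auc_t = auc_trapezoid(profile)
        auc_inf, frac = auc_to_infinity(auc_t, float(profile.concentrations[-1]),
                                        lz.lambda_z)
        mean_rt = mrt(profile, lz.lambda_z)
        if profile.route is Route.INTRAVENOUS:
            c_top, fallback = c0_backextrapolate(profile)
            tmax = None
        else:
            i = int(np.argmax(profile.concentrations))  # argmax: earliest tie
            c_top, fallback = float(profile.concentrations[i]), False
            tmax = float(profile.times[i])
        dose_ug_per_kg = profile.dose * 1000.0
        cl_f = dose_ug_per_kg / auc_inf  # (μg/kg)/(μg·h/mL) = mL/h/kg
        return NCAResult(route=profile.route, dose=profile.dose,
                         c0_or_cmax=c_top, tmax=tmax, lambda_z=lz.lambda_z,
                         t_half=lz.t_half, auc_0_t=auc_t, auc_0_inf=auc_inf,
                         auc_extrap_frac=frac, mrt=mean_rt,
                         clearance_over_f=cl_f, c0_fallback=fallback,
                         lambda_z_n_points=lz.n_points,
                         lambda_z_r2_adj=lz.r2_adj)
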