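"""Binding-constant estimation and van't Hoff thermodynamics.

For a small molecule binding to one set of *n* equivalent sites on a
protein, the quenching data obey the double-logarithm relation

    lg((F0 - F)/F) = lg Ka + n lg [Q],

so an ordinary least-squares line of lg((F0-F)/F) on lg[Q] yields the
association constant Ka (10^intercept, L/mol) and the number of binding
sites n (slope). The temperature dependence of Ka carries the binding
thermodynamics through the van't Hoff relation

    ln((Ka)2/(Ka)1) = (1/T1 - 1/T2) ΔH°/R,

together with ΔG° = -RT ln Ka = ΔH° - TΔS°. The signs of (ΔH°, ΔS°)
classify the dominant noncovalent force (Ross-Subramanian rules):
both negative → van der Waals / hydrogen bonds; both positive →
hydrophobic; ΔH° < 0 with ΔS° > 0 → electrostatic.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .datatypes import TitrationSeries, ValidationError
from .quenching import corrected_intensities

__all__ = [
    "R_GAS",
    "BindingFit",
    "DoubleLogBindingModel",
    "VantHoffModel",
    "ThermoParams",
    "vant_hoff_enthalpy",
    "gibbs_from_ka",
    "gibbs_from_enthalpy_entropy",
    "entropy_from_gibbs",
    "BindingForce",
    "ForceCall",
    "classify_forces",
]

#: Universal gas constant, J mol^-1 K^-1. Fixed — no unit configurability.
R_GAS = 8.314


@dataclass(frozen=True)
class BindingFit:
    """One-set-of-sites binding parameters at a single temperature."""

    ka: float  # L/mol
    n_sites: float
    r_corr: float
    intercept_stderr: float
    slope_stderr: float
    temperature: float  # K
    n_points: int

    def summary(self) -> str:
        return "\n".join([
            "Double-log binding fit",
            "======================",
            f"temperature   {self.temperature:.6g} K",
            f"n points      {self.n_points}",
            f"Ka            {self.ka:.6g} L/mol",
            f"n sites       {self.n_sites:.6g}  (se {self.slope_stderr:.3g})",
            f"r             {self.r_corr:.6f}",
        ])


class DoubleLogBindingModel:
    """Estimate (Ka, n) from an inner-filter-corrected titration.

    Points with F >= F0 at nonzero quencher carry no quenching signal and
    are rejected: the double-log transform requires 0 < F < F0.
    """

    def __init__(self, series: TitrationSeries):
        self.series = series
        f_corr = corrected_intensities(series)
        q = series.quencher_conc
        zero = q == 0
        self.f0 = float(f_corr[zero][0])
        self.q = q[~zero]
        self.f = f_corr[~zero]
        if np.any(self.f >= self.f0):
            raise ValueError("no quenching: F >= F0 at nonzero quencher")
        if np.any(self.f <= 0):
            raise ValueError("corrected intensities must be positive")
        if len(self.q) < 3:
            raise ValidationError("need >= 3 usable nonzero-quencher points")

    def fit(self) -> BindingFit:
        x = np.log10(self.q)
        y = np.log10((self.f0 - self.f) / self.f)
        if np.ptp(x) == 0:
            raise np.linalg.LinAlgError("degenerate titration: all [Q] equal")
        res = stats.linregress(x, y)
        return BindingFit(ka=float(10.0 ** res.intercept),
                          n_sites=float(res.slope),
                          r_corr=float(res.rvalue),
                          intercept_stderr=float(res.intercept_stderr),
                          slope_stderr=float(res.stderr),
                          temperature=self.series.temperature,
                          n_points=len(x))


# ---------------------------------------------------------------------------
# thermodynamics

def vant_hoff_enthalpy(ka_by_temperature) -> float:
    """van't Hoff enthalpy change ΔH° in kJ/mol.

    For exactly two temperatures the closed two-point formula is used;
    for more, the slope of ln Ka against 1/T times -R. The two coincide
    exactly at two points (least squares through two points is exact).

    Parameters
    ----------
    ka_by_temperature : sequence of (temperature_K, ka) pairs
    """
    pairs = sorted((float(t), float(k)) for t, k in ka_by_temperature)
    if len(pairs) < 2:
        raise ValueError("need >= 2 temperatures")
    temps = np.array([t for t, _ in pairs])
    kas = np.array([k for _, k in pairs])
    if np.any(kas <= 0):
        raise ValueError("ka must be positive")
    if len(np.unique(temps)) != len(temps):
        raise np.linalg.LinAlgError("duplicate temperatures")
    if len(pairs) == 2:
        (t1, k1), (t2, k2) = pairs
        return float(np.log(k2 / k1) / (1.0 / t1 - 1.0 / t2) * R_GAS / 1000.0)
    res = stats.linregress(1.0 / temps, np.log(kas))
    return float(-res.slope * R_GAS / 1000.0)


def gibbs_from_ka(ka: float, temperature: float) -> float:
    """ΔG° = -RT ln Ka, in kJ/mol."""
    if ka <= 0 or temperature <= 0:
        raise ValueError("ka and temperature must be positive")
    return float(-R_GAS * temperature * np.log(ka) / 1000.0)


def gibbs_from_enthalpy_entropy(dH: float, dS: float, temperature: float) -> float:
    """ΔG° = ΔH° - TΔS°, with ΔH° in kJ/mol and ΔS° in J mol^-1 K^-1."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(dH - temperature * dS / 1000.0)


def entropy_from_gibbs(dH: float, dG: float, temperature: float) -> float:
    """ΔS° = (ΔH° - ΔG°) × 1000 / T, in J mol^-1 K^-1."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float((dH - dG) * 1000.0 / temperature)


class BindingForce(str, Enum):
    HYDROPHOBIC = "hydrophobic"
    ELECTROSTATIC = "electrostatic"
    VDW_HBOND = "vdw_hbond"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class ForceCall:
    force: BindingForce
    signs: tuple[int, int]  # sign(dH), sign(dS)


def classify_forces(dH: float, dS: float,
                    zero_band: tuple[float, float] = (1.0, 5.0)) -> ForceCall:
    """Dominant noncovalent binding force from the signs of (ΔH°, ΔS°).

    Values inside the zero band (default ±1 kJ/mol for ΔH°, ±5 J/(mol K)
    for ΔS° — about the resolution of spectroscopic fits) are treated as
    indistinguishable from zero and yield ``ambiguous``; so does the
    remaining quadrant (ΔH° > 0, ΔS° < 0), which no single force explains.
    """
    band_h, band_s = zero_band
    sh = 0 if abs(dH) <= band_h else (1 if dH > 0 else -1)
    ss = 0 if abs(dS) <= band_s else (1 if dS > 0 else -1)
    if sh < 0 and ss < 0:
        force = BindingForce.VDW_HBOND
    elif sh > 0 and ss > 0:
        force = BindingForce.HYDROPHOBIC
    elif sh < 0 and ss > 0:
        force = BindingForce.ELECTROSTATIC
    else:
        force = BindingForce.AMBIGUOUS
    return ForceCall(force=force, signs=(sh, ss))


@dataclass(frozen=True)
class ThermoParams:
    """Full thermodynamic parameter set over a temperature series.

    Invariant (by construction): dG(T) = dH - T·dS(T)/1000 for every T.
    """

    dH: float  # kJ/mol, assumed temperature-independent
    temperatures: tuple[float, ...]  # K
    dS_by_T: tuple[float, ...]  # J mol^-1 K^-1
    dG_by_T: tuple[float, ...]  # kJ/mol
    force: ForceCall
    gas_constant: float = R_GAS

    def summary(self) -> str:
        lines = ["Binding thermodynamics", "======================",
                 f"dH  {self.dH:.6g} kJ/mol   force: {self.force.force.value}",
                 "T (K)    dS (J/mol/K)   dG (kJ/mol)"]
        for t, s, g in zip(self.temperatures, self.dS_by_T, self.dG_by_T):
            lines.append(f"{t:<8.6g} {s:<14.6g} {g:.6g}")
        return "\n".join(lines)


class VantHoffModel:
    """van't Hoff analysis of an association constant over temperature.

    By default ΔS° is evaluated per temperature as (ΔH° - ΔG°(T))/T with
    ΔG°(T) = -RT ln Ka(T), which preserves any mild temperature variation
    of the entropy term. With ``constant_entropy=True`` a single ΔS° is
    instead taken from the intercept of the ln Ka vs 1/T regression
    (intercept = ΔS°/R).
    """

    def __init__(self, ka_by_temperature, constant_entropy: bool = False,
                 zero_band: tuple[float, float] = (1.0, 5.0)):
        self.pairs = sorted((float(t), float(k)) for t, k in ka_by_temperature)
        if len(self.pairs) < 2:
            raise ValueError("need >= 2 temperatures")
        self.constant_entropy = constant_entropy
        self.zero_band = zero_band

    def fit(self) -> ThermoParams:
        dH = vant_hoff_enthalpy(self.pairs)
        temps = tuple(t for t, _ in self.pairs)
        dG = tuple(gibbs_from_ka(k, t) for t, k in self.pairs)
        if self.constant_entropy:
            x = 1.0 / np.array(temps)
            y = np.log([k for _, k in self.pairs])
            res = stats.linregress(x, y)
            dS_const = float(res.intercept * R_GAS)
            dS = tuple(dS_const for _ in temps)
            dG = tuple(gibbs_from_enthalpy_entropy(dH, dS_const, t) for t in temps)
        else:
            dS = tuple(entropy_from_gibbs(dH, g, t) for t, g in zip(temps, dG))
        force = classify_forces(dH, float(np.mean(dS)), self.zero_band)
        return ThermoParams(dH=dH, temperatures=temps, dS_by_T=dS,
                            dG_by_T=dG, force=force)
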