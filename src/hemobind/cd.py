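"""Circular dichroism: mean residue ellipticity and α-helix content.

Observed ellipticity (mdeg) is normalized to mean residue ellipticity

    MRE = θ_obs / (10 × C_P × n × l)        [deg cm² dmol⁻¹]

with C_P the molar protein concentration, n the residue count and l the
path length in cm. The α-helix fraction follows from the 208 nm reading,

    α-helix(%) = (-MRE₂₀₈ - 4000) / (33000 - 4000) × 100,

where -4000 is the MRE at 208 nm where the β-form and random-coil bands
cross, and -33000 the MRE of pure α-helix at 208 nm. Values outside
[0, 100]% are returned with a warning flag, never clipped — clipping
would hide unit mistakes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import CDSpectrum

__all__ = [
    "COIL_REF_MRE",
    "HELIX_REF_MRE",
    "mre",
    "mre_at",
    "helix_percent",
    "mre_from_helix_percent",
    "HelixEstimate",
    "estimate_helix",
    "helicity_change",
]

#: -MRE of the β/coil crossing at 208 nm, deg cm² dmol⁻¹.
COIL_REF_MRE = 4000.0
#: -MRE of pure α-helix at 208 nm, deg cm² dmol⁻¹.
HELIX_REF_MRE = 33000.0


class CoverageError(ValueError):
    """The spectrum does not cover the required wavelength."""


def mre(spectrum: CDSpectrum) -> np.ndarray:
    """Per-wavelength mean residue ellipticity, deg cm² dmol⁻¹."""
    if spectrum.protein_conc <= 0:
        raise ValueError("protein_conc must be positive")
    denom = 10.0 * spectrum.protein_conc * spectrum.n_residues * spectrum.path_length
    return spectrum.ellipticity_obs / denom


def mre_at(spectrum: CDSpectrum, wavelength: float = 208.0) -> float:
    """MRE linearly interpolated to one wavelength (default 208 nm)."""
    wl = spectrum.wavelengths
    if not (wl[0] <= wavelength <= wl[-1]):
        raise CoverageError(
            f"{wavelength} nm outside spectral range [{wl[0]}, {wl[-1]}] nm")
    return float(np.interp(wavelength, wl, mre(spectrum)))


def helix_percent(mre_208: float) -> tuple[float, bool]:
    """α-helix content (%) from MRE at 208 nm.

    Returns ``(percent, out_of_range)``; the flag is True when the result
    falls outside [0, 100]%.
    """
    pct = (-mre_208 - COIL_REF_MRE) / (HELIX_REF_MRE - COIL_REF_MRE) * 100.0
    return float(pct), bool(pct < 0.0 or pct > 100.0)


def mre_from_helix_percent(helix_pct: float) -> float:
    """Inverse of :func:`helix_percent`: MRE₂₀₈ for a given helix fraction."""
    return -(COIL_REF_MRE + (HELIX_REF_MRE - COIL_REF_MRE) * helix_pct / 100.0)


@dataclass(frozen=True)
class HelixEstimate:
    """α-helix estimate for one spectrum."""

    mre_208: float
    helix_percent: float
    out_of_range: bool
    constants: tuple[float, float] = (COIL_REF_MRE, HELIX_REF_MRE)


def estimate_helix(spectrum: CDSpectrum) -> HelixEstimate:
    """MRE₂₀₈ and α-helix content for one spectrum."""
    m208 = mre_at(spectrum, 208.0)
    pct, flag = helix_percent(m208)
    return HelixEstimate(mre_208=m208, helix_percent=pct, out_of_range=flag)


def helicity_change(spectrum_free: CDSpectrum,
                    spectrum_bound: CDSpectrum) -> tuple[float, float, float]:
    """(helix_free %, helix_bound %, delta percentage points) on ligand binding."""
    free = estimate_helix(spectrum_free)
    bound = estimate_helix(spectrum_bound)
    return (free.helix_percent, bound.helix_percent,
            bound.helix_percent - free.helix_percent)
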