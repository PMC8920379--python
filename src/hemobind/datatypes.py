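"""Shared domain containers and their validation rules.

Every pipeline stage exchanges data through the small frozen containers
defined here. Unit conventions are deliberately rigid: spectroscopy works
in mol/L, the erythrocyte assays and pharmacokinetics in μg/mL, and no
container ever converts units implicitly — conversions are explicit calls
in :mod:`hemobind.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "ValidationError",
    "TitrationPoint",
    "TitrationSeries",
    "CDSpectrum",
    "PKProfile",
    "Route",
    "PartitionRecord",
    "ODMeasurement",
    "LoadingMeasurement",
]


class ValidationError(ValueError):
    """A container constraint was violated."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class TitrationPoint:
    """One fluorescence titration observation.

    Parameters
    ----------
    quencher_conc : float
        Quencher (ligand) concentration, mol/L.
    f_observed : float
        Measured fluorescence intensity, arbitrary units, before any
        inner-filter correction.
    a_ex, a_em : float
        Sample absorbance at the excitation and emission wavelengths
        (dimensionless); used for the inner-filter correction.
    """

    quencher_conc: float
    f_observed: float
    a_ex: float = 0.0
    a_em: float = 0.0

    def __post_init__(self) -> None:
        _require(np.isfinite(self.quencher_conc) and self.quencher_conc >= 0,
                 f"quencher_conc must be >= 0, got {self.quencher_conc}")
        _require(np.isfinite(self.f_observed) and self.f_observed >= 0,
                 f"f_observed must be >= 0, got {self.f_observed}")
        _require(self.a_ex >= 0, f"a_ex must be >= 0, got {self.a_ex}")
        _require(self.a_em >= 0, f"a_em must be >= 0, got {self.a_em}")


@dataclass(frozen=True)
class TitrationSeries:
    """An ordered fluorescence titration at one temperature.

    The zero-quencher point is mandatory: it defines F0 so that the
    inner-filter correction and every downstream fit share one provenance.
    """

    points: tuple[TitrationPoint, ...]
    temperature: float  # K
    protein_conc: float  # mol/L
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        _require(len(self.points) >= 2, "need at least 2 titration points")
        _require(self.temperature > 0, "temperature must be positive (kelvin)")
        _require(self.protein_conc > 0, "protein_conc must be positive")
        q = self.quencher_conc
        _require(np.all(np.diff(q) > 0),
                 "quencher_conc must be strictly increasing")
        n_zero = int(np.sum(q == 0))
        _require(n_zero == 1,
                 f"exactly one zero-quencher point required (found {n_zero})")

    @property
    def quencher_conc(self) -> np.ndarray:
        return np.array([p.quencher_conc for p in self.points])

    @property
    def f_observed(self) -> np.ndarray:
        return np.array([p.f_observed for p in self.points])

    @property
    def a_ex(self) -> np.ndarray:
        return np.array([p.a_ex for p in self.points])

    @property
    def a_em(self) -> np.ndarray:
        return np.array([p.a_em for p in self.points])

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class CDSpectrum:
    """A far-UV circular dichroism spectrum with protein metadata.

    ``n_residues`` defaults to 574, the residue count of the bovine
    hemoglobin tetramer used as the reference carrier protein.
    """

    wavelengths: np.ndarray  # nm, ascending
    ellipticity_obs: np.ndarray  # mdeg
    protein_conc: float  # mol/L
    n_residues: int = 574
    path_length: float = 1.0  # cm
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        el = np.asarray(self.ellipticity_obs, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "ellipticity_obs", el)
        _require(wl.ndim == 1 and wl.shape == el.shape,
                 "wavelengths and ellipticity_obs must be equal-length 1-D")
        _require(len(wl) >= 2, "need at least 2 spectral points")
        _require(np.all(np.diff(wl) > 0), "wavelengths must be ascending")
        _require(self.protein_conc > 0, "protein_conc must be positive")
        _require(self.n_residues > 0, "n_residues must be positive")
        _require(self.path_length > 0, "path_length must be positive")


class Route(str, Enum):
    """Administration route of a PK profile."""

    INTRAVENOUS = "intravenous"
    ORAL = "oral"


@dataclass(frozen=True)
class PKProfile:
    """A plasma concentration-time profile with dose and route.

    times in hours (ascending, unique, first >= 0); concentrations in
    μg/mL (>= 0); dose in mg/kg.
    """

    times: np.ndarray
    concentrations: np.ndarray
    dose: float
    route: Route

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "route", Route(self.route))
        _require(t.ndim == 1 and t.shape == c.shape,
                 "times and concentrations must be equal-length 1-D")
        _require(len(t) >= 1 and t[0] >= 0, "times must start at >= 0")
        _require(np.all(np.diff(t) > 0),
                 "times must be strictly increasing (no duplicates)")
        _require(np.all(c >= 0), "concentrations must be >= 0")
        _require(self.dose > 0, "dose must be positive")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class PartitionRecord:
    """One animal-timepoint pair of erythrocyte and plasma concentrations (μM).

    Either concentration may be ``None`` to flag a missing measurement.
    """

    subject_id: str
    time_min: float
    c_erythrocyte: float | None
    c_plasma: float | None

    def __post_init__(self) -> None:
        for name in ("c_erythrocyte", "c_plasma"):
            v = getattr(self, name)
            if v is not None:
                _require(np.isfinite(v) and v >= 0,
                         f"{name} must be >= 0 or None, got {v}")


@dataclass(frozen=True)
class ODMeasurement:
    """Microplate absorbances (545 nm) for one hemolysis condition.

    baseline_od is the saline (no-lysis) control, full_lysis_od the
    distilled-water (complete-lysis) control.
    """

    sample_od: float
    baseline_od: float
    full_lysis_od: float

    def __post_init__(self) -> None:
        _require(self.sample_od >= 0 and self.baseline_od >= 0
                 and self.full_lysis_od >= 0, "ODs must be >= 0")
        _require(self.full_lysis_od > self.baseline_od,
                 "full-lysis control OD must exceed the baseline control OD")


@dataclass(frozen=True)
class LoadingMeasurement:
    """Drug concentration in the incubation system before and after loading (μg/mL)."""

    conc_original: float
    conc_post: float

    def __post_init__(self) -> None:
        _require(self.conc_original > 0, "conc_original must be positive")
        _require(self.conc_post >= 0, "conc_post must be >= 0")
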