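"""Seeded synthetic-data generators with recorded ground truth.

Each generator emulates the data-generating model one analysis stage
assumes, so every fit in the package can be verified by parameter
recovery without any external data:

* quenching titrations obey F0/F = 1 + Ksv[Q], attenuated per point by
  the inner filter factor 10^(-(A_ex+A_em)/2);
* binding titrations obey (F0-F)/F = Ka [Q]^n;
* association constants over temperature follow the van't Hoff form
  Ka(T) = exp(-(ΔH°·1000 - T·ΔS°)/(R·T));
* CD spectra are smooth two-band (208/222 nm) curves whose MRE at 208 nm
  encodes a set α-helix fraction;
* hemolysis plates follow a Hill (sigmoidal) concentration-response;
* PK profiles are one-compartment (i.v. bolus exponential, oral Bateman);
* partition cohorts are lognormal with optional zero-inflated plasma.

Noise is multiplicative lognormal by default (intensities and
concentrations are positive); additive Gaussian is available for
robustness checks. Reproducibility contract: the same (generator name,
parameters, seed) always yields bit-identical output. Each generator
draws from its own substream — the child seed is
``SeedSequence([seed, crc32(generator_name)])`` — so adding a generator
never perturbs existing fixtures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .cd import mre_from_helix_percent
from .datatypes import (
    CDSpectrum,
    ODMeasurement,
    PartitionRecord,
    PKProfile,
    Route,
    TitrationPoint,
    TitrationSeries,
    ValidationError,
)
from .thermo import R_GAS

__all__ = [
    "GroundTruth",
    "gen_quenching_titration",
    "gen_binding_titration",
    "gen_temperature_series",
    "gen_cd_spectrum",
    "gen_pk_profile",
    "gen_hemolysis_plate",
    "gen_partition_cohort",
    "DEFAULT_Q_GRID",
    "DEFAULT_TEMPERATURES",
]

#: Quencher grid of the reference titration design: 0 to 1.75e-5 mol/L
#: in 0.25e-5 mol/L increments.
DEFAULT_Q_GRID = tuple(0.25e-5 * i for i in range(8))

#: Temperatures (K) of the reference three-temperature quenching study.
DEFAULT_TEMPERATURES = (293.0, 298.0, 310.0)


@dataclass(frozen=True)
class GroundTruth:
    """Provenance record attached to every generated dataset."""

    generator_name: str
    parameters: dict = field(default_factory=dict)
    seed: int | None = None
    noise_model: str = "none"  # none | multiplicative_lognormal | additive_gaussian
    noise_scale: float = 0.0


def _rng(name: str, seed: int | None) -> np.random.Generator:
    if seed is None:
        seed = 0
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def _apply_noise(values: np.ndarray, noise: str, scale: float,
                 rng: np.random.Generator) -> np.ndarray:
    if noise == "none" or scale == 0:
        return values
    if noise == "multiplicative_lognormal":
        sigma = np.sqrt(np.log1p(scale**2))  # CV -> lognormal sigma
        factors = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma,
                                size=values.shape)
        return values * factors
    if noise == "additive_gaussian":
        return np.clip(values + rng.normal(0.0, scale, size=values.shape),
                       0.0, None)
    raise ValueError(f"unknown noise model {noise!r}")


def gen_quenching_titration(ksv: float, f0: float = 1000.0,
                            q_grid=DEFAULT_Q_GRID,
                            inner_filter_a=None,
                            temperature: float = 298.0,
                            protein_conc: float = 2e-6,
                            noise: str = "none", noise_scale: float = 0.0,
                            seed: int | None = None) -> TitrationSeries:
    """Titration obeying the Stern-Volmer law with optional inner filtering.

    ``inner_filter_a`` is a per-point sequence of (a_ex, a_em) pairs; the
    observed intensity is the true intensity attenuated by
    10^(-(a_ex+a_em)/2), so the correction step recovers it exactly.
    """
    if ksv < 0:
        raise ValueError("ksv must be >= 0")
    q = np.asarray(sorted(q_grid), dtype=float)
    if 0.0 not in q:
        raise ValidationError("q_grid must include 0 (defines F0)")
    if inner_filter_a is None:
        inner_filter_a = [(0.0, 0.0)] * len(q)
    rng = _rng("quenching_titration", seed)
    f_true = f0 / (1.0 + ksv * q)
    f_true = _apply_noise(f_true, noise, noise_scale, rng)
    points = tuple(
        TitrationPoint(qi, fi * 10.0 ** (-(aex + aem) / 2.0), aex, aem)
        for qi, fi, (aex, aem) in zip(q, f_true, inner_filter_a))
    truth = GroundTruth("quenching_titration",
                        {"ksv": ksv, "f0": f0}, seed, noise, noise_scale)
    return TitrationSeries(points=points, temperature=temperature,
                           protein_conc=protein_conc,
                           meta={"ground_truth": truth})


def gen_binding_titration(ka: float, n_sites: float, f0: float = 1000.0,
                          q_grid=DEFAULT_Q_GRID,
                          temperature: float = 298.0,
                          protein_conc: float = 2e-6,
                          noise: str = "none", noise_scale: float = 0.0,
                          seed: int | None = None) -> TitrationSeries:
    """Titration obeying the one-set-of-sites law (F0-F)/F = Ka [Q]^n."""
    if ka <= 0 or n_sites <= 0:
        raise ValueError("ka and n_sites must be positive")
    q = np.asarray(sorted(q_grid), dtype=float)
    if 0.0 not in q:
        raise ValidationError("q_grid must include 0 (defines F0)")
    rng = _rng("binding_titration", seed)
    with np.errstate(divide="ignore"):
        f_true = np.where(q > 0, f0 / (1.0 + ka * q**n_sites), f0)
    f_true = _apply_noise(f_true, noise, noise_scale, rng)
    points = tuple(TitrationPoint(qi, fi) for qi, fi in zip(q, f_true))
    truth = GroundTruth("binding_titration",
                        {"ka": ka, "n_sites": n_sites, "f0": f0},
                        seed, noise, noise_scale)
    return TitrationSeries(points=points, temperature=temperature,
                           protein_conc=protein_conc,
                           meta={"ground_truth": truth})


def gen_temperature_series(dH: float, dS: float,
                           temperatures=DEFAULT_TEMPERATURES):
    """(T, Ka) pairs with Ka(T) = exp(-(ΔH°·1000 - T·ΔS°)/(R·T)).

    ΔH° in kJ/mol, ΔS° in J mol^-1 K^-1. Deterministic (no noise): the
    van't Hoff stage is an exact-algebra recovery target.
    """
    temps = [float(t) for t in temperatures]
    if len(set(temps)) != len(temps) or any(t <= 0 for t in temps):
        raise ValueError("temperatures must be distinct and positive")
    return [(t, float(np.exp(-(dH * 1000.0 - t * dS) / (R_GAS * t))))
            for t in temps]


def gen_cd_spectrum(helix_fraction: float, protein_conc: float = 5e-8,
                    n_residues: int = 574,
                    wavelength_grid=None, path_length: float = 1.0,
                    noise: str = "none", noise_scale: float = 0.0,
                    seed: int | None = None) -> CDSpectrum:
    """Smooth far-UV CD spectrum with a set α-helix fraction.

    The spectrum is a fixed two-negative-band shape (minima at 208 and
    222 nm) scaled so that the interpolated MRE at 208 nm equals
    -(4000 + 290·helix_fraction) before noise.
    """
    if not 0.0 <= helix_fraction <= 100.0:
        raise ValueError("helix_fraction must be in [0, 100]")
    if wavelength_grid is None:
        wavelength_grid = np.arange(200.0, 260.5, 0.5)
    wl = np.asarray(wavelength_grid, dtype=float)
    if not (wl.min() <= 208.0 <= wl.max()):
        raise ValidationError("wavelength grid must cover 208 nm")
    # two-band α-helix-like shape, normalized to 1 at 208 nm
    shape = (np.exp(-((wl - 208.0) ** 2) / (2 * 6.0**2))
             + 0.9 * np.exp(-((wl - 222.0) ** 2) / (2 * 7.0**2)))
    shape = shape / np.interp(208.0, wl, shape)
    target_mre_208 = mre_from_helix_percent(helix_fraction)
    mre_curve = target_mre_208 * shape
    ellipticity = mre_curve * 10.0 * protein_conc * n_residues * path_length
    rng = _rng("cd_spectrum", seed)
    if noise != "none" and noise_scale > 0:
        # additive in mdeg regardless of sign; lognormal would flip signs
        ellipticity = ellipticity + rng.normal(0.0, noise_scale, wl.shape)
    truth = GroundTruth("cd_spectrum",
                        {"helix_fraction": helix_fraction,
                         "mre_208": target_mre_208}, seed, noise, noise_scale)
    return CDSpectrum(wavelengths=wl, ellipticity_obs=ellipticity,
                      protein_conc=protein_conc, n_residues=n_residues,
                      path_length=path_length, meta={"ground_truth": truth})


def gen_pk_profile(model: str, params: dict, times, dose: float,
                   noise_cv: float = 0.0,
                   seed: int | None = None) -> PKProfile:
    """One-compartment concentration-time profile.

    model="iv_1cpt": C(t) = C0 e^(-ke t), params {"c0", "ke"}.
    model="oral_1cpt": Bateman, params {"f_dose_over_v", "ka", "ke"} where
    f_dose_over_v = F·dose/V in μg/mL; the ka = ke limit uses the
    continuous limit A·ke·t·e^(-ke t).
    Multiplicative lognormal noise with coefficient of variation noise_cv.
    """
    t = np.asarray(sorted(times), dtype=float)
    if np.any(t < 0):
        raise ValidationError("times must be >= 0")
    ke = float(params["ke"])
    if ke <= 0:
        raise ValueError("ke must be positive")
    if model == "iv_1cpt":
        c0 = float(params["c0"])
        conc = c0 * np.exp(-ke * t)
        route = Route.INTRAVENOUS
    elif model == "oral_1cpt":
        amp = float(params["f_dose_over_v"])
        ka = float(params["ka"])
        if ka <= 0:
            raise ValueError("ka must be positive")
        if np.isclose(ka, ke):
            conc = amp * ke * t * np.exp(-ke * t)
        else:
            conc = amp * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
        route = Route.ORAL
    else:
        raise ValueError(f"unknown PK model {model!r}")
    rng = _rng("pk_profile", seed)
    conc = _apply_noise(conc, "multiplicative_lognormal" if noise_cv else "none",
                        noise_cv, rng)
    return PKProfile(times=t, concentrations=conc, dose=dose, route=route)


def gen_hemolysis_plate(conc_grid, ec50: float = 1.45, hill: float = 18.0,
                        od_baseline: float = 0.08, od_full: float = 1.10,
                        noise: str = "none", noise_scale: float = 0.0,
                        seed: int | None = None):
    """Hill-response hemolysis plate.

    fraction lysed = c^h / (ec50^h + c^h); sample OD interpolates between
    the saline-control and water-control ODs. The defaults (EC50 1.45
    mg/mL, Hill 18) reproduce the reference qualitative pattern: no lysis
    at <= 1.0 mg/mL, ~58% at 1.5, ~90% at 1.6 mg/mL.

    Returns a list of (condition_label, ODMeasurement) pairs.
    """
    if od_full <= od_baseline:
        raise ValidationError("od_full must exceed od_baseline")
    if hill <= 0 or ec50 <= 0:
        raise ValueError("ec50 and hill must be positive")
    rng = _rng("hemolysis_plate", seed)
    out = []
    for c in conc_grid:
        c = float(c)
        frac = 0.0 if c == 0 else c**hill / (ec50**hill + c**hill)
        od = od_baseline + frac * (od_full - od_baseline)
        od = float(_apply_noise(np.array([od]), noise, noise_scale, rng)[0])
        out.append((f"{c:g} mg/mL",
                    ODMeasurement(sample_od=od, baseline_od=od_baseline,
                                  full_lysis_od=od_full)))
    return out


def gen_partition_cohort(n_subjects: int = 6, times=(5.0, 30.0, 120.0),
                         mean_ce: float = 0.5, mean_cp: float = 0.3,
                         zero_inflation: float = 0.3, cv: float = 0.8,
                         seed: int | None = None) -> list[PartitionRecord]:
    """Cohort of erythrocyte/plasma records with zero-inflated plasma.

    Concentrations are lognormal with the requested means and CV; each
    plasma value is independently set to 0 (below detection) with
    probability ``zero_inflation``, exercising the infinite-ratio path.
    """
    if not 0.0 <= zero_inflation <= 1.0:
        raise ValueError("zero_inflation must be a probability")
    rng = _rng("partition_cohort", seed)
    sigma = np.sqrt(np.log1p(cv**2))
    records = []
    for t in times:
        for subj in range(1, n_subjects + 1):
            ce = float(rng.lognormal(np.log(mean_ce) - sigma**2 / 2, sigma))
            cp = float(rng.lognormal(np.log(mean_cp) - sigma**2 / 2, sigma))
            if rng.random() < zero_inflation:
                cp = 0.0
            records.append(PartitionRecord(subject_id=str(subj),
                                           time_min=float(t),
                                           c_erythrocyte=ce, c_plasma=cp))
    return records
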