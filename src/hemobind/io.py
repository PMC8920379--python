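"""CSV readers/writers and explicit unit conversions.

CSV is the single interchange format. Column names are fixed and
case-sensitive so fixtures are bit-reproducible:

======================  =====================================================
schema                  columns
======================  =====================================================
titration               quencher_conc_M, fluorescence, a_ex, a_em
cd_spectrum             wavelength_nm, ellipticity_mdeg
pk_profile              time_h, conc_ug_per_ml
partition               subject_id, time_min, c_ery_uM, c_plasma_uM
od_plate                condition, sample_od, baseline_od, full_lysis_od
======================  =====================================================

Series-level metadata (temperature, protein concentration, dose, route, ...)
travels in ``# key = value`` comment lines at the top of the file, so one
file is self-contained and round-trips exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CDSpectrum,
    PartitionRecord,
    PKProfile,
    Route,
    TitrationPoint,
    TitrationSeries,
    ValidationError,
)

__all__ = [
    "SchemaError",
    "read_titration_csv",
    "write_titration_csv",
    "read_cd_csv",
    "write_cd_csv",
    "read_pk_csv",
    "write_pk_csv",
    "read_partition_csv",
    "write_partition_csv",
    "convert_mass_to_molar",
    "convert_molar_to_mass",
]

_FLOAT_FMT = "%.12g"  # >= 10 significant digits on every numeric field


class SchemaError(ValueError):
    """A CSV file does not match its fixed schema."""


def _read_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
    return meta


def _read_table(path: Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except ValueError as exc:
        raise SchemaError(f"{path}: cannot parse CSV: {exc}") from exc
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    return df


def _numeric(df: pd.DataFrame, cols: list[str], path: Path) -> pd.DataFrame:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} "
                f"in column '{col}' at data row {row}")
        df[col] = coerced
    return df


def _write_with_meta(df: pd.DataFrame, meta: dict, path: Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key} = {val}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)
    return path


# ---------------------------------------------------------------------------
# titration

def read_titration_csv(path) -> TitrationSeries:
    """Read a fluorescence titration CSV into a validated :class:`TitrationSeries`.

    Rows are re-ordered to ascending quencher concentration; metadata lines
    must supply ``temperature_K`` and ``protein_conc_M``.
    """
    path = Path(path)
    meta = _read_meta(path)
    for key in ("temperature_K", "protein_conc_M"):
        if key not in meta:
            raise SchemaError(f"{path}: missing metadata line '# {key} = ...'")
    df = _read_table(path, ["quencher_conc_M", "fluorescence", "a_ex", "a_em"])
    df = _numeric(df, ["quencher_conc_M", "fluorescence", "a_ex", "a_em"], path)
    df = df.sort_values("quencher_conc_M", kind="stable").reset_index(drop=True)
    if not (df["quencher_conc_M"] == 0).any():
        raise ValidationError(f"{path}: no zero-quencher (F0) row present")
    points = tuple(
        TitrationPoint(row.quencher_conc_M, row.fluorescence, row.a_ex, row.a_em)
        for row in df.itertuples())
    extra = {k: v for k, v in meta.items()
             if k not in ("temperature_K", "protein_conc_M")}
    return TitrationSeries(points=points,
                           temperature=float(meta["temperature_K"]),
                           protein_conc=float(meta["protein_conc_M"]),
                           meta=extra)


def write_titration_csv(series: TitrationSeries, path) -> Path:
    """Write a :class:`TitrationSeries` so that re-reading reproduces it exactly."""
    df = pd.DataFrame({
        "quencher_conc_M": series.quencher_conc,
        "fluorescence": series.f_observed,
        "a_ex": series.a_ex,
        "a_em": series.a_em,
    })
    meta = {"temperature_K": repr(series.temperature),
            "protein_conc_M": repr(series.protein_conc), **series.meta}
    return _write_with_meta(df, meta, path)


# ---------------------------------------------------------------------------
# CD spectra

def read_cd_csv(path) -> CDSpectrum:
    path = Path(path)
    meta = _read_meta(path)
    if "protein_conc_M" not in meta:
        raise SchemaError(f"{path}: missing metadata line '# protein_conc_M = ...'")
    df = _read_table(path, ["wavelength_nm", "ellipticity_mdeg"])
    df = _numeric(df, ["wavelength_nm", "ellipticity_mdeg"], path)
    df = df.sort_values("wavelength_nm", kind="stable")
    extra = {k: v for k, v in meta.items()
             if k not in ("protein_conc_M", "n_residues", "path_length_cm")}
    return CDSpectrum(
        wavelengths=df["wavelength_nm"].to_numpy(),
        ellipticity_obs=df["ellipticity_mdeg"].to_numpy(),
        protein_conc=float(meta["protein_conc_M"]),
        n_residues=int(meta.get("n_residues", 574)),
        path_length=float(meta.get("path_length_cm", 1.0)),
        meta=extra)


def write_cd_csv(spectrum: CDSpectrum, path) -> Path:
    df = pd.DataFrame({"wavelength_nm": spectrum.wavelengths,
                       "ellipticity_mdeg": spectrum.ellipticity_obs})
    meta = {"protein_conc_M": repr(spectrum.protein_conc),
            "n_residues": spectrum.n_residues,
            "path_length_cm": repr(spectrum.path_length), **spectrum.meta}
    return _write_with_meta(df, meta, path)


# ---------------------------------------------------------------------------
# PK profiles

def read_pk_csv(path) -> PKProfile:
    path = Path(path)
    meta = _read_meta(path)
    for key in ("dose_mg_per_kg", "route"):
        if key not in meta:
            raise SchemaError(f"{path}: missing metadata line '# {key} = ...'")
    df = _read_table(path, ["time_h", "conc_ug_per_ml"])
    df = _numeric(df, ["time_h", "conc_ug_per_ml"], path)
    df = df.sort_values("time_h", kind="stable")
    return PKProfile(times=df["time_h"].to_numpy(),
                     concentrations=df["conc_ug_per_ml"].to_numpy(),
                     dose=float(meta["dose_mg_per_kg"]),
                     route=Route(meta["route"]))


def write_pk_csv(profile: PKProfile, path) -> Path:
    df = pd.DataFrame({"time_h": profile.times,
                       "conc_ug_per_ml": profile.concentrations})
    meta = {"dose_mg_per_kg": repr(profile.dose), "route": profile.route.value}
    return _write_with_meta(df, meta, path)


# ---------------------------------------------------------------------------
# partition records

def read_partition_csv(path) -> list[PartitionRecord]:
    path = Path(path)
    df = _read_table(path, ["subject_id", "time_min", "c_ery_uM", "c_plasma_uM"])
    records = []
    for i, row in df.iterrows():
        def opt(v):
            if pd.isna(v) or (isinstance(v, str) and v.strip() in ("", "-", "–")):
                return None
            return float(v)
        try:
            records.append(PartitionRecord(
                subject_id=str(row["subject_id"]),
                time_min=float(row["time_min"]),
                c_erythrocyte=opt(row["c_ery_uM"]),
                c_plasma=opt(row["c_plasma_uM"])))
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: bad value at data row {i}: {exc}") from exc
    return records


def write_partition_csv(records: list[PartitionRecord], path) -> Path:
    df = pd.DataFrame({
        "subject_id": [r.subject_id for r in records],
        "time_min": [r.time_min for r in records],
        "c_ery_uM": [r.c_erythrocyte for r in records],
        "c_plasma_uM": [r.c_plasma for r in records],
    })
    return _write_with_meta(df, {}, path)


# ---------------------------------------------------------------------------
# unit conversions

def convert_mass_to_molar(conc_mass: float, molar_mass: float) -> float:
    """μg/mL → mol/L.

    1 μg/mL = 1 mg/L, so molarity = conc_mass / (1000 × molar_mass).
    """
    if conc_mass <= 0 or molar_mass <= 0:
        raise ValueError("conc_mass and molar_mass must be positive")
    return conc_mass / (1000.0 * molar_mass)


def convert_molar_to_mass(conc_molar: float, molar_mass: float) -> float:
    """mol/L → μg/mL; exact inverse of :func:`convert_mass_to_molar`."""
    if conc_molar <= 0 or molar_mass <= 0:
        raise ValueError("conc_molar and molar_mass must be positive")
    return conc_molar * 1000.0 * molar_mass
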