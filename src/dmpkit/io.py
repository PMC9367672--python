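"""CSV schemas, readers/writers and input validation for the pipeline.

All interchange is plain CSV. One reader per stage input, one writer per
stage report; `validate_inputs` checks files against their schema with
row-level diagnostics before anything is fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .ivive import SpeciesPhysiology
from .kinetics import KineticDataset
from .nca import ConcentrationTimeProfile
from .screening import ND, InhibitionRecord, PeakAreaMatrix
from .stability import DepletionSeries, percent_remaining

SCHEMAS = {
    "kinetics": {
        "required": ["enzyme_source", "metabolite_id", "concentration_uM", "velocity", "protein_basis"],
        "numeric": {"concentration_uM": (0.0, None), "velocity": (0.0, None)},
    },
    "depletion": {
        "required": ["enzyme_source", "reaction_system", "time_min"],
        "numeric": {"time_min": (0.0, None)},
    },
    "physiology": {
        "required": ["species", "liver_weight_g_per_kg", "microsomal_protein_mg_per_g", "qh_ml_per_min_kg"],
        "numeric": {
            "liver_weight_g_per_kg": (0.0, None),
            "microsomal_protein_mg_per_g": (0.0, None),
            "qh_ml_per_min_kg": (0.0, None),
        },
    },
    "plasma": {
        "required": ["subject_id", "time_h", "conc_ug_per_ml"],
        "numeric": {"time_h": (0.0, None), "conc_ug_per_ml": (0.0, None)},
    },
    "peak_areas": {
        "required": ["species", "metabolite", "area"],
        "numeric": {},  # area admits the N.D. marker, checked separately
    },
    "inhibition": {
        "required": ["inhibitor", "isoform", "metabolite_id", "control_area", "inhibited_area"],
        "numeric": {"control_area": (0.0, None), "inhibited_area": (0.0, None)},
    },
    "rhcyp": {
        "required": ["isoform", "metabolite", "area"],
        "numeric": {"area": (0.0, None)},
    },
}


@dataclass
class FileValidation:
    path: str
    ok: bool
    errors: list = field(default_factory=list)  # (row_index or None, message)


def validate_file(path: str | Path, schema_name: str) -> FileValidation:
    """Check one CSV against a named schema; row indices are 0-based data rows."""
    if schema_name not in SCHEMAS:
        raise ConfigurationError(f"unknown schema {schema_name!r}")
    schema = SCHEMAS[schema_name]
    result = FileValidation(path=str(path), ok=True)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # unreadable or malformed file
        result.ok = False
        result.errors.append((None, f"unreadable: {exc}"))
        return result
    for col in schema["required"]:
        if col not in df.columns:
            result.ok = False
            result.errors.append((None, f"missing required column {col!r}"))
    if not result.ok:
        return result
    for col, (lo, hi) in schema["numeric"].items():
        vals = pd.to_numeric(df[col], errors="coerce")
        for idx in df.index[vals.isna() & df[col].notna()]:
            result.ok = False
            result.errors.append((int(idx), f"{col} is not numeric: {df.at[idx, col]!r}"))
        if lo is not None:
            for idx in df.index[vals < lo]:
                result.ok = False
                result.errors.append((int(idx), f"{col} below {lo}: {vals[idx]}"))
        if hi is not None:
            for idx in df.index[vals > hi]:
                result.ok = False
                result.errors.append((int(idx), f"{col} above {hi}: {vals[idx]}"))
    return result


def validate_inputs(paths: dict[str, str | Path]) -> dict[str, FileValidation]:
    """Validate a mapping of schema name -> CSV path."""
    return {name: validate_file(p, name) for name, p in paths.items()}


# ---------------------------------------------------------------- readers

def read_kinetics_csv(path: str | Path) -> list[KineticDataset]:
    """One KineticDataset per (enzyme_source, metabolite_id) group."""
    df = pd.read_csv(path)
    out = []
    for (src, met), grp in df.groupby(["enzyme_source", "metabolite_id"], sort=True):
        basis = grp["protein_basis"].iloc[0]
        out.append(
            KineticDataset(
                enzyme_source=str(src),
                metabolite_id=str(met),
                concentrations=grp["concentration_uM"].to_numpy(float),
                velocities=grp["velocity"].to_numpy(float),
                protein_basis=str(basis),
            )
        )
    return out


def read_depletion_csv(path: str | Path, value_column: str = "percent_remaining") -> list[DepletionSeries]:
    """One DepletionSeries per (enzyme_source, reaction_system) group.

    ``value_column`` selects 'percent_remaining' (pre-normalized) or
    'amount' (raw parent amounts, normalized here).
    """
    df = pd.read_csv(path)
    if value_column not in df.columns:
        raise ConfigurationError(f"depletion CSV lacks column {value_column!r}")
    out = []
    for (src, system), grp in df.groupby(["enzyme_source", "reaction_system"], sort=True):
        grp = grp.sort_values("time_min")
        t = grp["time_min"].to_numpy(float)
        vals = grp[value_column].to_numpy(float)
        if value_column == "amount":
            out.append(percent_remaining(t, vals, enzyme_source=str(src), reaction_system=str(system)))
        else:
            out.append(
                DepletionSeries(
                    enzyme_source=str(src),
                    reaction_system=str(system),
                    times=t,
                    percent_remaining=vals,
                )
            )
    return out


def read_physiology_csv(path: str | Path) -> dict[str, SpeciesPhysiology]:
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        out[str(row["species"])] = SpeciesPhysiology(
            species=str(row["species"]),
            liver_weight=float(row["liver_weight_g_per_kg"]),
            microsomal_protein=float(row["microsomal_protein_mg_per_g"]),
            qh=float(row["qh_ml_per_min_kg"]),
        )
    return out


def read_plasma_csv(path: str | Path) -> list[ConcentrationTimeProfile]:
    df = pd.read_csv(path)
    out = []
    for subject, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("time_h")
        out.append(
            ConcentrationTimeProfile(
                times=grp["time_h"].to_numpy(float),
                concentrations=grp["conc_ug_per_ml"].to_numpy(float),
                subject_id=str(subject),
            )
        )
    return out


def read_peak_areas_csv(path: str | Path) -> PeakAreaMatrix:
    """Long-format species/metabolite/area CSV; 'N.D.' (or blank) = not detected."""
    df = pd.read_csv(path, dtype={"area": str})
    df["area"] = df["area"].replace({ND: np.nan, "ND": np.nan, "": np.nan}).astype(float)
    wide = df.pivot(index="species", columns="metabolite", values="area")
    return PeakAreaMatrix(areas=wide)


def read_inhibition_csv(path: str | Path) -> list[InhibitionRecord]:
    df = pd.read_csv(path)
    return [
        InhibitionRecord(
            inhibitor=str(r["inhibitor"]),
            target_isoform=str(r["isoform"]),
            metabolite_id=str(r["metabolite_id"]),
            activity_control=float(r["control_area"]),
            activity_inhibited=float(r["inhibited_area"]),
        )
        for _, r in df.iterrows()
    ]


def read_rhcyp_csv(path: str | Path) -> dict[str, dict[str, float]]:
    """Per-metabolite isoform activity maps: {metabolite: {isoform: area}}."""
    df = pd.read_csv(path)
    out: dict[str, dict[str, float]] = {}
    for _, r in df.iterrows():
        out.setdefault(str(r["metabolite"]), {})[str(r["isoform"])] = float(r["area"])
    return out


# ---------------------------------------------------------------- writers

def write_kinetics_dataset_csv(datasets, path: str | Path) -> None:
    rows = []
    for ds in datasets:
        for s, v in zip(ds.concentrations, ds.velocities):
            rows.append(
                {
                    "enzyme_source": ds.enzyme_source,
                    "metabolite_id": ds.metabolite_id,
                    "concentration_uM": s,
                    "velocity": v,
                    "protein_basis": ds.protein_basis,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def fit_report_frame(fits) -> pd.DataFrame:
    """One row per fitted (enzyme_source, model) with parameters, SEs, diagnostics."""
    rows = []
    for f in fits:
        row = {
            "enzyme_source": f.enzyme_source,
            "metabolite_id": f.metabolite_id,
            "model": f.model,
            "protein_basis": f.protein_basis,
            "n_points": f.n_points,
            "rss": f.rss,
            "aicc": f.aicc,
            "clint": f.clint,
        }
        for name, value in f.params.items():
            row[name] = value
            row[f"{name}_se"] = f.param_se[name]
        rows.append(row)
    return pd.DataFrame(rows)


def write_depletion_csv(series_list, path: str | Path) -> None:
    rows = []
    for s in series_list:
        for t, p in zip(s.times, s.percent_remaining):
            rows.append(
                {
                    "enzyme_source": s.enzyme_source,
                    "reaction_system": s.reaction_system,
                    "time_min": t,
                    "percent_remaining": p,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_plasma_csv(profiles, path: str | Path) -> None:
    rows = []
    for p in profiles:
        for t, c in zip(p.times, p.concentrations):
            rows.append({"subject_id": p.subject_id, "time_h": t, "conc_ug_per_ml": c})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_peak_areas_csv(matrix: PeakAreaMatrix, path: str | Path) -> None:
    long = matrix.areas.stack(future_stack=True).rename("area").reset_index()
    long.columns = ["species", "metabolite", "area"]
    long["area"] = long["area"].map(lambda x: ND if pd.isna(x) else repr(float(x)))
    long.to_csv(path, index=False)
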