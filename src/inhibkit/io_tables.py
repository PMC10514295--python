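"""CSV readers for the assay, velocity, titration and composition schemas,
plus unit normalization helpers.

All tables are comma-separated UTF-8 with a mandatory header and '.'
decimal separator.  Headers are matched case-insensitively; extra columns
are ignored.  Temperatures are accepted in Celsius and converted with an
integer 273 offset (so 20 C maps to 293 K), keeping arithmetic parity with
the conventional rounded mapping used in the source tables this package
consumes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .binding import FluorescenceTitration
from .cd_structure import SecondaryStructureComposition
from .dose_response import AssayRecord, DoseResponse
from .errors import EmptyInputError, SchemaError
from .kinetics import VelocityDataset

#: Celsius -> Kelvin offset (integer, matching 20 C -> 293 K).
KELVIN_OFFSET = 273

SCHEMAS: dict[str, dict[str, list[str]]] = {
    "assay": {
        "required": ["compound_id", "conc_um", "replicate", "abs_control", "abs_sample"],
        "optional": [],
    },
    "velocity": {
        "required": ["inhibitor_um", "substrate_mm", "velocity"],
        "optional": [],
    },
    "titration": {
        "required": ["temperature_c", "dt_um", "fluorescence"],
        "optional": ["background"],
    },
    "composition": {
        "required": ["label", "helix_pct", "turn_pct", "coil_pct"],
        "optional": [],
    },
}


def celsius_to_kelvin(t_C: float) -> float:
    """Celsius to Kelvin with the integer 273 offset (20 C -> 293 K)."""
    return t_C + KELVIN_OFFSET


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Returns a DataFrame with lower-cased column names restricted to the
    schema's columns; the index preserves file row numbers (header = row 1)
    for error messages.  Raises :class:`SchemaError` naming any missing
    column and :class:`EmptyInputError` for a table without data rows.
    """
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}; one of {sorted(SCHEMAS)}")
    path = Path(path)
    schema = SCHEMAS[schema_name]
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in schema["required"]:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    keep = schema["required"] + [c for c in schema["optional"] if c in df.columns]
    df = df[keep]
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    df.index = df.index + 2  # header occupies file line 1
    numeric = [c for c in keep if c not in ("compound_id", "label")]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: unparseable value in column {col!r} at line {bad[0]}"
            )
        if coerced.isna().any():
            line = int(df.index[coerced.isna()][0])
            raise SchemaError(f"{path}: empty cell in column {col!r} at line {line}")
        df[col] = coerced
    return df


def read_assay(path: str | Path) -> dict[str, DoseResponse]:
    """Read assay.csv into one DoseResponse per compound."""
    df = read_table(path, "assay")
    out: dict[str, DoseResponse] = {}
    for cid, grp in df.groupby("compound_id", sort=True):
        records = [
            AssayRecord(
                compound_id=str(cid),
                conc_uM=float(r.conc_um),
                replicate=int(r.replicate),
                abs_control=float(r.abs_control),
                abs_sample=float(r.abs_sample),
            )
            for r in grp.itertuples()
        ]
        out[str(cid)] = DoseResponse.from_records(records)
    return out


def read_velocity(path: str | Path) -> VelocityDataset:
    """Read long-format velocity.csv into a VelocityDataset matrix."""
    df = read_table(path, "velocity")
    i_grid = np.sort(df["inhibitor_um"].unique())
    s_grid = np.sort(df["substrate_mm"].unique())
    pivot = df.pivot_table(
        index="inhibitor_um", columns="substrate_mm", values="velocity"
    )
    if pivot.isna().any().any():
        raise SchemaError(f"{path}: velocity grid is not complete (missing cells)")
    v = pivot.loc[i_grid, s_grid].to_numpy()
    return VelocityDataset(inhibitor_uM=i_grid, substrate_mM=s_grid, v=v)


def read_titrations(path: str | Path, pt_nM: float) -> list[FluorescenceTitration]:
    """Read titration.csv into one FluorescenceTitration per temperature.

    Concentrations arrive in uM (ligand) and nM (protein, via flag) and
    are normalized to mol/L.  An optional per-point ``background`` column
    is subtracted from the fluorescence before analysis.
    """
    df = read_table(path, "titration")
    intensity = df["fluorescence"].to_numpy(dtype=float)
    if "background" in df.columns:
        intensity = intensity - df["background"].to_numpy(dtype=float)
    out = []
    for t_C in sorted(df["temperature_c"].unique()):
        m = (df["temperature_c"] == t_C).to_numpy()
        out.append(
            FluorescenceTitration(
                temperature_K=celsius_to_kelvin(float(t_C)),
                pt_M=pt_nM * 1e-9,
                dt_M=df["dt_um"].to_numpy(dtype=float)[m] * 1e-6,
                intensity=intensity[m],
            )
        )
    return out


def read_compositions(path: str | Path) -> dict[str, SecondaryStructureComposition]:
    """Read composition.csv into per-label secondary-structure rows."""
    df = read_table(path, "composition")
    return {
        str(r.label): SecondaryStructureComposition(
            label=str(r.label),
            helix_pct=float(r.helix_pct),
            turn_pct=float(r.turn_pct),
            coil_pct=float(r.coil_pct),
        )
        for r in df.itertuples()
    }
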