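"""CSV readers and writers for the pipeline's three table schemas.

All formats are plain UTF-8 CSV:

* ``panel.csv`` — year, precip_mm, biomass (+ optional species column for
  long format with several species in one file);
* ``aci_<id>.csv`` — t_s, Ci_umol_mol, A_umol_m2_s;
* ``experiment.csv`` — replicate, species, treatment, week, response_name,
  value (long format).

Readers validate the schema and raise :class:`SchemaError` naming the
missing column or the first malformed row (1-based data row number).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from c4drought.errors import SchemaError

PANEL_COLUMNS = ["year", "precip_mm", "biomass"]
ACI_COLUMNS = ["t_s", "Ci_umol_mol", "A_umol_m2_s"]
EXPERIMENT_COLUMNS = ["replicate", "species", "treatment", "week", "response_name", "value"]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def _coerce_numeric(df: pd.DataFrame, cols: list[str], path) -> pd.DataFrame:
    for c in cols:
        converted = pd.to_numeric(df[c], errors="coerce")
        bad = converted.isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise SchemaError(f"{path}: non-numeric value in column {c!r} at data row {row}")
        df[c] = converted
    return df


def write_panel(panel: pd.DataFrame, path) -> Path:
    path = Path(path)
    panel.to_csv(path, index=False)
    return path


def read_panel(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, PANEL_COLUMNS, path)
    return _coerce_numeric(df, PANEL_COLUMNS, path)


def split_panel_by_species(panel: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Extract per-species panels from a long-format panel with a species column."""
    if "species" not in panel.columns:
        return {"all": panel}
    return {
        str(sp): grp.drop(columns="species").reset_index(drop=True)
        for sp, grp in panel.groupby("species", sort=True)
    }


def write_aci(curve: pd.DataFrame, path) -> Path:
    path = Path(path)
    curve[ACI_COLUMNS].to_csv(path, index=False)
    return path


def read_aci(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ACI_COLUMNS, path)
    return _coerce_numeric(df, ACI_COLUMNS, path)


def write_experiment(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_experiment(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, EXPERIMENT_COLUMNS, path)
    return _coerce_numeric(df, ["replicate", "week", "value"], path)
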