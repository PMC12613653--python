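"""Region-year panel I/O with schema validation.

The panel is a tidy CSV: one row per (region, year) with life expectancy
and the candidate covariates. Units are fixed by the schema (years for
``le`` and ``schooling``, percent for ``urbanization``/``oop``/
``dependency``, 10k currency units for ``gdp_pc``, males per 100 females
for ``sex_ratio``, metres for ``wdem``); no silent conversion happens
anywhere downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED = ["region", "year", "le", "urbanization"]
KNOWN_COVARIATES = [
    "gdp_pc", "schooling", "physicians", "oop", "dependency", "sex_ratio",
    "wdem", "population",
]
OPTIONAL = KNOWN_COVARIATES + ["env_type", "stage"]

#: plausibility bounds; violations are schema errors, not warnings
BOUNDS = {
    "le": (30.0, 100.0),          # exclusive
    "urbanization": (0.0, 100.0),  # inclusive
    "oop": (0.0, 100.0),
}


class PanelSchemaError(ValueError):
    pass


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED if c not in panel.columns]
    if missing:
        raise PanelSchemaError(f"panel lacks required columns: {missing}")
    unknown = [c for c in panel.columns if c not in REQUIRED + OPTIONAL]
    if unknown:
        raise PanelSchemaError(f"panel has unknown columns: {unknown}")

    dup = panel.duplicated(subset=["region", "year"])
    if dup.any():
        keys = panel.loc[dup, ["region", "year"]].to_records(index=False).tolist()
        raise PanelSchemaError(f"duplicate (region, year) rows: {keys}")

    errors = []
    le = panel["le"].to_numpy(dtype=float)
    bad = np.where(~((le > BOUNDS["le"][0]) & (le < BOUNDS["le"][1])))[0]
    errors += [f"row {i}: le={le[i]} outside (30, 100)" for i in bad]
    for col in ("urbanization", "oop"):
        if col in panel.columns:
            v = panel[col].to_numpy(dtype=float)
            lo, hi = BOUNDS[col]
            bad = np.where(~((v >= lo) & (v <= hi)))[0]
            errors += [f"row {i}: {col}={v[i]} outside [{lo}, {hi}]" for i in bad]
    if errors:
        raise PanelSchemaError("panel validation failed:\n" + "\n".join(errors))

    out = panel.copy()
    out["region"] = out["region"].astype(int)
    out["year"] = out["year"].astype(int)
    return out.sort_values(["region", "year"]).reset_index(drop=True)


def read_panel(path) -> pd.DataFrame:
    return validate_panel(pd.read_csv(path))


def write_panel(path, panel: pd.DataFrame) -> None:
    """Write with repr-exact floats so a write -> read round trip is lossless."""
    validate_panel(panel).to_csv(path, index=False, float_format="%.17g")
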