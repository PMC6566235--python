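"""Reading compositions, coefficient tables and calibration datasets.

Supported composition dialects:

* long-form CSV with header ``nutrient,amount_g_per_100g``;
* wide-form CSV with one nutrient per column (``sucrose,starch,fiber_sol,
  fiber_ins,fat,protein`` style headers), one product per row;
* JSON with an ``amounts`` mapping plus optional ``starch_availability``
  and ``serving_g`` (a flat name→amount mapping also works).

Coefficient files are JSON mirroring the registry; omission falls back to
the bundled defaults.  The output of ``glyco calibrate`` (a ``b_estimates``
mapping) is accepted directly as a coefficient file.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .model_core import (
    CoefficientTable,
    Composition,
    GlycoError,
    NutrientSpec,
    default_coefficients,
    normalize_nutrient,
)

__all__ = [
    "read_composition",
    "read_compositions_wide",
    "read_coefficients",
    "read_calibration_data",
]

_META_COLUMNS = {"product_id", "process", "gi_obs", "gi_observed", "gi_pred",
                 "gl_obs", "gl_pred", "starch_availability", "serving_g"}


def _composition_from_json(obj: dict) -> Composition:
    if "amounts" in obj:
        return Composition(
            amounts=obj["amounts"],
            starch_availability=obj.get("starch_availability"),
            serving_g=obj.get("serving_g"),
        )
    return Composition(amounts=obj)


def read_composition(path: str | Path) -> Composition:
    """Read a single-product composition from CSV or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            obj = json.load(fh)
        if not isinstance(obj, dict):
            raise GlycoError(f"{path}: expected a JSON object")
        return _composition_from_json(obj)

    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "nutrient" in cols and "amount_g_per_100g" in cols:
        amounts = dict(zip(df["nutrient"], df["amount_g_per_100g"]))
        return Composition(amounts=amounts)
    # wide form: first data row
    comps = read_compositions_wide(df)
    if len(comps) != 1:
        raise GlycoError(f"{path}: expected a single product, found {len(comps)}")
    return comps[0][1]


def read_compositions_wide(df: pd.DataFrame) -> list[tuple[str, Composition]]:
    """Parse a wide-form table (one nutrient column per nutrient)."""
    nutrient_cols = [c for c in df.columns if c not in _META_COLUMNS]
    if not nutrient_cols:
        raise GlycoError("no nutrient columns found")
    out = []
    for i, row in df.iterrows():
        amounts = {c: row[c] for c in nutrient_cols if pd.notna(row[c])}
        availability = None
        if "starch_availability" in df.columns and pd.notna(row.get("starch_availability")):
            availability = float(row["starch_availability"])
        serving = None
        if "serving_g" in df.columns and pd.notna(row.get("serving_g")):
            serving = float(row["serving_g"])
        pid = str(row["product_id"]) if "product_id" in df.columns else str(i)
        out.append(
            (pid, Composition(amounts=amounts, starch_availability=availability,
                              serving_g=serving))
        )
    return out


def read_coefficients(path: str | Path | None) -> CoefficientTable:
    """Load a coefficient table from JSON, or the defaults when path is None.

    A plain ``{nutrient: b}`` mapping or a calibration result with a
    ``b_estimates`` key overrides the default lowering coefficients; the
    fully explicit per-nutrient spec form replaces the whole table.
    """
    if path is None:
        return default_coefficients()
    with open(path) as fh:
        obj = json.load(fh)
    if not isinstance(obj, dict):
        raise GlycoError(f"{path}: expected a JSON object")
    if "b_estimates" in obj:
        return default_coefficients().with_b(obj["b_estimates"])
    values = list(obj.values())
    if values and all(isinstance(v, (int, float)) for v in values):
        return default_coefficients().with_b(obj)
    specs = {}
    for name, spec in obj.items():
        key = normalize_nutrient(name)
        specs[key] = NutrientSpec(
            key,
            spec["role"],
            gi=spec.get("gi"),
            availability_default=spec.get("availability_default"),
            b=spec.get("b"),
        )
    return CoefficientTable(specs)


def read_calibration_data(path: str | Path) -> list[tuple[str, Composition, float]]:
    """Read a calibration CSV: product_id, nutrient columns, gi_observed
    and optionally starch_availability."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    gi_col = "gi_observed" if "gi_observed" in df.columns else "gi_obs"
    if gi_col not in df.columns:
        raise GlycoError(f"{path}: missing gi_observed column")
    gi = df[gi_col].astype(float)
    comps = read_compositions_wide(df.drop(columns=[gi_col]))
    return [(pid, comp, g) for (pid, comp), g in zip(comps, gi)]
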