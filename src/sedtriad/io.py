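"""CSV schema validation for the pipeline's tabular inputs."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .exceptions import SchemaError

#: declared input schemas: column -> (dtype kind, validator or None)
SCHEMAS = {
    "chemistry": {
        "site": ("str", None),
        "analyte": ("str", None),
        "mean": ("num", lambda v: v >= 0),
        "sd": ("num_optional", lambda v: v >= 0),
        "units": ("str", None),
    },
    "guidelines": {
        "analyte": ("str", None),
        "pel": ("num", lambda v: v > 0),
        "units": ("str", None),
        "class": ("str", lambda v: v in ("metal", "organic")),
    },
    "dose_response": {
        "site": ("str", None),
        "fraction": ("int", lambda v: v in (1, 2, 3, 4)),
        "endpoint": ("str", lambda v: v in ("viability_pct", "tail_pct")),
        "fpg": ("bool", None),
        "concentration": ("num", lambda v: v >= 0),
        "replicate": ("any", None),
        "response": ("num", None),
    },
    "nucleoids": {
        "site": ("str", None),
        "fraction": ("int", lambda v: v in (1, 2, 3, 4)),
        "fpg": ("bool", None),
        "concentration": ("num", lambda v: v >= 0),
        "replicate": ("any", None),
        "gel": ("any", None),
        "tail_pct": ("num", lambda v: 0 <= v <= 100),
    },
    "biomarkers": {
        "station": ("str", None),
        "species": ("str", None),
        "biomarker": ("str", None),
        "value": ("num", None),
    },
    "biomarker_panel": {
        "station": ("str", None),
        "species": ("str", None),
        "biomarker": ("str", None),
        "mean": ("num", None),
        "sd": ("num_optional", lambda v: v >= 0),
    },
    "coordinates": {
        "site": ("str", None),
        "x": ("num", None),
        "y": ("num", None),
    },
    "loe_matrix": None,  # free-form: site index + numeric endpoint columns
}


def validate_schema(source, schema_name: str) -> pd.DataFrame:
    """Read (if a path) and validate a table against a declared schema.

    Returns the typed DataFrame or raises :class:`SchemaError` whose
    ``violations`` lists every offending column/row.
    """
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}")
    if isinstance(source, (str, Path)):
        try:
            frame = pd.read_csv(source)
        except Exception as exc:  # parse errors carry pandas' line info
            raise SchemaError(f"cannot parse {source}: {exc}") from exc
    else:
        frame = source.copy()

    schema = SCHEMAS[schema_name]
    if schema is None:
        return frame

    violations = []
    for col, (kind, check) in schema.items():
        if col not in frame.columns:
            violations.append(f"missing column {col!r}")
            continue
        series = frame[col]
        if kind in ("num", "num_optional", "int"):
            coerced = pd.to_numeric(series, errors="coerce")
            bad = coerced.isna() & series.notna()
            if kind != "num_optional" and series.isna().any():
                bad |= series.isna()
            if bad.any():
                violations.append(
                    f"column {col!r}: non-numeric or missing values at rows "
                    f"{list(frame.index[bad])[:5]}")
                continue
            frame[col] = coerced
            series = coerced
            if kind == "int":
                frame[col] = series.astype("int64", errors="ignore")
        elif kind == "bool":
            mapped = series.map({True: True, False: False, "True": True, "False": False,
                                 "true": True, "false": False, 1: True, 0: False})
            if mapped.isna().any():
                violations.append(f"column {col!r}: values not interpretable as boolean")
                continue
            frame[col] = mapped.astype(bool)
            series = frame[col]
        if check is not None:
            vals = series.dropna()
            bad_rows = [i for i, v in vals.items() if not check(v)]
            if bad_rows:
                violations.append(
                    f"column {col!r}: {len(bad_rows)} out-of-range values "
                    f"(first at rows {bad_rows[:5]})")
    if violations:
        raise SchemaError(
            f"table failed schema {schema_name!r}: {'; '.join(violations)}",
            violations=violations)
    return frame
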