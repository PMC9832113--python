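"""Dataset I/O, schema validation, and descriptive cross-tabulations.

Datasets travel as plain CSV with a header row, UTF-8, and a configurable
missing token. The descriptive table reproduces the classic risk-factor x
outcome percentage layout: for each level of each risk factor, the percent of
non-missing children positive on each of the six indicators.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model_spec import ModelSpec


@dataclass
class DatasetSchema:
    """Required indicator columns, covariate levels, and the missing token."""

    indicators: tuple
    covariate_levels: dict  # name -> tuple of allowed levels
    missing_token: str = "NA"

    @classmethod
    def from_spec(cls, spec: ModelSpec, missing_token: str = "NA") -> "DatasetSchema":
        return cls(
            indicators=spec.indicator_names(),
            covariate_levels={c.name: tuple(map(str, c.levels)) for c in spec.covariates},
            missing_token=missing_token,
        )


def _schema_of(schema) -> DatasetSchema:
    if isinstance(schema, DatasetSchema):
        return schema
    if isinstance(schema, ModelSpec):
        return DatasetSchema.from_spec(schema)
    raise TypeError("schema must be a DatasetSchema or ModelSpec")


def read_dataset(path, schema) -> pd.DataFrame:
    """Read and validate a child-level CSV against the schema.

    Indicator columns become floats in {0, 1, NaN}; covariate columns stay as
    strings with the missing token normalized to NaN. Raises ValueError naming
    the column, the offending value and the first offending row (0-based data
    row) on any violation.
    """
    sch = _schema_of(schema)
    try:
        data = pd.read_csv(
            path, dtype=str, keep_default_na=False,
            na_values=[sch.missing_token, ""],
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file (no header row)") from None
    if len(data) == 0:
        raise ValueError(f"{path}: dataset has a header but zero data rows")
    required = list(sch.indicators) + list(sch.covariate_levels)
    absent = [c for c in required if c not in data.columns]
    if absent:
        raise ValueError(f"{path}: missing required columns {absent}")
    for col in sch.indicators:
        vals = pd.to_numeric(data[col], errors="coerce")
        bad = vals.notna() & ~vals.isin([0.0, 1.0])
        bad |= data[col].notna() & vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: indicator {col!r} has non-binary value "
                f"{data[col].iloc[row]!r} at row {row}"
            )
        data[col] = vals
    for col, levels in sch.covariate_levels.items():
        ok = data[col].isna() | data[col].isin(levels)
        if not ok.all():
            row = int(np.flatnonzero(~ok.to_numpy())[0])
            raise ValueError(
                f"{path}: covariate {col!r} has unknown level "
                f"{data[col].iloc[row]!r} at row {row}"
            )
    return data


def write_dataset(data: pd.DataFrame, path, missing_token: str = "NA") -> None:
    """Write a dataset as CSV; indicator floats are printed as bare 0/1."""
    out = data.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            as_int = out[col].astype("Int64", errors="ignore")
            if ((out[col].dropna() % 1) == 0).all():
                out[col] = as_int
    out.to_csv(path, index=False, na_rep=missing_token)


def descriptive_table(data: pd.DataFrame, risk_factors, outcomes=None,
                      spec: Optional[ModelSpec] = None) -> pd.DataFrame:
    """Percent of children positive on each outcome, per risk-factor level.

    Each percentage is 100 * (positive in level) / (non-missing in level).
    Values are unrounded; round for display only.
    """
    if outcomes is None:
        outcomes = list(spec.indicator_names()) if spec is not None else [
            c for c in ("stunting", "wasting", "underweight", "diarrhea", "cough", "fever")
            if c in data.columns
        ]
    rows = []
    index = []
    for factor in risk_factors:
        levels = (
            [str(l) for l in spec.covariate(factor).levels]
            if spec is not None
            else sorted(data[factor].dropna().astype(str).unique())
        )
        for level in levels:
            sel = data[factor].astype(str) == level
            rec = {}
            for out in outcomes:
                y = pd.to_numeric(data.loc[sel, out], errors="coerce")
                denom = y.notna().sum()
                rec[out] = 100.0 * y.sum() / denom if denom else np.nan
            rows.append(rec)
            index.append((factor, level))
    return pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["factor", "level"]))


# ---------------------------------------------------------------------------
# run manifests


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_path, options: dict, inputs=()) -> Path:
    """Record the options, seed, package version and input checksums of a run."""
    from . import __version__

    manifest = {
        "package": "mimicgsem",
        "version": __version__,
        "options": {k: (v if isinstance(v, (int, float, str, bool, type(None))) else str(v))
                    for k, v in options.items()},
        "inputs": {str(p): file_checksum(p) for p in inputs if Path(p).exists()},
    }
    path = Path(str(out_path) + ".manifest.json")
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
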