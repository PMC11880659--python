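"""Delimited-text formats, config round-tripping and atomic writes.

The canonical on-disk format is the tidy long table (one row per
individual x trait x occasion) with a header:
``individual_id,mesocosm_id,treatment,trait,occasion,value``.
Occasions are 1-based in files ("trial 1" is occasion 1).  All writes go
through a temp-file-and-rename so interrupted runs never leave a
half-written artifact.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import pandas as pd
import yaml

from .design import ParameterSet
from .errors import SchemaError
from .synthetic import LONG_COLUMNS
from .traits import StandardizationParams

FLOAT_FORMAT = "%.12g"


def atomic_write_text(path, text: str) -> None:
    """Write ``text`` to ``path`` via a temp file + rename in the same dir."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_long_table(table: pd.DataFrame, path) -> None:
    """Write a long table as CSV with a stable float format (atomic)."""
    atomic_write_text(
        path, table[LONG_COLUMNS].to_csv(index=False, float_format=FLOAT_FORMAT)
    )


def read_long_table(path) -> pd.DataFrame:
    """Read and validate a long table.

    Rejects schema mismatches, non-numeric values and duplicate
    (individual, trait, occasion) keys, reporting 1-based file line
    numbers (header is line 1).
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={"individual_id": str, "mesocosm_id": str, "treatment": str, "trait": str})
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")

    occ = pd.to_numeric(df["occasion"], errors="coerce")
    bad = df.index[occ.isna()]
    if len(bad):
        raise SchemaError(f"{path}: non-numeric occasion at line(s) {[i + 2 for i in bad[:5]]}")
    vals = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[vals.isna() & df["value"].notna()]
    if len(bad):
        raise SchemaError(f"{path}: non-numeric value at line(s) {[i + 2 for i in bad[:5]]}")
    df["occasion"] = occ.astype(int)
    df["value"] = vals

    dup = df.duplicated(subset=["individual_id", "trait", "occasion"], keep=False)
    if dup.any():
        lines = [i + 2 for i in df.index[dup][:10]]
        raise SchemaError(
            f"{path}: duplicate (individual_id, trait, occasion) keys at line(s) {lines}"
        )
    return df[LONG_COLUMNS]


def write_truth(truth: ParameterSet, path) -> None:
    """Serialize a ground-truth parameter set as YAML (atomic)."""
    atomic_write_text(path, yaml.safe_dump(truth.to_dict(), sort_keys=True))


def read_truth(path) -> ParameterSet:
    with open(path) as fh:
        return ParameterSet.from_dict(yaml.safe_load(fh))


def write_standardization(params: StandardizationParams, path) -> None:
    atomic_write_text(path, yaml.safe_dump(params.to_dict(), sort_keys=True))


def read_standardization(path) -> StandardizationParams:
    with open(path) as fh:
        return StandardizationParams.from_dict(yaml.safe_load(fh))


def write_table(df: pd.DataFrame, path) -> None:
    """Write any summary table as CSV with the package float format (atomic)."""
    atomic_write_text(path, df.to_csv(index=False, float_format=FLOAT_FORMAT))


def write_json(obj, path) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
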