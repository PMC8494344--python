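"""Portable table persistence: CSV plus a JSON sidecar of column types.

Used wherever a processed table crosses a stage boundary (in place of a
language-specific binary serialization) so downstream stages — or other
languages — recover booleans, numbers, and strings faithfully.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

_SIDE_SUFFIX = ".types.json"


def _type_name(dtype) -> str:
    if pd.api.types.is_bool_dtype(dtype):
        return "bool"
    if pd.api.types.is_integer_dtype(dtype):
        return "int"
    if pd.api.types.is_float_dtype(dtype):
        return "float"
    return "str"


def write_table(df: pd.DataFrame, path: Path | str) -> Path:
    """Write ``df`` to CSV with a ``<name>.types.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    sidecar = {col: _type_name(df[col].dtype) for col in df.columns}
    side_path = path.with_suffix(path.suffix + _SIDE_SUFFIX)
    side_path.write_text(json.dumps(sidecar, indent=1), encoding="utf-8")
    return path


def read_table(path: Path | str) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, restoring column types."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace("", np.nan)
    side_path = path.with_suffix(path.suffix + _SIDE_SUFFIX)
    if not side_path.exists():
        return df
    types = json.loads(side_path.read_text(encoding="utf-8"))
    for col, tname in types.items():
        if col not in df.columns:
            continue
        if tname == "bool":
            df[col] = df[col].map({"True": True, "False": False}).fillna(False).astype(bool)
        elif tname in ("int", "float"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
            if tname == "int" and not df[col].isna().any():
                df[col] = df[col].astype(int)
    return df
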