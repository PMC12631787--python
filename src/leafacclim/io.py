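"""CSV dialects and configuration files.

Column names carry their units (``tair_C``, ``ppfd_umol_m2_s``, ...), so
every artifact is self-describing; files are header-keyed, so column order is
free.  Validation errors name the offending column or row.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .synthetic import GASEX_COLUMNS, MET_COLUMNS


def _require_columns(df: pd.DataFrame, required, path):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")


def read_met_csv(path) -> pd.DataFrame:
    """Read a met-driver CSV; validates columns, timestamps and ordering."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, MET_COLUMNS, path)
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable timestamp ({exc})") from exc
    bad = df["timestamp"].diff().dt.total_seconds().iloc[1:] <= 0
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(f"{path}: non-monotone timestamp at row {row}")
    return df[MET_COLUMNS]


def write_met_csv(df: pd.DataFrame, path) -> None:
    _require_columns(df, MET_COLUMNS, "met frame")
    df.loc[:, MET_COLUMNS].to_csv(path, index=False)


def read_gasex_csv(path) -> pd.DataFrame:
    """Read a gas-exchange observation CSV (synthetic-data dialect)."""
    df = pd.read_csv(path, comment="#")
    required = [c for c in GASEX_COLUMNS if c != "timestamp"]
    _require_columns(df, required, path)
    if "timestamp" in df.columns:
        df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce")
    bad_mode = ~df["mode"].isin(["light", "dark"])
    if bad_mode.any():
        row = int(bad_mode.idxmax())
        raise ValueError(f"{path}: invalid mode at row {row}")
    return df


def write_gasex_csv(df: pd.DataFrame, path) -> None:
    cols = [c for c in list(df.columns) if c in GASEX_COLUMNS or
            c == "antecedent_tair_C"]
    df.loc[:, cols].to_csv(path, index=False)


def write_fits_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_params(path) -> dict:
    """Species-parameter JSON/YAML keyed by SpeciesParams field names."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh)
        return json.load(fh)


def write_params(params: dict, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(params, fh, sort_keys=False)
        else:
            json.dump(params, fh, indent=2)


def write_json_report(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
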