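"""Reading and writing the long-format trial CSV and config files.

The native dialect is comma-separated UTF-8 with a header and "." decimals:

    participant_id,block,trial,condition,size_diff_pct,test_side,response

External deposits with different column names or response codings are
adapted through a column-mapping config (a YAML/JSON dict) rather than
hard-coded schemas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .design import TRIAL_COLUMNS

__all__ = ["read_trials_csv", "write_trials_csv", "read_config", "SchemaError"]

KNOWN_CONDITIONS = ("Balls", "Coins", "Soccer", "Tennis")
_SIDES = {"left", "right"}


class SchemaError(ValueError):
    """A trial file does not match the expected schema."""


def read_trials_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    condition_map: Mapping[str, str] | None = None,
    response_map: Mapping[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Read and validate a long-format trial file.

    ``column_map`` renames source columns to the native schema (e.g.
    ``{"subject": "participant_id"}``); ``condition_map`` and
    ``response_map`` recode cell values.  Returns one validated table per
    participant, keyed by id.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(TRIAL_COLUMNS)].copy()
    if condition_map:
        df["condition"] = df["condition"].replace(dict(condition_map))
    if response_map:
        df["response"] = df["response"].replace(dict(response_map))

    bad_size = pd.to_numeric(df["size_diff_pct"], errors="coerce").isna()
    if bad_size.any():
        rows = df.index[bad_size].tolist()[:10]
        raise SchemaError(f"size_diff_pct not numeric at rows {rows}")
    df["size_diff_pct"] = df["size_diff_pct"].astype(float)

    bad_cond = ~df["condition"].isin(KNOWN_CONDITIONS)
    if bad_cond.any():
        rows = df.index[bad_cond].tolist()[:10]
        labels = sorted(df.loc[bad_cond, "condition"].unique())
        raise SchemaError(f"unknown condition labels {labels} at rows {rows}")

    for col in ("test_side", "response"):
        vals = df[col].dropna()
        bad = ~vals.isin(_SIDES)
        if bad.any():
            rows = vals.index[bad].tolist()[:10]
            raise SchemaError(f"{col} must be 'left'/'right'; bad values at rows {rows}")

    return {pid: g.reset_index(drop=True) for pid, g in df.groupby("participant_id", sort=True)}


def write_trials_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.loc[:, list(TRIAL_COLUMNS)].to_csv(path, index=False)


def read_config(path: str | Path) -> dict:
    """Read a YAML or JSON config file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
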