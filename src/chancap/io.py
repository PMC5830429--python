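"""Delimited-text readers and writers for the pipeline's tabular artifacts.

All stage products are plain text so every intermediate of a run can be
inspected and re-run: traces and peak tables as CSV, noise parameters and
reports as JSON, configs and designs as YAML.  Readers validate the schema
and name the offending column on failure.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

PEAK_REQUIRED = ["cell_id", "concentration_nM", "replicate", "pulse_index", "peak_log_response"]
PEAK_COLUMNS = ["cell_id", "experiment_id", *PEAK_REQUIRED[1:], "qc_flag"]
TRACE_COLUMNS = ["time_s", "cell_id", "ratio"]


class SchemaError(ValueError):
    """An input table does not match the expected column schema."""


def _require(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def read_peak_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, PEAK_REQUIRED, f"peak table {path}")
    if "qc_flag" not in df.columns:
        df["qc_flag"] = "ok"
    if "experiment_id" not in df.columns:
        df["experiment_id"] = 0
    bad = df["qc_flag"] != "artifact_removed"
    if not np.all(np.isfinite(df.loc[bad, "peak_log_response"])):
        raise SchemaError(f"peak table {path}: non-finite peak_log_response in retained rows")
    return df[PEAK_COLUMNS]


def write_peak_table(df: pd.DataFrame, path: str | Path) -> None:
    _require(df, PEAK_REQUIRED, "peak table")
    out = df.copy()
    if "qc_flag" not in out.columns:
        out["qc_flag"] = "ok"
    if "experiment_id" not in out.columns:
        out["experiment_id"] = 0
    out[PEAK_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_traces(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, TRACE_COLUMNS, f"trace table {path}")
    if not np.all(np.isfinite(df["ratio"])):
        raise SchemaError(f"trace table {path}: non-finite ratio values")
    return df[TRACE_COLUMNS]


def write_traces(df: pd.DataFrame, path: str | Path) -> None:
    _require(df, TRACE_COLUMNS, "trace table")
    df[TRACE_COLUMNS].to_csv(path, index=False, float_format="%.8g")
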