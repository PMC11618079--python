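"""CSV schemas of the pipeline artifacts (ISO-8601 UTC timestamps, UTF-8)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

RECORD_COLUMNS = [
    "bird_id",
    "logger_id",
    "timestamp",
    "f_H_bpm",
    "T_b_C",
    "qi_class",
    "is_night",
    "has_ecg_truth",
    "true_fH_bpm",
]


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    out = records.copy()
    for col in RECORD_COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA
    out = out[RECORD_COLUMNS]
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.tz_localize(None)
    for col in ("is_night", "has_ecg_truth"):
        if col in df:
            df[col] = df[col].astype(bool)
    return df


def write_ambient(ambient: pd.DataFrame, path: str | Path) -> None:
    out = ambient[["site", "timestamp", "T_a_C"]].copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def read_ambient(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.tz_localize(None)
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_events_frames(nights: pd.DataFrame, anchors: pd.DataFrame, night_path, anchor_path) -> None:
    nights.to_csv(night_path, index=False)
    anchors.to_csv(anchor_path, index=False)
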