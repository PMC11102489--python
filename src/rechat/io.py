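"""Reading and writing the pipeline's on-disk formats (JSONL / CSV)."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "write_messages_jsonl",
    "read_messages_jsonl",
    "write_messages_csv",
    "read_messages_csv",
    "write_table",
    "read_table",
]

_MSG_COLS = ["chat_id", "sender", "sent_at", "text"]


def write_messages_jsonl(messages: pd.DataFrame, path: str | Path) -> None:
    """One JSON object per message: chat_id, sender, sent_at (ISO-8601), text."""
    df = messages[_MSG_COLS].copy()
    df["sent_at"] = df["sent_at"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    with open(path, "w") as fh:
        for rec in df.to_dict(orient="records"):
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_messages_jsonl(path: str | Path) -> pd.DataFrame:
    df = pd.read_json(path, lines=True, convert_dates=False)
    df["sent_at"] = pd.to_datetime(df["sent_at"])
    return df[_MSG_COLS]


def write_messages_csv(messages: pd.DataFrame, path: str | Path) -> None:
    df = messages[_MSG_COLS].copy()
    df["sent_at"] = df["sent_at"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


def read_messages_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    df["sent_at"] = pd.to_datetime(df["sent_at"])
    return df[_MSG_COLS]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """CSV writer for record/report tables (timestamps in ISO form)."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_table(path: str | Path, date_cols: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    for col in date_cols:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    return df
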