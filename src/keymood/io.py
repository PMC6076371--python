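"""Readers and writers for keystroke event logs, accelerometer logs and
weekly mood assessments.

Two on-disk formats are supported: CSV with a header row, and JSONL (one
JSON object per line) with identical field names. Timestamps are ISO-8601
with an explicit UTC offset; the offset is the subject's local offset and is
preserved on a per-record basis (column ``tz_offset_min``) so that local
clock hours can be recovered for circadian binning.

Frame schemas (returned by the readers, accepted by the writers):

``events``
    subject_id (str), timestamp (datetime64[ns, UTC]), tz_offset_min (int),
    event_class (str, one of :class:`~keymood.types.EventClass`)
``accel``
    subject_id, timestamp, tz_offset_min, x, y, z (float, m/s^2)
``assessments``
    subject_id, assessed_at, tz_offset_min, scale (str), score (int)

Readers sort deterministically by (subject_id, timestamp) with a stable
sort, so input record order never affects downstream results; duplicate
timestamps within a subject are kept in file order and flagged in the log.
"""
from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .types import EventClass, Scale, SCALE_RANGES

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["subject_id", "timestamp", "event_class"]
ACCEL_COLUMNS = ["subject_id", "timestamp", "x", "y", "z"]
ASSESSMENT_COLUMNS = ["subject_id", "assessed_at", "scale", "score"]

_OFFSET_RE = re.compile(r"(Z|[+-]\d{2}:?\d{2})$")

_VALID_EVENT_CLASSES = {e.value for e in EventClass}
_VALID_SCALES = {s.value for s in Scale}


def _detect_format(path: str | Path, format: str | None) -> str:
    if format is not None:
        fmt = format.upper()
        if fmt not in {"CSV", "JSONL"}:
            raise ValueError(f"unknown format {format!r}; expected 'CSV' or 'JSONL'")
        return fmt
    suffix = Path(path).suffix.lower()
    return "JSONL" if suffix in {".jsonl", ".ndjson", ".json"} else "CSV"


def _read_records(path: str | Path, format: str | None) -> pd.DataFrame:
    """Load raw records into a string-typed frame; 'line' column = 1-based file line."""
    fmt = _detect_format(path, format)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "CSV":
        try:
            df = pd.read_csv(path, dtype=str, skip_blank_lines=False)
        except pd.errors.EmptyDataError:
            return pd.DataFrame()
        df["line"] = np.arange(2, len(df) + 2)  # header is line 1
        return df
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw:
                continue
            try:
                rec = json.loads(raw)
            except json.JSONDecodeError as exc:
                raise ParseError(f"invalid JSON: {exc}", line=lineno) from exc
            if not isinstance(rec, dict):
                raise ParseError("record is not a JSON object", line=lineno)
            rec = {k: (None if v is None else str(v)) for k, v in rec.items()}
            rec["line"] = lineno
            rows.append(rec)
    return pd.DataFrame(rows)


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")


def _first_bad_line(df: pd.DataFrame, bad_mask) -> int:
    return int(df.loc[bad_mask, "line"].iloc[0])


def _parse_timestamps(df: pd.DataFrame, column: str) -> tuple[pd.Series, pd.Series]:
    """Parse an ISO-8601 column -> (UTC datetimes, offset minutes)."""
    raw = df[column].astype(str)
    offsets = raw.str.extract(_OFFSET_RE, expand=False)
    if offsets.isna().any():
        raise ParseError(
            f"{column} lacks an explicit UTC offset",
            line=_first_bad_line(df, offsets.isna()),
        )
    parsed = pd.to_datetime(raw, utc=True, errors="coerce", format="ISO8601")
    if parsed.isna().any():
        raise ParseError(
            f"unparseable {column} value {raw[parsed.isna()].iloc[0]!r}",
            line=_first_bad_line(df, parsed.isna()),
        )
    off_min = offsets.where(offsets != "Z", "+00:00")
    sign = np.where(off_min.str.startswith("-"), -1, 1)
    digits = off_min.str.replace(re.compile(r"[+:\-]"), "", regex=True)
    minutes = sign * (digits.str[:2].astype(int) * 60 + digits.str[2:4].astype(int))
    return parsed, pd.Series(minutes, index=df.index, dtype="int64")


def _finalize(df: pd.DataFrame, time_col: str, flag_duplicates: bool, what: str) -> pd.DataFrame:
    df = df.sort_values(["subject_id", time_col], kind="stable").reset_index(drop=True)
    if flag_duplicates:
        dup = df.duplicated(["subject_id", time_col], keep=False)
        if dup.any():
            logger.warning(
                "%s: %d records share a (subject, timestamp) millisecond; "
                "kept in stable file order", what, int(dup.sum()),
            )
    return df


def read_event_log(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a keypress event log, returning a validated, ordered frame.

    Unknown ``event_class`` values raise :class:`ParseError` naming the line.
    """
    raw = _read_records(path, format)
    if raw.empty:
        return pd.DataFrame(
            {
                "subject_id": pd.Series(dtype=str),
                "timestamp": pd.Series(dtype="datetime64[ns, UTC]"),
                "tz_offset_min": pd.Series(dtype="int64"),
                "event_class": pd.Series(dtype=str),
            }
        )
    _require_columns(raw, EVENT_COLUMNS, path)
    ts, off = _parse_timestamps(raw, "timestamp")
    cls = raw["event_class"].astype(str)
    bad = ~cls.isin(_VALID_EVENT_CLASSES)
    if bad.any():
        raise ParseError(
            f"unknown event_class {cls[bad].iloc[0]!r}", line=_first_bad_line(raw, bad)
        )
    df = pd.DataFrame(
        {
            "subject_id": raw["subject_id"].astype(str),
            "timestamp": ts,
            "tz_offset_min": off,
            "event_class": cls,
        }
    )
    return _finalize(df, "timestamp", flag_duplicates=True, what="event log")


def read_accel_log(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read an accelerometer log. Missing or non-finite components are rejected."""
    raw = _read_records(path, format)
    if raw.empty:
        return pd.DataFrame(
            {
                "subject_id": pd.Series(dtype=str),
                "timestamp": pd.Series(dtype="datetime64[ns, UTC]"),
                "tz_offset_min": pd.Series(dtype="int64"),
                "x": pd.Series(dtype=float),
                "y": pd.Series(dtype=float),
                "z": pd.Series(dtype=float),
            }
        )
    _require_columns(raw, ACCEL_COLUMNS, path)
    ts, off = _parse_timestamps(raw, "timestamp")
    comps = {}
    for c in ("x", "y", "z"):
        vals = pd.to_numeric(raw[c], errors="coerce")
        bad = ~np.isfinite(vals.to_numpy(dtype=float, na_value=np.nan))
        if bad.any():
            raise ParseError(
                f"accelerometer component {c}={raw[c][bad].iloc[0]!r} is not a finite number",
                line=_first_bad_line(raw, bad),
            )
        comps[c] = vals.astype(float)
    df = pd.DataFrame(
        {
            "subject_id": raw["subject_id"].astype(str),
            "timestamp": ts,
            "tz_offset_min": off,
            **comps,
        }
    )
    return _finalize(df, "timestamp", flag_duplicates=False, what="accel log")


def read_assessments(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read weekly mood assessments, enforcing score-range and one-per-week invariants."""
    raw = _read_records(path, format)
    if raw.empty:
        return pd.DataFrame(
            {
                "subject_id": pd.Series(dtype=str),
                "assessed_at": pd.Series(dtype="datetime64[ns, UTC]"),
                "tz_offset_min": pd.Series(dtype="int64"),
                "scale": pd.Series(dtype=str),
                "score": pd.Series(dtype="int64"),
            }
        )
    _require_columns(raw, ASSESSMENT_COLUMNS, path)
    ts, off = _parse_timestamps(raw, "assessed_at")
    scale = raw["scale"].astype(str)
    bad = ~scale.isin(_VALID_SCALES)
    if bad.any():
        raise ParseError(
            f"unknown scale {scale[bad].iloc[0]!r}", line=_first_bad_line(raw, bad)
        )
    score = pd.to_numeric(raw["score"], errors="coerce")
    if score.isna().any() or (score != score.round()).any():
        raise ParseError(
            "score must be an integer", line=_first_bad_line(raw, score.isna() | (score != score.round()))
        )
    score = score.astype("int64")
    for sc, (lo, hi) in SCALE_RANGES.items():
        mask = scale == sc.value
        out = mask & ((score < lo) | (score > hi))
        if out.any():
            raise ValidationError(
                f"{sc.value} score {int(score[out].iloc[0])} outside valid range [{lo}, {hi}] "
                f"(line {_first_bad_line(raw, out)})"
            )
    df = pd.DataFrame(
        {
            "subject_id": raw["subject_id"].astype(str),
            "assessed_at": ts,
            "tz_offset_min": off,
            "scale": scale,
            "score": score,
        }
    )
    # at most one assessment per subject per scale per calendar (ISO) week,
    # judged on the subject-local clock
    local = df["assessed_at"] + pd.to_timedelta(df["tz_offset_min"], unit="m")
    iso = local.dt.isocalendar()
    key = pd.DataFrame(
        {"subject_id": df["subject_id"], "scale": df["scale"], "year": iso["year"], "week": iso["week"]}
    )
    dup = key.duplicated(keep=False)
    if dup.any():
        first = df[dup].iloc[0]
        raise ValidationError(
            f"multiple {first['scale']} assessments for subject {first['subject_id']} "
            f"in the same calendar week"
        )
    return _finalize(df, "assessed_at", flag_duplicates=False, what="assessments")


# ---------------------------------------------------------------------------
# writers


def _format_timestamps(ts: pd.Series, offset_min: pd.Series) -> pd.Series:
    """Render UTC instants as ISO-8601 strings in each record's local offset."""
    local = ts + pd.to_timedelta(offset_min, unit="m")
    base = local.dt.strftime("%Y-%m-%dT%H:%M:%S.%f").str[:-3]
    off = offset_min.astype(int)
    sign = np.where(off < 0, "-", "+")
    hh = (np.abs(off) // 60).astype(int)
    mm = (np.abs(off) % 60).astype(int)
    suffix = [f"{s}{h:02d}:{m:02d}" for s, h, m in zip(sign, hh, mm)]
    return base + pd.Series(suffix, index=ts.index)


def _write(df: pd.DataFrame, path: str | Path, format: str | None) -> None:
    fmt = _detect_format(path, format)
    if fmt == "CSV":
        df.to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            for rec in df.to_dict(orient="records"):
                fh.write(json.dumps(rec) + "\n")


def write_event_log(events: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    out = pd.DataFrame(
        {
            "subject_id": events["subject_id"],
            "timestamp": _format_timestamps(events["timestamp"], events["tz_offset_min"]),
            "event_class": events["event_class"],
        }
    )
    _write(out, path, format)


def write_accel_log(accel: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    out = pd.DataFrame(
        {
            "subject_id": accel["subject_id"],
            "timestamp": _format_timestamps(accel["timestamp"], accel["tz_offset_min"]),
            "x": accel["x"],
            "y": accel["y"],
            "z": accel["z"],
        }
    )
    _write(out, path, format)


def write_assessments(assessments: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    out = pd.DataFrame(
        {
            "subject_id": assessments["subject_id"],
            "assessed_at": _format_timestamps(
                assessments["assessed_at"], assessments["tz_offset_min"]
            ),
            "scale": assessments["scale"],
            "score": assessments["score"],
        }
    )
    _write(out, path, format)
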