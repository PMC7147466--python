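"""Reading and writing the raw free-living data streams.

Four per-patient CSV files make up a raw dataset, all comma-separated,
UTF-8, with a header row and timezone-naive ISO-8601 timestamps:

* ``cgm.csv``      — ``timestamp,glucose_mgdl``
* ``events.csv``   — ``timestamp,kind,value`` with ``kind`` one of
  ``rapid_insulin`` / ``long_insulin`` (units U), ``meal`` (grams of
  carbohydrate) or ``smbg`` (mg/dL fingerstick)
* ``activity.csv`` — ``timestamp,steps,heart_rate,calories`` at one row
  per minute
* ``sleep.csv``    — ``start,end`` sleep periods

These dialects are a vendor-neutral stand-in for intermittently scanned
CGM reader exports and wrist-worn tracker exports.  Malformed rows are
skipped with their line numbers logged rather than aborting the read;
structural problems (missing columns, overlapping sleep periods) raise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EVENT_KINDS = frozenset({"rapid_insulin", "long_insulin", "meal", "smbg"})
SMBG_MIN, SMBG_MAX = 20.0, 600.0

CGM_COLUMNS = ["timestamp", "glucose_mgdl"]
EVENT_COLUMNS = ["timestamp", "kind", "value"]
ACTIVITY_COLUMNS = ["timestamp", "steps", "heart_rate", "calories"]
SLEEP_COLUMNS = ["start", "end"]


class FormatError(ValueError):
    """The file does not conform to the expected CSV dialect."""


class ValidationError(ValueError):
    """Record content violates a domain invariant."""


@dataclass(frozen=True, order=True)
class SleepPeriod:
    """One tracker-reported sleep interval (naive local time)."""

    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValidationError(
                f"sleep period end ({self.end}) must be after start ({self.start})"
            )

    @property
    def duration(self) -> pd.Timedelta:
        return self.end - self.start


def _load_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    return frame


def _drop_bad_rows(frame: pd.DataFrame, bad: pd.Series, path: str | Path, why: str) -> pd.DataFrame:
    if bad.any():
        # +2: one for the header row, one for 0-based indexing
        lines = [int(i) + 2 for i in frame.index[bad]]
        log.warning("%s: skipped %d %s row(s) at line(s) %s", Path(path).name, len(lines), why, lines)
    return frame.loc[~bad]


def _dedupe_sorted(frame: pd.DataFrame, time_col: str, path: str | Path) -> pd.DataFrame:
    frame = frame.sort_values(time_col, kind="stable").reset_index(drop=True)
    dup = frame[time_col].duplicated(keep="first")
    if dup.any():
        log.warning("%s: dropped %d duplicate-timestamp row(s), keeping first", Path(path).name, int(dup.sum()))
        frame = frame.loc[~dup].reset_index(drop=True)
    return frame


def read_cgm_csv(path: str | Path) -> pd.DataFrame:
    """Read a CGM export into a time-sorted ``timestamp,glucose_mgdl`` frame.

    Rows whose timestamp or glucose cell cannot be parsed, or whose glucose
    is not a positive finite number, are skipped (logged with line numbers).
    Duplicate timestamps keep the first occurrence.
    """
    raw = _load_table(path, CGM_COLUMNS)
    if raw.empty:
        return pd.DataFrame({"timestamp": pd.to_datetime([]), "glucose_mgdl": pd.Series([], dtype=float)})
    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    glu = pd.to_numeric(raw["glucose_mgdl"], errors="coerce")
    out = pd.DataFrame({"timestamp": ts, "glucose_mgdl": glu})
    bad = ts.isna() | glu.isna() | ~np.isfinite(glu) | (glu <= 0)
    out = _drop_bad_rows(out, bad, path, "malformed")
    return _dedupe_sorted(out, "timestamp", path)


def read_events_csv(path: str | Path) -> pd.DataFrame:
    """Read the insulin/meal/SMBG event log.

    Invariants enforced by skipping offending rows: insulin and meal values
    strictly positive; SMBG within [20, 600] mg/dL; ``kind`` recognised.
    """
    raw = _load_table(path, EVENT_COLUMNS)
    if raw.empty:
        return pd.DataFrame(
            {"timestamp": pd.to_datetime([]), "kind": pd.Series([], dtype=str), "value": pd.Series([], dtype=float)}
        )
    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    val = pd.to_numeric(raw["value"], errors="coerce")
    kind = raw["kind"].astype(str).str.strip()
    out = pd.DataFrame({"timestamp": ts, "kind": kind, "value": val})
    bad = ts.isna() | val.isna() | ~kind.isin(EVENT_KINDS)
    bad |= kind.isin({"rapid_insulin", "long_insulin", "meal"}) & ~(val > 0)
    bad |= (kind == "smbg") & ((val < SMBG_MIN) | (val > SMBG_MAX))
    out = _drop_bad_rows(out, bad, path, "malformed")
    return out.sort_values("timestamp", kind="stable").reset_index(drop=True)


def read_activity_csv(path: str | Path) -> pd.DataFrame:
    """Read the per-minute steps / heart-rate / calories trace.

    ``heart_rate`` may be empty (sensor off-wrist); steps and calories must
    be nonnegative numbers.
    """
    raw = _load_table(path, ACTIVITY_COLUMNS)
    if raw.empty:
        return pd.DataFrame(
            {
                "timestamp": pd.to_datetime([]),
                "steps": pd.Series([], dtype=float),
                "heart_rate": pd.Series([], dtype=float),
                "calories": pd.Series([], dtype=float),
            }
        )
    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    steps = pd.to_numeric(raw["steps"], errors="coerce")
    hr = pd.to_numeric(raw["heart_rate"], errors="coerce")  # NaN = not worn
    cal = pd.to_numeric(raw["calories"], errors="coerce")
    out = pd.DataFrame({"timestamp": ts, "steps": steps, "heart_rate": hr, "calories": cal})
    bad = ts.isna() | steps.isna() | (steps < 0) | cal.isna() | (cal < 0)
    out = _drop_bad_rows(out, bad, path, "malformed")
    return _dedupe_sorted(out, "timestamp", path)


def read_sleep_csv(path: str | Path) -> list[SleepPeriod]:
    """Read sleep periods, validating that they do not overlap."""
    raw = _load_table(path, SLEEP_COLUMNS)
    if raw.empty:
        return []
    start = pd.to_datetime(raw["start"], errors="coerce", format="ISO8601")
    end = pd.to_datetime(raw["end"], errors="coerce", format="ISO8601")
    out = pd.DataFrame({"start": start, "end": end})
    bad = start.isna() | end.isna() | ~(end > start)
    out = _drop_bad_rows(out, bad, path, "malformed")
    out = out.sort_values("start", kind="stable").reset_index(drop=True)
    prev_end = out["end"].shift(1)
    overlap = out["start"] < prev_end
    if overlap.any():
        i = int(np.flatnonzero(overlap.to_numpy())[0])
        raise ValidationError(
            f"{Path(path).name}: overlapping sleep periods "
            f"({out['start'][i - 1]}–{out['end'][i - 1]}) and ({out['start'][i]}–{out['end'][i]})"
        )
    return [SleepPeriod(s, e) for s, e in zip(out["start"], out["end"])]


# --- writers ---------------------------------------------------------------

_TS_FMT = "%Y-%m-%dT%H:%M:%S"


def _fmt_ts(series: pd.Series) -> pd.Series:
    return pd.to_datetime(series).dt.strftime(_TS_FMT)


def write_cgm_csv(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = pd.DataFrame(
        {"timestamp": _fmt_ts(frame["timestamp"]), "glucose_mgdl": frame["glucose_mgdl"].map(lambda v: f"{v:.1f}")}
        if len(frame)
        else {c: [] for c in CGM_COLUMNS}
    )
    out.to_csv(path, index=False, lineterminator="\n")
    return path


def write_events_csv(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = pd.DataFrame(
        {
            "timestamp": _fmt_ts(frame["timestamp"]),
            "kind": frame["kind"],
            "value": frame["value"].map(lambda v: f"{v:.2f}"),
        }
        if len(frame)
        else {c: [] for c in EVENT_COLUMNS}
    )
    out.to_csv(path, index=False, lineterminator="\n")
    return path


def write_activity_csv(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = pd.DataFrame(
        {
            "timestamp": _fmt_ts(frame["timestamp"]),
            "steps": frame["steps"].map(lambda v: f"{int(v)}"),
            "heart_rate": frame["heart_rate"].map(lambda v: "" if pd.isna(v) else f"{int(round(v))}"),
            "calories": frame["calories"].map(lambda v: f"{v:.2f}"),
        }
        if len(frame)
        else {c: [] for c in ACTIVITY_COLUMNS}
    )
    out.to_csv(path, index=False, lineterminator="\n")
    return path


def write_sleep_csv(periods: list[SleepPeriod], path: str | Path) -> Path:
    path = Path(path)
    rows = [(p.start.strftime(_TS_FMT), p.end.strftime(_TS_FMT)) for p in periods]
    pd.DataFrame(rows, columns=SLEEP_COLUMNS).to_csv(path, index=False, lineterminator="\n")
    return path
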