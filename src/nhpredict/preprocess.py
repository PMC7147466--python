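"""Stream integration: resampling to the common 5-min grid and gap imputation.

All downstream stages work on a shared 5-minute grid (288 points per full
day).  CGM records land on the grid by nearest-neighbour snapping within
half a grid step; interior gaps of at most 120 minutes are filled by
linear interpolation between the bounding measured points, and every grid
point carries a provenance flag (``measured`` / ``imputed`` / ``missing``)
so later stages can choose which points to trust.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

GRID_STEP = pd.Timedelta(minutes=5)
GRID_STEP_MIN = 5
POINTS_PER_DAY = 288
#: longest imputable gap: 120 min between bounding measured points,
#: i.e. at most 23 consecutive missing 5-min points
MAX_IMPUTE_POINTS = 23

MEASURED, IMPUTED, MISSING = "measured", "imputed", "missing"


@dataclass
class GlucoseTrace:
    """Glucose on a uniform 5-min grid with per-point provenance.

    ``glucose`` holds NaN wherever ``provenance == "missing"``.
    """

    grid: pd.DatetimeIndex
    glucose: np.ndarray
    provenance: np.ndarray

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.glucose) or len(self.grid) != len(self.provenance):
            raise ValueError("grid, glucose and provenance must have equal length")
        if len(self.grid) > 1:
            steps = np.diff(self.grid.asi8)
            if not np.all(steps == GRID_STEP.value):
                raise ValueError("grid spacing must be exactly 5 min")

    def __len__(self) -> int:
        return len(self.grid)

    @property
    def is_missing(self) -> np.ndarray:
        return self.provenance == MISSING

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timestamp": self.grid, "glucose_mgdl": self.glucose, "provenance": self.provenance}
        )


def make_grid(origin: pd.Timestamp, end: pd.Timestamp) -> pd.DatetimeIndex:
    """5-min grid from ``origin`` up to the last point <= ``end``."""
    origin = pd.Timestamp(origin)
    n = int((pd.Timestamp(end) - origin) // GRID_STEP) + 1
    return pd.date_range(origin, periods=max(n, 0), freq="5min")


def resample_to_grid(records: pd.DataFrame, grid_origin: pd.Timestamp,
                     grid_end: pd.Timestamp | None = None) -> GlucoseTrace:
    """Snap raw CGM records onto the 5-min grid.

    Each grid point takes the nearest raw record within +/-2.5 min
    (ties resolved toward the earlier record); grid points with no record
    in reach are flagged missing.  One full day of dense records yields
    288 grid points, none missing.
    """
    grid_origin = pd.Timestamp(grid_origin)
    if records.empty:
        if grid_end is None:
            grid = pd.DatetimeIndex([], freq="5min")
            return GlucoseTrace(grid, np.array([], dtype=float), np.array([], dtype=object))
        grid = make_grid(grid_origin, grid_end)
        return GlucoseTrace(grid, np.full(len(grid), np.nan), np.full(len(grid), MISSING, dtype=object))
    times = pd.DatetimeIndex(records["timestamp"])
    if not times.is_monotonic_increasing:
        raise ValueError("records must be time-sorted")
    values = np.asarray(records["glucose_mgdl"], dtype=float)
    if grid_end is None:
        grid_end = times[-1] + GRID_STEP / 2
    grid = make_grid(grid_origin, grid_end)

    t = times.asi8
    g = grid.asi8
    pos = np.searchsorted(t, g)
    left = np.clip(pos - 1, 0, len(t) - 1)
    right = np.clip(pos, 0, len(t) - 1)
    d_left = np.abs(g - t[left])
    d_right = np.abs(t[right] - g)
    use_left = d_left <= d_right  # tie -> earlier record
    idx = np.where(use_left, left, right)
    dist = np.where(use_left, d_left, d_right)
    within = dist <= (GRID_STEP / 2).value

    glucose = np.where(within, values[idx], np.nan)
    provenance = np.where(within, MEASURED, MISSING).astype(object)
    return GlucoseTrace(grid, glucose, provenance)


def impute_gaps(trace: GlucoseTrace) -> GlucoseTrace:
    """Linearly interpolate interior missing runs of <= 120 min.

    A run of ``m`` consecutive missing points sits between measured anchors
    120 min apart when ``m == 23``; longer runs, and runs at either edge of
    the trace (no second anchor), are left missing.  Interpolated points are
    flagged ``imputed`` and always lie within the closed interval spanned by
    their two anchors.
    """
    glucose = trace.glucose.copy()
    provenance = trace.provenance.copy()
    missing = trace.is_missing
    if not missing.any():
        return replace(trace, glucose=glucose, provenance=provenance)

    n = len(trace)
    # run starts/ends over the missing mask
    padded = np.concatenate(([False], missing, [False]))
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])  # exclusive
    for s, e in zip(starts, ends):
        if s == 0 or e == n:
            continue  # edge run: no bounding anchor
        if e - s > MAX_IMPUTE_POINTS:
            continue  # gap longer than 120 min between anchors
        lo, hi = s - 1, e  # bounding non-missing points
        span = hi - lo
        frac = (np.arange(s, e) - lo) / span
        glucose[s:e] = glucose[lo] + frac * (glucose[hi] - glucose[lo])
        provenance[s:e] = IMPUTED
    return replace(trace, glucose=glucose, provenance=provenance)


def align_activity(activity: pd.DataFrame, grid: pd.DatetimeIndex) -> pd.DataFrame:
    """Aggregate per-minute activity rows into the 5-min grid bins.

    Bin ``t`` covers ``[t, t + 5 min)``: steps and calories are summed,
    heart rate is averaged over the rows present.  Bins with no rows get
    zero steps/calories and missing heart rate.
    """
    out = pd.DataFrame(
        {"steps": 0.0, "heart_rate": np.nan, "calories": 0.0}, index=grid
    )
    if activity.empty or len(grid) == 0:
        out.index.name = "timestamp"
        return out.reset_index()
    ts = pd.DatetimeIndex(activity["timestamp"])
    bins = ts.floor("5min")
    keep = (bins >= grid[0]) & (bins <= grid[-1])
    work = activity.loc[np.asarray(keep)].copy()
    work["bin"] = bins[keep]
    agg = work.groupby("bin").agg(
        steps=("steps", "sum"), heart_rate=("heart_rate", "mean"), calories=("calories", "sum")
    )
    out.loc[agg.index, ["steps", "heart_rate", "calories"]] = agg[["steps", "heart_rate", "calories"]].values
    out.index.name = "timestamp"
    return out.reset_index()


def gridded_frame(trace: GlucoseTrace, activity_gridded: pd.DataFrame) -> pd.DataFrame:
    """Canonical per-patient gridded table (CSV-ready)."""
    frame = trace.to_frame()
    merged = frame.merge(activity_gridded, on="timestamp", how="left")
    merged[["steps", "calories"]] = merged[["steps", "calories"]].fillna(0.0)
    return merged
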