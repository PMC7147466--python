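"""Turning nights into labeled learning instances.

Each usable night contributes one instance: a 29-component feature vector
computed from the 6 h of data before sleep onset, and a binary label from
the 6 h after onset (1 if any glucose reading drops below 70 mg/dL, the
nocturnal-hypoglycemia threshold of 3.9 mmol/L).

The 29 features are organised into 11 named groups; the exhaustive model
search operates over subsets of these groups.  Twenty-five features
describe the pre-sleep CGM signal, plus one insulin-on-board feature, one
carbohydrate-on-board feature, and two physical-activity features (AOB and
calories burned), so the breakdown is 25 CGM + 1 IOB + 1 COB + 2 activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SleepPeriod
from .preprocess import GRID_STEP_MIN, GlucoseTrace

log = logging.getLogger(__name__)

HYPO_THRESHOLD = 70.0  # mg/dL == 3.9 mmol/L
WINDOW_MIN = 360  # 6 h feature and label windows
WINDOW_POINTS = WINDOW_MIN // GRID_STEP_MIN  # 72 grid points
#: above-threshold time needed to separate two hypoglycemic episodes
EPISODE_GAP_MIN = 15.0
MIN_COVERAGE = 0.8

#: sleep-onset selection rule: first period of >= 3 h starting in the
#: 20:00-04:00 window defines the night
MIN_SLEEP_HOURS = 3.0
NIGHT_START_HOUR = 20.0
NIGHT_END_HOUR = 4.0

# ordered feature catalog: group name -> feature names
FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "endpoint": ("glucose_at_onset", "mean_last_30min"),
    "central": ("mean_glucose", "median_glucose", "mean_last_hour"),
    "dispersion": ("sd_glucose", "cv_glucose", "iqr_glucose"),
    "extremes": ("min_glucose", "max_glucose", "range_glucose"),
    "rates": ("slope_mgdl_h", "mean_abs_rate_mgdl_h", "max_fall_rate_mgdl_h", "max_rise_rate_mgdl_h"),
    "ranges": ("pct_below_70", "pct_70_180", "pct_above_180", "pct_above_250"),
    "risk": ("lbgi", "hbgi", "auc_below_70"),
    "hypo_history": ("hypo_episode_count", "minutes_since_hypo", "any_hypo"),
    "iob": ("iob_at_onset",),
    "cob": ("cob_at_onset",),
    "activity": ("aob_at_onset", "calories_in_window"),
}

FEATURE_NAMES: tuple[str, ...] = tuple(n for group in FEATURE_GROUPS.values() for n in group)
N_FEATURES = len(FEATURE_NAMES)  # 29
GROUP_NAMES: tuple[str, ...] = tuple(FEATURE_GROUPS)
N_GROUPS = len(GROUP_NAMES)  # 11

#: per-group column indices into the 29-vector
GROUP_INDICES: dict[str, np.ndarray] = {}
_offset = 0
for _g, _names in FEATURE_GROUPS.items():
    GROUP_INDICES[_g] = np.arange(_offset, _offset + len(_names))
    _offset += len(_names)
del _offset, _g, _names


@dataclass
class NightInstance:
    """One night's labeled example."""

    patient_id: str
    night_date: pd.Timestamp
    sleep_onset: pd.Timestamp
    x: np.ndarray  # 29 finite components in FEATURE_NAMES order
    y: int  # 1 = night with hypoglycemia
    coverage_pre: float
    coverage_post: float


def select_nights(sleep: list[SleepPeriod]) -> list[pd.Timestamp]:
    """Pick one sleep onset per calendar night.

    The night's onset is the start of the first sleep period lasting at
    least 3 h that begins between 20:00 and 04:00; a period starting before
    midnight belongs to its start date, one starting after midnight to the
    previous date.  Nights without a qualifying period yield nothing.
    """
    chosen: dict[pd.Timestamp, pd.Timestamp] = {}
    for period in sorted(sleep):
        if period.duration < pd.Timedelta(hours=MIN_SLEEP_HOURS):
            continue
        hour = period.start.hour + period.start.minute / 60 + period.start.second / 3600
        if hour >= NIGHT_START_HOUR:
            night = period.start.normalize()
        elif hour <= NIGHT_END_HOUR:
            night = period.start.normalize() - pd.Timedelta(days=1)
        else:
            continue
        chosen.setdefault(night, period.start)
    return [chosen[k] for k in sorted(chosen)]


def snap_to_grid(onset: pd.Timestamp, grid: pd.DatetimeIndex) -> int:
    """Index of the last grid point at or before ``onset`` (-1 if none)."""
    return int(np.searchsorted(grid.asi8, pd.Timestamp(onset).value, side="right")) - 1


def _symmetric_risk(glucose: np.ndarray) -> np.ndarray:
    """Kovatchev symmetrised log-glucose risk coordinate f(g)."""
    return 1.509 * (np.log(glucose) ** 1.084 - 5.381)


def lbgi_hbgi(glucose: np.ndarray) -> tuple[float, float]:
    """Low/high blood-glucose indices: mean of 10*f(g)^2 over the low
    (f<0) and high (f>0) sides, each averaged over all readings."""
    f = _symmetric_risk(np.asarray(glucose, dtype=float))
    risk = 10.0 * f**2
    lbgi = float(np.where(f < 0, risk, 0.0).mean())
    hbgi = float(np.where(f > 0, risk, 0.0).mean())
    return lbgi, hbgi


def hypo_episodes(times_min: np.ndarray, glucose: np.ndarray) -> list[tuple[float, float]]:
    """Maximal sub-70 episodes as (start, end) minutes.

    Consecutive sub-threshold readings form a run; two runs merge into one
    episode when the above-threshold stretch separating them is shorter
    than 15 min.
    """
    below = glucose < HYPO_THRESHOLD
    runs: list[tuple[float, float]] = []
    start = None
    end = None
    for t, b in zip(times_min, below):
        if b:
            if start is None:
                start = t
            end = t
        else:
            if start is not None:
                runs.append((start, end))
                start = None
    if start is not None:
        runs.append((start, end))
    # merge runs separated by < 15 min above threshold
    merged: list[tuple[float, float]] = []
    for ep in runs:
        if merged and ep[0] - merged[-1][1] < EPISODE_GAP_MIN:
            merged[-1] = (merged[-1][0], ep[1])
        else:
            merged.append(ep)
    return merged


def extract_features(trace: GlucoseTrace, iob: np.ndarray, cob: np.ndarray,
                     aob: np.ndarray, calories: np.ndarray,
                     onset: pd.Timestamp) -> np.ndarray:
    """29-component pre-sleep feature vector in ``FEATURE_NAMES`` order.

    The window is the 72 grid points ending at the onset grid point
    (inclusive), i.e. the 6 h before sleep.  CGM features use the window's
    non-missing readings; on-board features are read off at the onset
    point.  Caller is responsible for the coverage precondition.
    """
    i = snap_to_grid(onset, trace.grid)
    lo = i - (WINDOW_POINTS - 1)
    if lo < 0 or i >= len(trace.grid):
        raise ValueError("pre-sleep window extends outside the trace")
    idx = np.arange(lo, i + 1)
    glu = trace.glucose[idx]
    ok = ~np.isnan(glu)
    g = glu[ok]
    t_min = (trace.grid.asi8[idx][ok] - trace.grid.asi8[i]) / 60e9  # minutes, <= 0
    if g.size < 2:
        raise ValueError("not enough readings in the pre-sleep window")

    onset_t = 0.0
    # endpoint group: last reading at/just before onset, last-30-min mean
    glucose_at_onset = float(g[-1])
    # half-open sub-windows (onset-30, onset] and (onset-60, onset]
    last30 = g[t_min > -30.0]
    mean_last_30 = float(last30.mean()) if last30.size else glucose_at_onset
    last60 = g[t_min > -60.0]
    mean_last_60 = float(last60.mean()) if last60.size else glucose_at_onset

    mean = float(g.mean())
    median = float(np.median(g))
    sd = float(g.std(ddof=1))
    cv = 100.0 * sd / mean
    q75, q25 = np.percentile(g, [75, 25])
    iqr = float(q75 - q25)

    gmin, gmax = float(g.min()), float(g.max())

    hours = t_min / 60.0
    slope = float(np.polyfit(hours, g, 1)[0])  # mg/dL per hour
    dg = np.diff(g)
    dt_h = np.diff(hours)
    rates = dg / dt_h
    mean_abs_rate = float(np.abs(rates).mean())
    max_fall = float(max(0.0, -rates.min()))
    max_rise = float(max(0.0, rates.max()))

    npts = g.size
    pct = lambda m: 100.0 * float(m.sum()) / npts  # noqa: E731
    pct_below_70 = pct(g < 70)
    pct_70_180 = pct((g >= 70) & (g <= 180))
    pct_above_180 = pct(g > 180)
    pct_above_250 = pct(g > 250)

    lbgi, hbgi = lbgi_hbgi(g)
    excursion = np.maximum(0.0, HYPO_THRESHOLD - g)
    auc_below_70 = float(np.trapezoid(excursion, t_min))  # mg/dL * min

    episodes = hypo_episodes(t_min, g)
    n_episodes = float(len(episodes))
    if episodes:
        minutes_since = float(min(WINDOW_MIN, onset_t - episodes[-1][1]))
    else:
        minutes_since = float(WINDOW_MIN)
    any_hypo = 1.0 if episodes else 0.0

    cal_window = float(np.asarray(calories, dtype=float)[idx].sum())

    x = np.array(
        [
            glucose_at_onset, mean_last_30,
            mean, median, mean_last_60,
            sd, cv, iqr,
            gmin, gmax, gmax - gmin,
            slope, mean_abs_rate, max_fall, max_rise,
            pct_below_70, pct_70_180, pct_above_180, pct_above_250,
            lbgi, hbgi, auc_below_70,
            n_episodes, minutes_since, any_hypo,
            float(iob[i]),
            float(cob[i]),
            float(aob[i]), cal_window,
        ],
        dtype=float,
    )
    assert x.shape == (N_FEATURES,)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature value")
    return x


def window_coverage(trace: GlucoseTrace, start_idx: int, n_points: int = WINDOW_POINTS) -> float:
    """Fraction of non-missing points among ``n_points`` from ``start_idx``."""
    idx = np.arange(start_idx, start_idx + n_points)
    if idx[0] < 0 or idx[-1] >= len(trace.grid):
        return 0.0
    return float((~np.isnan(trace.glucose[idx])).mean())


def label_night(trace: GlucoseTrace, onset: pd.Timestamp) -> int:
    """1 if any non-missing reading in the 6 h from onset is < 70 mg/dL."""
    i = snap_to_grid(onset, trace.grid)
    idx = np.arange(i, i + WINDOW_POINTS)
    if idx[0] < 0 or idx[-1] >= len(trace.grid):
        raise ValueError("label window extends outside the trace")
    glu = trace.glucose[idx]
    ok = ~np.isnan(glu)
    return int(bool((glu[ok] < HYPO_THRESHOLD).any()))


def build_dataset(patient_id: str, trace: GlucoseTrace,
                  activity_gridded: pd.DataFrame, sleep: list[SleepPeriod],
                  iob: np.ndarray, cob: np.ndarray, aob: np.ndarray,
                  min_coverage: float = MIN_COVERAGE) -> list[NightInstance]:
    """One labeled instance per usable night.

    Nights are dropped (logged, not raised) when either 6-h window has
    glucose coverage below ``min_coverage`` or extends outside the trace.
    """
    calories = np.asarray(activity_gridded["calories"], dtype=float)
    instances: list[NightInstance] = []
    for onset in select_nights(sleep):
        i = snap_to_grid(onset, trace.grid)
        cov_pre = window_coverage(trace, i - (WINDOW_POINTS - 1))
        cov_post = window_coverage(trace, i)
        if cov_pre < min_coverage or cov_post < min_coverage:
            log.info("%s: night %s discarded (coverage pre=%.2f post=%.2f)",
                     patient_id, onset.date(), cov_pre, cov_post)
            continue
        x = extract_features(trace, iob, cob, aob, calories, onset)
        y = label_night(trace, onset)
        night = onset.normalize() if onset.hour >= 12 else onset.normalize() - pd.Timedelta(days=1)
        instances.append(NightInstance(patient_id, night, onset, x, y, cov_pre, cov_post))
    if not instances:
        log.warning("%s: no usable nights — empty dataset", patient_id)
    return instances


def format_class_count(count: int, total: int) -> str:
    """Table-style class count, e.g. 24 of 104 renders as ``24 (23%)``."""
    pct = int(np.floor(100.0 * count / total + 0.5)) if total else 0
    return f"{count} ({pct}%)"


def class_count_summary(instances: list[NightInstance]) -> pd.DataFrame:
    """Per-patient instance bookkeeping: total, Class 1 and Class 0 counts."""
    frame = pd.DataFrame(
        {"patient_id": [ni.patient_id for ni in instances], "y": [ni.y for ni in instances]}
    )
    rows = []
    for pid, sub in frame.groupby("patient_id", sort=True):
        total = len(sub)
        pos = int(sub["y"].sum())
        rows.append(
            {
                "patient_id": pid,
                "total_instances": total,
                "class_1": format_class_count(pos, total),
                "class_0": format_class_count(total - pos, total),
            }
        )
    return pd.DataFrame(rows)


def instances_to_frame(instances: list[NightInstance]) -> pd.DataFrame:
    """Tidy instances table: ``patient_id,night_date,f1..f29,label,coverage``."""
    cols = {f"f{j + 1}": [ni.x[j] for ni in instances] for j in range(N_FEATURES)}
    return pd.DataFrame(
        {
            "patient_id": [ni.patient_id for ni in instances],
            "night_date": [ni.night_date.date().isoformat() for ni in instances],
            "sleep_onset": [ni.sleep_onset.isoformat() for ni in instances],
            **cols,
            "label": [ni.y for ni in instances],
            "coverage_pre": [ni.coverage_pre for ni in instances],
            "coverage_post": [ni.coverage_post for ni in instances],
        }
    )


def frame_to_matrix(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) arrays from an instances table."""
    X = frame[[f"f{j + 1}" for j in range(N_FEATURES)]].to_numpy(dtype=float)
    y = frame["label"].to_numpy(dtype=int)
    return X, y


def feature_catalog_json() -> dict:
    """Sidecar catalog mapping f1..f29 to names and groups."""
    entries = []
    j = 0
    for group, names in FEATURE_GROUPS.items():
        for name in names:
            entries.append({"column": f"f{j + 1}", "name": name, "group": group})
            j += 1
    return {"n_features": N_FEATURES, "n_groups": N_GROUPS, "features": entries}
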