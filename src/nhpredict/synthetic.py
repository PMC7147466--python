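"""Synthetic free-living T1D data generator.

Emulates the four raw streams a study patient on multiple daily
injections produces over weeks at home: intermittently scanned CGM
glucose (15-min cadence with sensor-dropout gaps), manually logged meals
and insulin doses, per-minute wristband activity, and nightly sleep
periods.

Glucose follows a minimal linear-response model on an internal 5-min
step — not a physiological simulator.  Around a homeostatic set point,
glucose responds additively to the carbohydrate and insulin *appearance*
signals implied by the on-board compartment curves, is drained in
proportion to activity on board, receives an extra nocturnal drift while
asleep (the nocturnal-hypoglycemia propensity knob), and carries AR(1)
measurement-scale noise:

    G[t+1] = G[t] + alpha * (G_set - G[t])
                  + k_meal * dCH_appeared[t]  - k_ins * dIns_appeared[t]
                  - k_act * AOB[t] - drift_night[t] + e[t+1]

with per-night lognormal variation of the nocturnal drift.  The model is
deliberately simple; its purpose is to create learnable structure (the
pre-sleep glucose trajectory, insulin on board and evening activity carry
information about the night ahead) with a controllable fraction of
hypoglycemic nights, defaulting to roughly one third.

All randomness flows from ``SimConfig.seed``; identical configs produce
byte-identical exports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .physio import PhysioParams, aob_profile, onboard_curve
from .preprocess import GRID_STEP_MIN

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A SimConfig field violates its constraint."""


@dataclass(frozen=True)
class MealSpec:
    """One scheduled daily meal: clock time (h), timing jitter (min),
    carbohydrate grams mean/sd."""

    clock_hour: float
    jitter_min: float
    carbs_mean: float
    carbs_sd: float


@dataclass(frozen=True)
class ActivitySpec:
    """One scheduled daily activity bout."""

    clock_hour: float
    jitter_min: float
    duration_min: float
    steps_per_min: float


def _default_meals() -> tuple[MealSpec, ...]:
    return (
        MealSpec(8.0, 20.0, 45.0, 12.0),
        MealSpec(13.5, 30.0, 60.0, 15.0),
        MealSpec(21.5, 30.0, 55.0, 15.0),
    )


def _default_activity() -> tuple[ActivitySpec, ...]:
    return (ActivitySpec(19.0, 45.0, 45.0, 14.0),)


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of one synthetic patient.

    ``basal_overdose`` (mg/dL per 5-min step while asleep) is the
    dimensionless-in-spirit nocturnal-hypoglycemia propensity knob; the
    default is calibrated so that about one third of nights contain a
    sub-70 mg/dL reading.
    """

    n_days: int = 84  # 12 weeks of free living
    meal_schedule: tuple[MealSpec, ...] = field(default_factory=_default_meals)
    insulin_ratio: float = 1.0  # U per 10 g CH
    dose_noise_sd: float = 0.35  # relative dosing error
    basal_overdose: float = 1.4  # nocturnal drift, mg/dL per step
    activity: tuple[ActivitySpec, ...] = field(default_factory=_default_activity)
    sleep_onset_hour: float = 23.5
    sleep_jitter_min: float = 30.0
    sleep_duration_hr: float = 8.0
    sensor_dropout_rate: float = 0.6  # gaps per day
    sensor_gap_mean_min: float = 45.0
    sensor_gap_shape: float = 0.6  # lognormal sigma of gap length
    noise_sd: float = 0.3  # AR(1) innovation sd, mg/dL
    ar_coef: float = 0.85
    night_drift_sigma: float = 0.25  # per-night lognormal spread of the drift
    extra_boluses: tuple[tuple[int, float, float], ...] = ()  # (day, clock h, U)
    seed: int = 0

    def __post_init__(self) -> None:
        checks = {
            "n_days": self.n_days >= 1,
            "insulin_ratio": self.insulin_ratio >= 0,
            "dose_noise_sd": self.dose_noise_sd >= 0,
            "basal_overdose": self.basal_overdose >= 0,
            "sleep_jitter_min": self.sleep_jitter_min >= 0,
            "sleep_duration_hr": self.sleep_duration_hr > 0,
            "sensor_dropout_rate": self.sensor_dropout_rate >= 0,
            "sensor_gap_mean_min": self.sensor_gap_mean_min > 0,
            "noise_sd": self.noise_sd >= 0,
            "ar_coef": 0 <= self.ar_coef < 1,
            "night_drift_sigma": self.night_drift_sigma >= 0,
        }
        for name, ok in checks.items():
            if not ok:
                raise ConfigError(f"invalid value for field {name!r}: {getattr(self, name)}")
        for m in self.meal_schedule:
            if m.carbs_mean <= 0 or m.carbs_sd < 0 or m.jitter_min < 0:
                raise ConfigError(f"invalid value for field 'meal_schedule': {m}")
        for a in self.activity:
            if a.duration_min <= 0 or a.steps_per_min < 0:
                raise ConfigError(f"invalid value for field 'activity': {a}")


@dataclass
class RawDataset:
    """The four raw per-patient streams, pre-preprocessing."""

    cgm: pd.DataFrame
    events: pd.DataFrame
    activity: pd.DataFrame
    sleep: list[nio.SleepPeriod]


# linear-response gains (mg/dL per g CH, per U insulin, per AOB step-unit)
K_MEAL = 3.5
K_INS = 35.0
K_ACT = 0.002
ALPHA = 0.025  # homeostatic pull per 5-min step
G_SET = 150.0
GLUCOSE_MIN, GLUCOSE_MAX = 40.0, 400.0
CGM_CADENCE_MIN = 15  # sensor-scan cadence before resampling
SMBG_NOISE_SD = 6.0
LONG_INSULIN_HOUR = 22.0
LONG_INSULIN_UNITS = 20.0


def _appeared_cumulative(event_min: np.ndarray, amounts: np.ndarray,
                         grid_min: np.ndarray, tau: float) -> np.ndarray:
    """Cumulative amount appeared in plasma at each grid time."""
    out = np.zeros(len(grid_min))
    for t0, amount in zip(event_min, amounts):
        dt = grid_min - t0
        active = dt >= 0
        out[active] += amount * (1.0 - onboard_curve(dt[active], tau))
    return out


def simulate_patient(config: SimConfig, physio: PhysioParams = PhysioParams()) -> RawDataset:
    """Generate one patient's raw streams.

    The simulation spans ``n_days`` full days plus the following morning so
    the last night's sleep is fully covered; there is exactly one sleep
    period per night.
    """
    rng = np.random.default_rng(config.seed)
    origin = pd.Timestamp("2019-01-01 00:00:00")
    span_min = config.n_days * 1440 + 720  # + next morning
    grid_min = np.arange(0, span_min + GRID_STEP_MIN, GRID_STEP_MIN, dtype=float)
    n = len(grid_min)
    grid = origin + pd.to_timedelta(grid_min, unit="m")

    # --- logged events -----------------------------------------------------
    meal_t, meal_g = [], []
    bolus_t, bolus_u = [], []
    long_t = []
    for day in range(config.n_days):
        for meal in config.meal_schedule:
            t = day * 1440 + meal.clock_hour * 60 + rng.normal(0, meal.jitter_min)
            carbs = max(10.0, rng.normal(meal.carbs_mean, meal.carbs_sd))
            carbs = float(np.round(carbs))
            dose = carbs / 10.0 * config.insulin_ratio * (1.0 + rng.normal(0, config.dose_noise_sd))
            dose = max(0.5, float(np.round(dose, 1)))
            meal_t.append(t)
            meal_g.append(carbs)
            bolus_t.append(t - 2.0)  # bolus logged just before eating
            bolus_u.append(dose)
        long_t.append(day * 1440 + LONG_INSULIN_HOUR * 60)
    for day, clock_hour, units in config.extra_boluses:
        bolus_t.append(day * 1440 + clock_hour * 60)
        bolus_u.append(float(units))
    meal_t, meal_g = np.array(meal_t), np.array(meal_g)
    bolus_t, bolus_u = np.array(bolus_t), np.array(bolus_u)

    # --- sleep -------------------------------------------------------------
    sleep: list[nio.SleepPeriod] = []
    sleep_bounds = []
    for day in range(config.n_days):
        onset = day * 1440 + config.sleep_onset_hour * 60 + rng.normal(0, config.sleep_jitter_min)
        duration = max(240.0, config.sleep_duration_hr * 60 + rng.normal(0, 20.0))
        onset = float(np.round(onset))
        end = float(np.round(onset + duration))
        sleep.append(nio.SleepPeriod(origin + pd.Timedelta(minutes=onset),
                                     origin + pd.Timedelta(minutes=end)))
        sleep_bounds.append((onset, end))

    asleep = np.zeros(n, dtype=bool)
    night_factor = np.zeros(n)
    for onset, end in sleep_bounds:
        factor = float(np.exp(rng.normal(0, config.night_drift_sigma)
                              - config.night_drift_sigma**2 / 2))
        mask = (grid_min >= onset) & (grid_min < end)
        asleep |= mask
        night_factor[mask] = factor

    # --- per-minute activity ----------------------------------------------
    minutes = np.arange(span_min + 1)
    steps_min = np.zeros(len(minutes))
    awake_min = np.ones(len(minutes), dtype=bool)
    for onset, end in sleep_bounds:
        lo, hi = int(onset), min(int(end), len(minutes))
        awake_min[lo:hi] = False
    steps_min[awake_min] = rng.poisson(0.2, int(awake_min.sum()))
    for day in range(config.n_days):
        for bout in config.activity:
            start = int(day * 1440 + bout.clock_hour * 60 + rng.normal(0, bout.jitter_min))
            stop = min(start + int(bout.duration_min), len(minutes))
            if start < 0 or start >= len(minutes):
                continue
            steps_min[start:stop] += rng.poisson(bout.steps_per_min, stop - start)

    steps_grid = np.add.reduceat(steps_min[:-1], np.arange(0, span_min, GRID_STEP_MIN))
    steps_grid = np.append(steps_grid, steps_min[-1])
    aob = aob_profile(steps_grid, grid, PhysioParams(tau_act=physio.tau_act))

    # --- glucose dynamics --------------------------------------------------
    appeared_ch = _appeared_cumulative(meal_t, meal_g, grid_min, physio.tau_ch)
    appeared_ins = _appeared_cumulative(bolus_t, bolus_u, grid_min, physio.tau_ins)
    d_ch = np.diff(appeared_ch, prepend=0.0)
    d_ins = np.diff(appeared_ins, prepend=0.0)

    innovations = rng.normal(0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)
    glucose = np.empty(n)
    glucose[0] = G_SET
    e = 0.0
    for t in range(1, n):
        e = config.ar_coef * e + innovations[t]
        drift = config.basal_overdose * night_factor[t] if asleep[t] else 0.0
        g = (
            glucose[t - 1]
            + ALPHA * (G_SET - glucose[t - 1])
            + K_MEAL * d_ch[t]
            - K_INS * d_ins[t]
            - K_ACT * aob[t - 1]
            - drift
            + e
        )
        glucose[t] = min(max(g, GLUCOSE_MIN), GLUCOSE_MAX)

    # --- CGM records: 15-min cadence, sensor noise, dropout gaps -----------
    cadence = CGM_CADENCE_MIN // GRID_STEP_MIN
    scan_idx = np.arange(0, n, cadence)
    sensor_noise = rng.normal(0, 0.5 * config.noise_sd, len(scan_idx)) if config.noise_sd > 0 else 0.0
    cgm_values = np.clip(np.round(glucose[scan_idx] + sensor_noise, 1), GLUCOSE_MIN, GLUCOSE_MAX)
    cgm_minutes = grid_min[scan_idx]
    keep = np.ones(len(scan_idx), dtype=bool)
    for day in range(config.n_days + 1):
        for _ in range(rng.poisson(config.sensor_dropout_rate)):
            start = day * 1440 + rng.uniform(0, 1440)
            mu = np.log(config.sensor_gap_mean_min) - config.sensor_gap_shape**2 / 2
            length = float(rng.lognormal(mu, config.sensor_gap_shape))
            keep &= ~((cgm_minutes >= start) & (cgm_minutes < start + length))
    cgm = pd.DataFrame(
        {"timestamp": grid[scan_idx[keep]], "glucose_mgdl": cgm_values[keep]}
    ).reset_index(drop=True)

    # --- SMBG: fingerstick shortly before each meal -------------------------
    smbg_t = meal_t - 5.0
    smbg_idx = np.clip(np.round(smbg_t / GRID_STEP_MIN).astype(int), 0, n - 1)
    smbg_noise = rng.normal(0, SMBG_NOISE_SD, len(smbg_t)) if config.noise_sd > 0 else np.zeros(len(smbg_t))
    smbg_v = np.clip(np.round(glucose[smbg_idx] + smbg_noise), nio.SMBG_MIN, nio.SMBG_MAX)

    # --- event log ----------------------------------------------------------
    def _rows(times, kinds, values):
        return pd.DataFrame(
            {
                "timestamp": origin + pd.to_timedelta(np.round(times), unit="m"),
                "kind": kinds,
                "value": np.round(values, 2),
            }
        )

    events = pd.concat(
        [
            _rows(meal_t, "meal", meal_g),
            _rows(bolus_t, "rapid_insulin", bolus_u),
            _rows(np.array(long_t), "long_insulin", np.full(len(long_t), LONG_INSULIN_UNITS)),
            _rows(smbg_t, "smbg", smbg_v),
        ],
        ignore_index=True,
    ).sort_values(["timestamp", "kind"], kind="stable").reset_index(drop=True)
    # enforce strictly increasing timestamps within the stream
    ts = events["timestamp"].to_numpy().copy()
    one_min = np.timedelta64(60, "s")
    for i in range(1, len(ts)):
        if ts[i] <= ts[i - 1]:
            ts[i] = ts[i - 1] + one_min
    events["timestamp"] = ts

    # --- per-minute activity table ------------------------------------------
    hr = 60.0 + 0.5 * steps_min + rng.normal(0, 3.0, len(minutes))
    activity = pd.DataFrame(
        {
            "timestamp": origin + pd.to_timedelta(minutes, unit="m"),
            "steps": steps_min.astype(int).astype(float),
            "heart_rate": np.round(hr),
            "calories": np.round(1.2 + 0.06 * steps_min, 2),
        }
    )

    return RawDataset(cgm=cgm, events=events, activity=activity, sleep=sleep)


def write_raw_exports(data: RawDataset, directory: str | Path) -> list[Path]:
    """Write the four raw CSVs; output round-trips through the readers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return [
        nio.write_cgm_csv(data.cgm, directory / "cgm.csv"),
        nio.write_events_csv(data.events, directory / "events.csv"),
        nio.write_activity_csv(data.activity, directory / "activity.csv"),
        nio.write_sleep_csv(data.sleep, directory / "sleep.csv"),
    ]


def read_raw_exports(directory: str | Path) -> RawDataset:
    """Inverse of :func:`write_raw_exports`."""
    directory = Path(directory)
    return RawDataset(
        cgm=nio.read_cgm_csv(directory / "cgm.csv"),
        events=nio.read_events_csv(directory / "events.csv"),
        activity=nio.read_activity_csv(directory / "activity.csv"),
        sleep=nio.read_sleep_csv(directory / "sleep.csv"),
    )


def cohort_configs(n_patients: int, base_seed: int, n_days: int = 84,
                   **overrides) -> list[tuple[str, SimConfig]]:
    """Convenience: per-patient configs with distinct seeds and mildly
    varied NH propensity, mimicking a heterogeneous cohort."""
    rng = np.random.default_rng(base_seed)
    out = []
    for i in range(n_patients):
        cfg = SimConfig(n_days=n_days, seed=int(base_seed + 1000 + i), **overrides)
        propensity = float(np.round(cfg.basal_overdose * rng.uniform(0.6, 1.5), 3))
        cfg = replace(cfg, basal_overdose=propensity)
        out.append((f"S{i + 1:02d}", cfg))
    return out
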