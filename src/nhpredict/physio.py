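"""On-board physiological effect signals: IOB, COB and AOB.

Insulin on board (IOB) and carbohydrate on board (COB) represent the part
of a past rapid-acting bolus (U) or announced meal (g CH) whose effect has
not yet appeared in plasma.  Both use the classic two-compartment impulse
response with equal time constants: a unit impulse at elapsed time ``t``
still has

    h(t) = exp(-t / tau) * (1 + t / tau)

on board, which starts at 1, decays smoothly to 0, and superposes linearly
across events.  Activity on board (AOB) accumulates step counts with a
first-order exponential forgetting factor, capturing the lingering
glucose-lowering effect of earlier physical activity.

Long-acting (basal) insulin doses are deliberately excluded from IOB —
the model applies to fast-acting prandial doses only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PhysioParams:
    """Time constants (minutes) of the three on-board models."""

    tau_ins: float = 75.0
    tau_ch: float = 40.0
    tau_act: float = 120.0

    def __post_init__(self) -> None:
        for name in ("tau_ins", "tau_ch", "tau_act"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


def onboard_curve(elapsed_min: np.ndarray, tau: float) -> np.ndarray:
    """Fraction of a unit impulse still on board after ``elapsed_min`` >= 0."""
    x = np.asarray(elapsed_min, dtype=float) / tau
    out = np.exp(-x) * (1.0 + x)
    return np.where(x >= 0, out, 0.0)


def _impulse_onboard(times: pd.DatetimeIndex, amounts: np.ndarray,
                     grid: pd.DatetimeIndex, tau: float) -> np.ndarray:
    out = np.zeros(len(grid), dtype=float)
    if len(times) == 0:
        return out
    g_min = grid.asi8 / 60e9
    t_min = times.asi8 / 60e9
    for t0, amount in zip(t_min, np.asarray(amounts, dtype=float)):
        dt = g_min - t0
        active = dt >= 0
        out[active] += amount * onboard_curve(dt[active], tau)
    return out


def _select_events(events: pd.DataFrame, kind: str) -> pd.DataFrame:
    if "kind" in events.columns:
        events = events.loc[events["kind"] == kind]
    return events


def iob_profile(doses: pd.DataFrame, grid: pd.DatetimeIndex, params: PhysioParams) -> np.ndarray:
    """Insulin on board (U) from rapid-acting doses, on the grid.

    ``doses`` is an event frame (``timestamp,value``, optionally with a
    ``kind`` column from which only ``rapid_insulin`` rows are used).
    """
    doses = _select_events(doses, "rapid_insulin")
    values = np.asarray(doses["value"], dtype=float) if len(doses) else np.array([])
    if (values < 0).any():
        raise ValueError("insulin doses must be nonnegative")
    return _impulse_onboard(pd.DatetimeIndex(doses["timestamp"]) if len(doses) else pd.DatetimeIndex([]),
                            values, grid, params.tau_ins)


def cob_profile(meals: pd.DataFrame, grid: pd.DatetimeIndex, params: PhysioParams) -> np.ndarray:
    """Carbohydrate on board (g): consumed CH not yet appeared in plasma."""
    meals = _select_events(meals, "meal")
    values = np.asarray(meals["value"], dtype=float) if len(meals) else np.array([])
    if (values < 0).any():
        raise ValueError("meal carbohydrate must be nonnegative")
    return _impulse_onboard(pd.DatetimeIndex(meals["timestamp"]) if len(meals) else pd.DatetimeIndex([]),
                            values, grid, params.tau_ch)


def aob_profile(steps: np.ndarray, grid: pd.DatetimeIndex, params: PhysioParams) -> np.ndarray:
    """Activity on board: leaky accumulation of gridded step counts.

    AOB(t) = sum_{k <= t} steps(k) * exp(-(t - k) / tau_act), evaluated
    recursively, so a bin's own steps enter with weight 1.
    """
    steps = np.asarray(steps, dtype=float)
    if len(steps) != len(grid):
        raise ValueError("steps must be aligned with the grid")
    if (steps < 0).any():
        raise ValueError("step counts must be nonnegative")
    if len(grid) == 0:
        return np.zeros(0)
    step_min = 5.0 if len(grid) < 2 else (grid.asi8[1] - grid.asi8[0]) / 60e9
    decay = float(np.exp(-step_min / params.tau_act))
    out = np.empty_like(steps)
    acc = 0.0
    for i, s in enumerate(steps):
        acc = acc * decay + s
        out[i] = acc
    return out
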