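"""Per-patient CGM summary statistics (glucometrics).

The summary row for a patient covers the whole monitored period: mean and
SD of glucose (mg/dL), coefficient of variation (%), and time-in-range
percentages.  Range conventions follow consensus CGM reporting: 70-180 is
the closed interval [70, 180]; the hypoglycemia cuts (<70, <54) and the
hyperglycemia cuts (>180, >250) are strict, so boundary readings at 70/180
count as in range and 250 counts as >180 but not >250.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .preprocess import MISSING, GlucoseTrace


class InsufficientDataError(ValueError):
    """Raised when a trace has no usable readings."""


@dataclass(frozen=True)
class GlucometricsRow:
    mean_cgm: float
    std_cgm: float
    cv_pct: float
    pct_70_180: float
    pct_below_70: float
    pct_below_54: float
    pct_above_180: float
    pct_above_250: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


COLUMNS = [f.name for f in fields(GlucometricsRow)]


def summarize_values(values: np.ndarray) -> GlucometricsRow:
    """Glucometrics over an array of glucose readings (mg/dL, no NaN)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InsufficientDataError("no usable glucose readings")
    mean = float(values.mean())
    std = float(values.std(ddof=1)) if values.size > 1 else 0.0
    pct = lambda mask: 100.0 * float(mask.sum()) / values.size  # noqa: E731
    return GlucometricsRow(
        mean_cgm=mean,
        std_cgm=std,
        cv_pct=100.0 * std / mean,
        pct_70_180=pct((values >= 70) & (values <= 180)),
        pct_below_70=pct(values < 70),
        pct_below_54=pct(values < 54),
        pct_above_180=pct(values > 180),
        pct_above_250=pct(values > 250),
    )


def summarize_trace(trace: GlucoseTrace, include_imputed: bool = True) -> GlucometricsRow:
    """Glucometrics over a gridded trace's non-missing readings.

    ``include_imputed=False`` restricts to directly measured points.
    """
    if include_imputed:
        keep = trace.provenance != MISSING
    else:
        keep = trace.provenance == "measured"
    return summarize_values(trace.glucose[keep])


def cohort_median(rows: list[GlucometricsRow]) -> GlucometricsRow:
    """Columnwise sample median across patients.

    Even cohort sizes use the mean of the two central order statistics.
    """
    if not rows:
        raise InsufficientDataError("no rows to summarise")
    table = np.array([[getattr(r, c) for c in COLUMNS] for r in rows], dtype=float)
    med = np.median(table, axis=0)
    return GlucometricsRow(**dict(zip(COLUMNS, (float(v) for v in med))))


def glucometrics_table(rows: dict[str, GlucometricsRow], median_label: str = "Median") -> pd.DataFrame:
    """Cohort table with one row per patient plus a cohort-median row."""
    records = {pid: row.as_dict() for pid, row in rows.items()}
    records[median_label] = cohort_median(list(rows.values())).as_dict()
    frame = pd.DataFrame.from_dict(records, orient="index")[COLUMNS]
    frame.index.name = "patient_id"
    return frame.round(2)
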