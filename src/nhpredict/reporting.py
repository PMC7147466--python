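"""Report tables: per-patient model results, cohort medians, and the
expected clinical effect of acting on the predictions.

Percentages are rendered to two decimals and counts as integers throughout,
so parsing a rendered table recovers the numeric records exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

METRIC_COLUMNS = ["sensitivity", "specificity", "accuracy", "gmean"]


@dataclass(frozen=True)
class PatientReport:
    """Best-subset cross-validated performance for one patient/classifier."""

    patient_id: str
    classifier: str
    sensitivity: float
    specificity: float
    accuracy: float
    gmean: float
    n_class1: int
    n_class0: int
    selected_groups: tuple[str, ...]

    def __post_init__(self) -> None:
        for c in METRIC_COLUMNS:
            v = getattr(self, c)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{c} must be a percentage in [0, 100], got {v}")


def reports_table(reports: list[PatientReport]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "classifier": r.classifier,
            "n_class1": r.n_class1,
            "n_class0": r.n_class0,
            **{c: round(getattr(r, c), 2) for c in METRIC_COLUMNS},
            "selected_groups": "+".join(r.selected_groups),
        }
        for r in reports
    ]
    return pd.DataFrame(rows)


def cohort_medians(table: pd.DataFrame, columns: list[str] | None = None) -> pd.Series:
    """Columnwise sample median over patients, rounded to 2 decimals.

    Even cohort sizes take the mean of the two central order statistics.
    """
    if table.empty:
        raise ValueError("no reports to summarise")
    columns = columns or [c for c in METRIC_COLUMNS if c in table.columns]
    med = table[columns].astype(float).median(axis=0)
    return med.round(2)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def expected_intervention_counts(sn: float, sp: float, n_pos: int, n_neg: int) -> tuple[int, int, int, int]:
    """Expected (TP, FN, FP, TN) night counts if the model ran prospectively.

    With sensitivity ``sn`` % over ``n_pos`` hypoglycemic nights and
    specificity ``sp`` % over ``n_neg`` event-free nights, the nearest-
    integer expected counts answer "how many nights with hypoglycemia would
    be caught, and how many false alarms raised".
    """
    for name, v in (("sn", sn), ("sp", sp)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must be in [0, 100], got {v}")
    if n_pos < 0 or n_neg < 0:
        raise ValueError("night counts must be nonnegative")
    tp = _round_half_up(sn * n_pos / 100.0)
    fp = _round_half_up((100.0 - sp) * n_neg / 100.0)
    return tp, n_pos - tp, fp, n_neg - fp


def accuracy_from_rates(sn: float, sp: float, n_pos: int, n_neg: int) -> float:
    """Count-weighted accuracy implied by SN/SP and the class sizes (%)."""
    if n_pos + n_neg == 0:
        raise ValueError("n_pos + n_neg must be positive")
    return round((sn * n_pos + sp * n_neg) / (n_pos + n_neg), 2)


def render_markdown(table: pd.DataFrame, float_fmt: str = "%.2f") -> str:
    """Simple pipe-table rendering without extra dependencies."""
    def fmt(v):
        if isinstance(v, (float, np.floating)):
            return float_fmt % v
        return str(v)

    header = "| " + " | ".join(table.columns) + " |"
    sep = "| " + " | ".join("---" for _ in table.columns) + " |"
    body = ["| " + " | ".join(fmt(v) for v in row) + " |" for row in table.itertuples(index=False)]
    return "\n".join([header, sep, *body]) + "\n"
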