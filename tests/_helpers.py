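"""Shared construction helpers for the test suite."""

import numpy as np
import pandas as pd

from nhpredict.preprocess import IMPUTED, MEASURED, MISSING, GlucoseTrace


def make_trace(values, start="2019-01-01 00:00", provenance=None) -> GlucoseTrace:
    """Gridded trace from a value list; NaN entries become missing points."""
    values = np.asarray(values, dtype=float)
    grid = pd.date_range(start, periods=len(values), freq="5min")
    if provenance is None:
        provenance = np.where(np.isnan(values), MISSING, MEASURED).astype(object)
    else:
        provenance = np.asarray(provenance, dtype=object)
    return GlucoseTrace(grid, values, provenance)


def records_frame(times, values) -> pd.DataFrame:
    return pd.DataFrame({"timestamp": pd.to_datetime(list(times)), "glucose_mgdl": list(values)})
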