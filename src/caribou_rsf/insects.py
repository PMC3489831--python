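"""Mosquito and oestrid-fly activity indices from temperature and wind.

The indices rise with temperature and fall with wind, anchored at the
published corner conditions: activity is maximal (index 1) at calm wind and
temperature above 18 degC for both taxa; minimal (index 0) below 6 degC with
wind above 6 m/s for mosquitoes, and below 13 degC with wind above 9 m/s
for oestrid flies.  Between the corners the index is the product of linear
temperature and wind ramps — the minimal separable form consistent with the
corners and with intermediate values scaling by distance from the optimum.
The exact historical functional form was not published; the parameters are
isolated in :class:`InsectIndexParams` so an alternative can be swapped in.

A caribou location is classified as a high-harassment ("high") period if the
index exceeds 0.5 at *either* weather station at any record in the 12 hours
preceding the fix (half-open window, strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["InsectIndexParams", "MOSQUITO", "FLY", "activity_index", "classify_period", "classify_fixes"]


@dataclass(frozen=True)
class InsectIndexParams:
    species: str
    temp_hi: float = 18.0
    temp_lo: float = 6.0
    wind_lo: float = 0.0
    wind_hi: float = 6.0
    threshold: float = 0.5
    lookback_hours: float = 12.0

    def __post_init__(self) -> None:
        if not self.temp_lo < self.temp_hi:
            raise ValueError("temp_lo must be below temp_hi")
        if not self.wind_lo < self.wind_hi:
            raise ValueError("wind_lo must be below wind_hi")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


MOSQUITO = InsectIndexParams(species="mosquito", temp_lo=6.0, wind_hi=6.0)
FLY = InsectIndexParams(species="fly", temp_lo=13.0, wind_hi=9.0)

#: Sensitivity variant: local evidence of mosquito flight ceasing above 4 m/s.
MOSQUITO_WIND4 = InsectIndexParams(species="mosquito", temp_lo=6.0, wind_hi=4.0)


def activity_index(temp_c, wind_ms, params: InsectIndexParams):
    """Bilinear activity index in [0, 1].

    ``clamp01((T - temp_lo)/(temp_hi - temp_lo)) * clamp01((wind_hi - W)/(wind_hi - wind_lo))``
    — 1 at (T >= temp_hi, W <= wind_lo), 0 whenever T <= temp_lo or
    W >= wind_hi, non-decreasing in T and non-increasing in W everywhere.
    """
    t = np.asarray(temp_c, dtype=float)
    w = np.asarray(wind_ms, dtype=float)
    t_score = np.clip((t - params.temp_lo) / (params.temp_hi - params.temp_lo), 0.0, 1.0)
    w_score = np.clip((params.wind_hi - w) / (params.wind_hi - params.wind_lo), 0.0, 1.0)
    out = np.clip(t_score * w_score, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def classify_period(fix_timestamp, weather: pd.DataFrame, params: InsectIndexParams) -> str:
    """Classify one fix time as 'high', 'low', or 'unknown' (no weather)."""
    return classify_fixes(pd.Series([pd.Timestamp(fix_timestamp)]), weather, params)[0]


def classify_fixes(timestamps: pd.Series, weather: pd.DataFrame, params: InsectIndexParams) -> np.ndarray:
    """Vectorized high/low classification over many fix timestamps.

    'high' iff any record of any station in ``(t - lookback, t]`` has index
    strictly above ``params.threshold``; 'low' otherwise; 'unknown' if the
    window contains no weather record at all.
    """
    w = weather.sort_values("timestamp", kind="stable")
    wt = pd.to_datetime(w["timestamp"], utc=True).astype("int64").to_numpy()
    idx = np.asarray(activity_index(w["temp_c"].to_numpy(), w["wind_ms"].to_numpy(), params))

    ts = pd.to_datetime(pd.Series(timestamps).reset_index(drop=True), utc=True).astype("int64").to_numpy()
    lb = int(params.lookback_hours * 3600 * 1e9)

    out = np.empty(len(ts), dtype=object)
    # half-open window (t - lookback, t]
    lo = np.searchsorted(wt, ts - lb, side="right")
    hi = np.searchsorted(wt, ts, side="right")
    for i in range(len(ts)):
        if hi[i] <= lo[i]:
            out[i] = "unknown"
        elif np.any(idx[lo[i]:hi[i]] > params.threshold):
            out[i] = "high"
        else:
            out[i] = "low"
    return out


def add_insect_state(fixes: pd.DataFrame, weather: pd.DataFrame, params: InsectIndexParams, column: str = "insect_state") -> pd.DataFrame:
    """Return a copy of ``fixes`` with an insect_state column appended."""
    out = fixes.copy()
    out[column] = classify_fixes(out["timestamp"], weather, params)
    return out
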