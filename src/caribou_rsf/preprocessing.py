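"""GPS fix screening, sedentary filtering, and biological-season partitioning.

Screening removes 2D fixes, fixes with positional dilution of precision
(PDOP) strictly greater than 10, duplicate timestamps, non-finite
coordinates, and physically implausible jumps (implied speed > 50 km/h).
The sedentary filter drops relocations within 25 m of the previously
retained fix, keeping the first location of each sedentary bout, to thin
serial autocorrelation before model fitting.

Seasons follow the herd's summer calendar: calving (Jun 1-15), post-calving
(Jun 16-30), mosquito harassment (Jul 1-15), oestrid fly harassment
(Jul 16 - Aug 7), late summer (Aug 8 - Sep 15).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.prepared import prep

__all__ = [
    "FIX_COLUMNS",
    "SeasonCalendar",
    "DEFAULT_CALENDAR",
    "TrackSet",
    "ScreenReport",
    "read_fixes_csv",
    "write_fixes_csv",
    "screen_fixes",
    "filter_sedentary",
    "assign_seasons",
    "flag_herd_switch",
    "vegetation_bias_report",
]

FIX_COLUMNS = ("animal_id", "timestamp", "x", "y", "fix_dim", "pdop")

#: Speed above which a fix is treated as an erroneous point (km/h).
MAX_SPEED_KMH = 50.0


@dataclass(frozen=True)
class SeasonCalendar:
    """Month-day season windows (inclusive on both ends), within one year."""

    windows: tuple = (
        ("calving", (6, 1), (6, 15)),
        ("post_calving", (6, 16), (6, 30)),
        ("mosquito", (7, 1), (7, 15)),
        ("oestrid_fly", (7, 16), (8, 7)),
        ("late_summer", (8, 8), (9, 15)),
    )
    #: Local-time offset from UTC in hours; season boundaries are local dates.
    utc_offset_hours: int = -8

    def __post_init__(self) -> None:
        prev_end = (0, 0)
        for name, start, end in self.windows:
            if not (prev_end < start <= end):
                raise ValueError(f"season windows must be ordered and non-overlapping (at {name!r})")
            prev_end = end

    def season_of(self, timestamps: pd.Series) -> pd.Series:
        """Season label per timestamp, or 'off_season'."""
        ts = pd.to_datetime(timestamps, utc=True) + pd.Timedelta(hours=self.utc_offset_hours)
        md = ts.dt.month * 100 + ts.dt.day
        out = pd.Series("off_season", index=timestamps.index, dtype=object)
        for name, (m1, d1), (m2, d2) in self.windows:
            mask = (md >= m1 * 100 + d1) & (md <= m2 * 100 + d2)
            out[mask] = name
        return out

    @property
    def names(self) -> tuple:
        return tuple(name for name, _, _ in self.windows)


DEFAULT_CALENDAR = SeasonCalendar()


@dataclass
class TrackSet:
    """GPS fixes plus per animal-year metadata.

    ``fixes`` has the FIX_COLUMNS schema (plus derived columns such as
    ``season`` once assigned); ``meta`` has one row per animal-year with
    ``parturient`` in {yes, no, unknown} and ``excluded_herd_switch``.
    """

    fixes: pd.DataFrame
    meta: pd.DataFrame = dc_field(default_factory=lambda: pd.DataFrame(
        columns=["animal_id", "year", "parturient", "excluded_herd_switch"]
    ))

    def __post_init__(self) -> None:
        missing = [c for c in ("animal_id", "timestamp", "x", "y") if c not in self.fixes.columns]
        if missing and len(self.fixes):
            raise ValueError(f"fixes missing required columns: {missing}")

    def copy_with(self, fixes: pd.DataFrame) -> "TrackSet":
        return TrackSet(fixes=fixes.reset_index(drop=True), meta=self.meta.copy())

    def analysis_fixes(self) -> pd.DataFrame:
        """Fixes excluding animal-years flagged as herd switches."""
        if "excluded_herd_switch" not in self.meta.columns or not len(self.meta):
            return self.fixes
        excluded = self.meta.loc[self.meta["excluded_herd_switch"].astype(bool)]
        if not len(excluded):
            return self.fixes
        years = self.fixes["timestamp"].dt.year
        drop = pd.Series(False, index=self.fixes.index)
        for _, row in excluded.iterrows():
            drop |= (self.fixes["animal_id"] == row["animal_id"]) & (years == row["year"])
        return self.fixes.loc[~drop].reset_index(drop=True)


@dataclass
class ScreenReport:
    """Counts of fixes removed by each screening rule."""

    n_input: int
    n_retained: int
    removed: dict

    @property
    def removal_fraction(self) -> float:
        return 0.0 if self.n_input == 0 else 1.0 - self.n_retained / self.n_input

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "removal_fraction": self.removal_fraction,
            "removed": self.removed,
        }
        s = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


def read_fixes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def write_fixes_csv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------


def screen_fixes(raw, pdop_max: float = 10.0, max_speed_kmh: float = MAX_SPEED_KMH):
    """Screen raw fixes; returns ``(TrackSet, ScreenReport)``.

    Removal rules, applied per animal in time order: non-finite coordinates,
    2D fixes, PDOP strictly greater than ``pdop_max``, duplicate timestamps
    (first kept), and fixes implying travel faster than ``max_speed_kmh``
    from the previous retained fix.
    """
    if isinstance(raw, TrackSet):
        meta = raw.meta
        df = raw.fixes
    else:
        meta = None
        df = pd.DataFrame(raw, columns=list(FIX_COLUMNS)) if not isinstance(raw, pd.DataFrame) else raw

    removed = {"nonfinite": 0, "fix_2d": 0, "pdop": 0, "duplicate_timestamp": 0, "speed": 0}
    n_input = len(df)
    if n_input == 0:
        ts = TrackSet(fixes=df.copy(), meta=meta if meta is not None else TrackSet(pd.DataFrame()).meta)
        return ts, ScreenReport(0, 0, removed)

    df = df.sort_values(["animal_id", "timestamp"], kind="stable").reset_index(drop=True)

    finite = np.isfinite(df["x"].to_numpy(float)) & np.isfinite(df["y"].to_numpy(float))
    removed["nonfinite"] = int((~finite).sum())
    df = df.loc[finite]

    if "fix_dim" in df.columns:
        is2d = df["fix_dim"].astype(str).str.upper() == "2D"
        removed["fix_2d"] = int(is2d.sum())
        df = df.loc[~is2d]
    if "pdop" in df.columns:
        bad = df["pdop"].to_numpy(float) > pdop_max  # strict: pdop == max is retained
        removed["pdop"] = int(bad.sum())
        df = df.loc[~bad]

    dup = df.duplicated(subset=["animal_id", "timestamp"], keep="first")
    removed["duplicate_timestamp"] = int(dup.sum())
    df = df.loc[~dup]

    # speed screen, per animal against the previous *retained* fix
    keep_idx = []
    for _, g in df.groupby("animal_id", sort=False):
        x = g["x"].to_numpy(float)
        y = g["y"].to_numpy(float)
        t = g["timestamp"].astype("int64").to_numpy() / 1e9  # seconds
        keep = np.ones(len(g), dtype=bool)
        last = 0
        for i in range(1, len(g)):
            dt = t[i] - t[last]
            if dt <= 0:
                keep[i] = False
                continue
            speed = np.hypot(x[i] - x[last], y[i] - y[last]) / dt * 3.6  # km/h
            if speed > max_speed_kmh:
                keep[i] = False
            else:
                last = i
        keep_idx.append(pd.Series(keep, index=g.index))
    keep_all = pd.concat(keep_idx).reindex(df.index) if keep_idx else pd.Series(dtype=bool)
    removed["speed"] = int((~keep_all).sum())
    df = df.loc[keep_all].reset_index(drop=True)

    if meta is None:
        years = sorted(set(zip(df["animal_id"], pd.to_datetime(df["timestamp"]).dt.year))) if len(df) else []
        meta = pd.DataFrame(
            {
                "animal_id": [a for a, _ in years],
                "year": [y for _, y in years],
                "parturient": "unknown",
                "excluded_herd_switch": False,
            }
        )
    return TrackSet(fixes=df, meta=meta), ScreenReport(n_input, len(df), removed)


def filter_sedentary(track, min_move: float = 25.0, group_cols=("animal_id",)):
    """Drop sedentary relocations, retaining the first fix of each bout.

    Within each group (animal, or animal-season if ``season`` is included in
    ``group_cols``), a fix is retained iff its displacement from the
    previously *retained* fix exceeds ``min_move`` meters.  The first fix of
    a sedentary bout is the last fix that moved; it is always retained, and
    subsequent fixes are dropped until the animal has moved more than
    ``min_move`` from it.  The first fix of every group is always retained.
    """
    is_trackset = isinstance(track, TrackSet)
    df = track.fixes if is_trackset else track
    if len(df) <= 1:
        return track
    group_cols = [c for c in group_cols if c in df.columns]

    def _keep(g: pd.DataFrame) -> pd.Series:
        x = g["x"].to_numpy(float)
        y = g["y"].to_numpy(float)
        keep = np.ones(len(g), dtype=bool)
        last = 0
        for i in range(1, len(g)):
            if np.hypot(x[i] - x[last], y[i] - y[last]) > min_move:
                last = i
            else:
                keep[i] = False
        return pd.Series(keep, index=g.index)

    if group_cols:
        keep = pd.concat([_keep(g) for _, g in df.groupby(group_cols, sort=False)])
        keep = keep.reindex(df.index)
    else:
        keep = _keep(df)
    out = df.loc[keep].reset_index(drop=True)
    return track.copy_with(out) if is_trackset else out


def assign_seasons(track, calendar: SeasonCalendar = DEFAULT_CALENDAR):
    """Label every fix with exactly one season (or 'off_season')."""
    is_trackset = isinstance(track, TrackSet)
    df = (track.fixes if is_trackset else track).copy()
    df["season"] = calendar.season_of(df["timestamp"])
    return track.copy_with(df) if is_trackset else df


# ---------------------------------------------------------------------------


def flag_herd_switch(trackset: TrackSet, other_calving_polygons, calendar: SeasonCalendar = DEFAULT_CALENDAR) -> TrackSet:
    """Flag animal-years after an apparent switch to another herd.

    An animal is assumed to have switched herds if any calving-season fix in
    a calving season *after its first* falls inside another herd's calving
    polygon; that year and all later years of the animal are flagged
    ``excluded_herd_switch`` and dropped by :meth:`TrackSet.analysis_fixes`.
    """
    polys = list(other_calving_polygons or [])
    meta = trackset.meta.copy()
    if "excluded_herd_switch" not in meta.columns:
        meta["excluded_herd_switch"] = False
    if not polys or not len(trackset.fixes):
        return TrackSet(fixes=trackset.fixes, meta=meta)

    fixes = trackset.fixes
    season = calendar.season_of(fixes["timestamp"])
    calving = fixes.loc[season == "calving"]
    prepared = [prep(p) for p in polys]

    flagged: dict[str, int] = {}
    for animal, g in calving.groupby("animal_id", sort=False):
        years = sorted(g["timestamp"].dt.year.unique())
        if len(years) < 2:
            continue
        first = years[0]
        for yr in years[1:]:
            pts = g.loc[g["timestamp"].dt.year == yr]
            inside = any(
                pp.contains(Point(px, py))
                for px, py in zip(pts["x"], pts["y"])
                for pp in prepared
            )
            if inside:
                flagged[animal] = yr
                break

    for animal, yr in flagged.items():
        mask = (meta["animal_id"] == animal) & (meta["year"] >= yr)
        if mask.any():
            meta.loc[mask, "excluded_herd_switch"] = True
        else:  # meta may not list the year; append rows for flagged years
            yrs = fixes.loc[fixes["animal_id"] == animal, "timestamp"].dt.year.unique()
            for y in sorted(y for y in yrs if y >= yr):
                meta.loc[len(meta)] = {
                    "animal_id": animal, "year": y,
                    "parturient": "unknown", "excluded_herd_switch": True,
                }
    return TrackSet(fixes=fixes, meta=meta)


def vegetation_bias_report(removed_classes, retained_classes) -> dict:
    """Chi-square comparison of vegetation classes at removed vs retained fixes.

    An optional diagnostic that screening did not preferentially remove
    fixes in particular vegetation types: observed = class counts among
    removed fixes, expected = proportional to class counts among retained
    fixes.  The construction of the published test was not specified; this
    is one reasonable interpretation and is labelled as such.
    """
    from scipy.stats import chisquare

    removed = pd.Series(removed_classes).value_counts()
    retained = pd.Series(retained_classes).value_counts()
    classes = sorted(set(removed.index) | set(retained.index))
    obs = np.array([removed.get(c, 0) for c in classes], dtype=float)
    exp_w = np.array([retained.get(c, 0) for c in classes], dtype=float)
    keep = exp_w > 0
    obs, exp_w = obs[keep], exp_w[keep]
    if obs.sum() == 0 or len(obs) < 2:
        return {"chi2": 0.0, "p_value": 1.0, "interpretation": "insufficient removals"}
    exp = exp_w / exp_w.sum() * obs.sum()
    stat, p = chisquare(obs, exp)
    return {
        "chi2": float(stat),
        "p_value": float(p),
        "classes": [str(c) for c in np.array(classes)[keep]],
        "interpretation": "removed-vs-retained class composition; construction is an interpretation",
    }
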