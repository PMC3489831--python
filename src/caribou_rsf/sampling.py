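"""Availability sampling at both scales of selection.

Landscape scale (2nd-order): availability is the herd's seasonal range,
the 95% isopleth of a Gaussian kernel density estimate of the season's
fixes with the ad hoc (normal-reference) bandwidth; one random location is
drawn per observed location, uniform over the range excluding water.

Patch scale (step selection): for each used location, five matched random
locations are generated by resampling, with replacement, movement rates
and bearings from that animal's own steps in that season, displacing from
the previous fix; each used point and its five matches form one stratum
for conditional logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .raster import LandscapeStack, Raster

__all__ = [
    "RangePolygon",
    "kde_range",
    "sample_available_landscape",
    "sample_available_steps",
    "build_landscape_table",
]


@dataclass
class RangePolygon:
    """A seasonal range: density-isopleth mask on a grid, with provenance."""

    mask: Raster  # boolean: inside the isopleth
    level: float
    bandwidth: tuple  # (hx, hy) in meters
    season: str = ""

    @property
    def area_m2(self) -> float:
        return float(self.mask.data.sum()) * self.mask.cell_size**2

    def contains(self, x, y) -> np.ndarray:
        inb = self.mask.in_bounds(x, y)
        row, col = self.mask.xy_to_rowcol(x, y)
        row = np.clip(row, 0, self.mask.nrows - 1)
        col = np.clip(col, 0, self.mask.ncols - 1)
        return inb & self.mask.data[row, col].astype(bool)

    def to_shapely(self):
        """Union of cell boxes inside the isopleth (for WKT export)."""
        from shapely.geometry import box
        from shapely.ops import unary_union

        cs = self.mask.cell_size
        rows, cols = np.nonzero(self.mask.data)
        boxes = [
            box(self.mask.x0 + c * cs, self.mask.y0 - (r + 1) * cs,
                self.mask.x0 + (c + 1) * cs, self.mask.y0 - r * cs)
            for r, c in zip(rows, cols)
        ]
        return unary_union(boxes)


def kde_range(points: pd.DataFrame, level: float = 0.95, cell_size: float | None = None,
              season: str = "", bandwidth: tuple | None = None) -> RangePolygon:
    """Kernel-density seasonal range at the given isopleth level.

    Gaussian product kernel evaluated on a grid (binned points smoothed
    with per-axis bandwidths).  Bandwidth defaults to the ad hoc
    normal-reference rule ``h = sd * n^(-1/6)`` per axis.  The isopleth is
    the smallest-density threshold whose super-level set holds at least
    ``level`` of the total density mass.
    """
    x = points["x"].to_numpy(float)
    y = points["y"].to_numpy(float)
    n = len(x)
    if n < 30:
        raise ValueError("need at least 30 points for a range estimate")
    sx, sy = x.std(), y.std()
    if sx <= 0 or sy <= 0:
        raise ValueError("degenerate point set: zero variance in a coordinate")
    if bandwidth is None:
        hx = sx * n ** (-1.0 / 6.0)
        hy = sy * n ** (-1.0 / 6.0)
    else:
        hx, hy = bandwidth
    if cell_size is None:
        cell_size = min(hx, hy) / 3.0

    pad = 3.5 * max(hx, hy)
    x0 = x.min() - pad
    y1 = y.max() + pad
    ncols = int(np.ceil((x.max() + pad - x0) / cell_size)) + 1
    nrows = int(np.ceil((y1 - (y.min() - pad)) / cell_size)) + 1

    counts = np.zeros((nrows, ncols))
    col = np.floor((x - x0) / cell_size).astype(int)
    row = np.floor((y1 - y) / cell_size).astype(int)
    np.add.at(counts, (row, col), 1.0)
    dens = gaussian_filter(counts, sigma=(hy / cell_size, hx / cell_size), mode="constant")

    flat = np.sort(dens.ravel())[::-1]
    csum = np.cumsum(flat)
    total = csum[-1]
    k = int(np.searchsorted(csum, level * total))
    thr = flat[min(k, len(flat) - 1)]
    mask = dens >= thr if level < 1.0 else dens > 0
    return RangePolygon(
        mask=Raster(mask, cell_size, x0, y1, nodata=0),
        level=level,
        bandwidth=(hx, hy),
        season=season,
    )


def sample_available_landscape(range_poly: RangePolygon, n: int, landmask: Raster | None = None,
                               seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """``n`` points uniform over the range polygon intersected with land.

    ``landmask`` is boolean with True = usable land (water screened out);
    rejection sampling from the range bounding box, reproducible under seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = range_poly.mask
    xmin, ymin, xmax, ymax = m.bounds

    def ok(x, y):
        good = range_poly.contains(x, y)
        if landmask is not None:
            inb = landmask.in_bounds(x, y)
            row, col = landmask.xy_to_rowcol(x, y)
            row = np.clip(row, 0, landmask.nrows - 1)
            col = np.clip(col, 0, landmask.ncols - 1)
            good &= inb & landmask.data[row, col].astype(bool)
        return good

    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    got = 0
    for _ in range(1000):
        need = n - got
        if need <= 0:
            break
        batch = max(4 * need, 128)
        cx = rng.uniform(xmin, xmax, size=batch)
        cy = rng.uniform(ymin, ymax, size=batch)
        good = ok(cx, cy)
        xs.append(cx[good][:need])
        ys.append(cy[good][:need])
        got += len(xs[-1])
    if got < n:
        raise ValueError("range polygon contains no usable land (or rejection sampling failed)")
    return pd.DataFrame({"x": np.concatenate(xs), "y": np.concatenate(ys), "used": 0})


def build_landscape_table(used: pd.DataFrame, range_poly: RangePolygon, landmask: Raster | None,
                          seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """1:1 used/available table for the landscape scale.

    Copies animal_id/year/season metadata onto available rows uniformly at
    random so grouping factors exist for the mixed model (availability is
    population-level; the group labels only serve the random intercepts).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    avail = sample_available_landscape(range_poly, len(used), landmask, rng)
    u = used.copy().reset_index(drop=True)
    u["used"] = 1
    pick = rng.integers(0, len(u), size=len(avail))
    for colname in ("animal_id", "year", "season", "insect_state", "parturient"):
        if colname in u.columns:
            avail[colname] = u[colname].to_numpy()[pick]
    keep = [c for c in u.columns if c in avail.columns or c in ("x", "y", "used")]
    return pd.concat([u[keep], avail], ignore_index=True, sort=False)


def sample_available_steps(track: pd.DataFrame, n_per_used: int = 5,
                           landscape: LandscapeStack | None = None,
                           seed: int | np.random.Generator = 0,
                           max_retries: int = 100) -> pd.DataFrame:
    """Matched step-based availability: 5 random locations per used fix.

    For each used fix at time t (with previous fix p), movement rates and
    bearings are drawn independently, with replacement, from the animal's
    empirical set of (rate, bearing) pairs in that season; each candidate
    is p displaced by rate x Delta-t at the bearing.  Candidates falling
    off the raster or on water are redrawn (up to ``max_retries``); strata
    that cannot be filled are dropped with a log entry in ``attrs``.

    Returns a long DataFrame with columns x, y, used, stratum_id plus the
    metadata of the source fix; animal-seasons with fewer than 2 fixes are
    skipped.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = track.sort_values(["animal_id", "timestamp"], kind="stable").reset_index(drop=True)
    group_cols = ["animal_id"] + (["season"] if "season" in df.columns else [])

    land = landscape.land if landscape is not None else None
    grid = landscape.grid if landscape is not None else None

    rows: list[pd.DataFrame] = []
    skipped_groups = 0
    dropped_strata = 0
    stratum = 0
    for _, g in df.groupby(group_cols, sort=False):
        if len(g) < 2:
            skipped_groups += 1
            continue
        x = g["x"].to_numpy(float)
        y = g["y"].to_numpy(float)
        t = g["timestamp"].astype("int64").to_numpy() / 3.6e12  # hours
        dt = np.diff(t)
        ok_dt = dt > 0
        rates = np.hypot(np.diff(x), np.diff(y))[ok_dt] / dt[ok_dt]
        bearings = np.arctan2(np.diff(y), np.diff(x))[ok_dt]
        if len(rates) == 0:
            skipped_groups += 1
            continue
        # one stratum per used fix i >= 1, all drawn vectorized with a retry
        # loop over still-invalid candidate slots
        idx_used = np.flatnonzero(ok_dt) + 1  # positions with a valid previous step
        m = len(idx_used)
        if m == 0:
            skipped_groups += 1
            continue
        px = x[idx_used - 1][:, None]
        py = y[idx_used - 1][:, None]
        dts = dt[idx_used - 1][:, None]
        ax = np.full((m, n_per_used), np.nan)
        ay = np.full((m, n_per_used), np.nan)
        pending = np.ones((m, n_per_used), dtype=bool)
        for _ in range(max_retries):
            if not pending.any():
                break
            n_draw = int(pending.sum())
            L = rates[rng.integers(0, len(rates), size=n_draw)] * np.broadcast_to(dts, pending.shape)[pending]
            B = bearings[rng.integers(0, len(bearings), size=n_draw)]
            cx = np.broadcast_to(px, pending.shape)[pending] + L * np.cos(B)
            cy = np.broadcast_to(py, pending.shape)[pending] + L * np.sin(B)
            if grid is not None:
                inb = grid.in_bounds(cx, cy)
                row, col = grid.xy_to_rowcol(cx, cy)
                row = np.clip(row, 0, grid.nrows - 1)
                col = np.clip(col, 0, grid.ncols - 1)
                good = inb & land[row, col]
            else:
                good = np.ones(n_draw, dtype=bool)
            slot_r, slot_c = np.nonzero(pending)
            ax[slot_r[good], slot_c[good]] = cx[good]
            ay[slot_r[good], slot_c[good]] = cy[good]
            pending[slot_r[good], slot_c[good]] = False
        full = ~pending.any(axis=1)
        dropped_strata += int((~full).sum())
        if not full.any():
            continue
        keep = np.flatnonzero(full)
        sids = stratum + 1 + np.arange(m)
        stratum += m
        n_rows_per = n_per_used + 1
        block_x = np.column_stack([x[idx_used[keep]][:, None], ax[keep]]).ravel()
        block_y = np.column_stack([y[idx_used[keep]][:, None], ay[keep]]).ravel()
        block = pd.DataFrame(
            {
                "x": block_x,
                "y": block_y,
                "used": np.tile([1] + [0] * n_per_used, len(keep)),
                "stratum_id": np.repeat(sids[keep], n_rows_per),
            }
        )
        meta_cols = [c for c in g.columns if c not in ("x", "y")]
        gmeta = g.iloc[idx_used[keep]][meta_cols].reset_index(drop=True)
        for c in meta_cols:
            block[c] = np.repeat(gmeta[c].to_numpy(), n_rows_per)
        rows.append(block)

    if not rows:
        out = pd.DataFrame(columns=["x", "y", "used", "stratum_id"])
    else:
        out = pd.concat(rows, ignore_index=True)
    out.attrs["skipped_animal_seasons"] = skipped_groups
    out.attrs["dropped_strata"] = dropped_strata
    return out
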