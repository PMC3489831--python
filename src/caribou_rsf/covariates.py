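"""Raster habitat covariates and standardized design matrices.

Builds the covariate suite of the analysis: per-class vegetation densities
in moving windows sized by the scale of maximum patchiness (three-term
local quadrat variance, TTLQV), NDVI phenology dates (green-up, maximum
growth, senescence), terrain ruggedness (vector ruggedness measure, VRM),
distance to the coastline, and precipitation; then assembles used/available
design matrices with the analysis transforms (log for elevation and
distance to coast, square root for ruggedness), z-standardization, optional
squared terms, and iterative VIF collinearity pruning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import LandscapeStack, Raster

__all__ = [
    "ttlqv_scale",
    "ttlqv_profile",
    "moving_window_density",
    "vrm",
    "ndvi_phenology",
    "distance_to_coast",
    "DesignSpec",
    "CovariateTable",
    "build_design",
    "vif",
    "vif_prune",
    "attach_standard_layers",
]


# ---------------------------------------------------------------------------
# TTLQV


def ttlqv_profile(indicator: np.ndarray, max_block: int) -> np.ndarray:
    """TTLQV variance V3(b) for b = 1..max_block, averaged over rows+columns.

    For a transect x and block size b, with S1, S2, S3 the sums of three
    consecutive length-b blocks starting at position i,
    ``V3(b) = mean_i (S1 - 2 S2 + S3)^2 / (8 b)``.  The 2-D value averages
    the transect statistic over all rows and all columns.
    """
    a = np.asarray(indicator, dtype=float)
    if a.ndim != 2:
        raise ValueError("indicator must be 2-D")
    out = np.full(max_block, np.nan)
    for b in range(1, max_block + 1):
        parts = []
        for arr in (a, a.T):
            n = arr.shape[1]
            if n < 3 * b:
                continue
            cs = np.zeros((arr.shape[0], n + 1))
            np.cumsum(arr, axis=1, out=cs[:, 1:])
            i = np.arange(0, n - 3 * b + 1)
            d = cs[:, i + 3 * b] - 3 * cs[:, i + 2 * b] + 3 * cs[:, i + b] - cs[:, i]
            parts.append(d**2 / (8.0 * b))
        if parts:
            out[b - 1] = float(np.mean(np.concatenate([p.ravel() for p in parts])))
    return out


def ttlqv_scale(veg_class: Raster, class_k: int, max_block: int = 32) -> float:
    """Scale (m) of maximum patchiness of class ``class_k`` via TTLQV.

    Returns ``b* x cell_size`` where b* maximizes the row/column-averaged
    V3 over block sizes 1..max_block (first maximum on ties).
    """
    if max_block < 2:
        raise ValueError("max_block must be >= 2")
    ind = (veg_class.data == class_k).astype(float)
    if ind.sum() == 0 or ind.sum() == ind.size:
        raise ValueError(f"degenerate indicator: class {class_k} absent or covers whole raster")
    v3 = ttlqv_profile(ind, max_block)
    if np.all(np.isnan(v3)):
        raise ValueError("raster too small for any block size")
    b_star = int(np.nanargmax(v3)) + 1
    return b_star * veg_class.cell_size


# ---------------------------------------------------------------------------
# moving-window density


def moving_window_density(veg_class: Raster, class_k: int, window_m: float) -> Raster:
    """Proportion of class-k cells in a centered square window.

    Window side is ``round(window_m / cell_size)`` forced odd; the
    denominator counts non-no-data cells only, so edge cells use the
    truncated window and cells next to water use the valid part.
    """
    w = max(int(round(window_m / veg_class.cell_size)), 1)
    if w % 2 == 0:
        w += 1
    valid = ~veg_class.is_nodata()
    ind = ((veg_class.data == class_k) & valid).astype(float)
    # separable window sums; zero padding outside = truncated edge windows
    count_k = ndimage.uniform_filter(ind, size=w, mode="constant", cval=0.0) * (w * w)
    count_v = ndimage.uniform_filter(valid.astype(float), size=w, mode="constant", cval=0.0) * (w * w)
    count_k = np.round(count_k, 6)
    count_v = np.round(count_v, 6)
    with np.errstate(invalid="ignore", divide="ignore"):
        dens = np.where(count_v > 0, count_k / count_v, np.nan)
    dens = np.clip(dens, 0.0, 1.0)
    return Raster(dens, veg_class.cell_size, veg_class.x0, veg_class.y0, nodata=np.nan)


# ---------------------------------------------------------------------------
# vector ruggedness measure


def _horn_gradients(dem: np.ndarray, cell: float):
    """Horn (3x3) finite-difference surface gradients dz/dx, dz/dy.

    Computed on the interior; the one-cell border is filled by replicating
    the nearest interior value, which keeps planar surfaces exactly planar
    (and hence VRM exactly zero) out to the edge.
    """
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float) / (8.0 * cell)
    # row index increases southward, so dz/dy needs a sign flip
    ky = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float) / (8.0 * cell)
    p = ndimage.correlate(dem, kx, mode="nearest")
    q = ndimage.correlate(dem, ky, mode="nearest")
    if dem.shape[0] > 2 and dem.shape[1] > 2:
        p = np.pad(p[1:-1, 1:-1], 1, mode="edge")
        q = np.pad(q[1:-1, 1:-1], 1, mode="edge")
    return p, q


def vrm(dem: Raster, window: int = 8) -> Raster:
    """Vector ruggedness measure: dispersion of terrain unit normals.

    Per cell the unit normal is (-p, -q, 1)/|(-p, -q, 1)| from Horn
    gradients; over a ``window x window`` neighbourhood, with R the length
    of the resultant vector of the n normals, VRM = 1 - R/n.  Zero for any
    planar surface, approaching 1 for maximally dispersed normals.
    """
    if dem.data.size < window * window:
        raise ValueError("dem smaller than the VRM window")
    z = dem.data.astype(float)
    p, q = _horn_gradients(z, dem.cell_size)
    norm = np.sqrt(1.0 + p**2 + q**2)
    nx, ny, nz = -p / norm, -q / norm, 1.0 / norm
    n = float(window * window)
    sx = ndimage.uniform_filter(nx, size=window, mode="nearest") * n
    sy = ndimage.uniform_filter(ny, size=window, mode="nearest") * n
    sz = ndimage.uniform_filter(nz, size=window, mode="nearest") * n
    r = np.sqrt(sx**2 + sy**2 + sz**2)
    out = np.clip(1.0 - r / n, 0.0, 1.0)
    return Raster(out, dem.cell_size, dem.x0, dem.y0, nodata=np.nan)


# ---------------------------------------------------------------------------
# NDVI phenology


def ndvi_phenology(ndvi: dict[int, Raster], threshold: float = 0.1):
    """Green-up, maximum-growth, and senescence day-of-year rasters.

    Green-up: first composite date with NDVI above ``threshold``.
    Max growth: date of the maximum NDVI (first occurrence on ties).
    Senescence: first date after max growth with NDVI below ``threshold``.
    Pixels never exceeding the threshold are no-data in all three.
    """
    if len(ndvi) < 3:
        raise ValueError("need at least 3 composites spanning the season")
    doys = np.array(sorted(ndvi))
    ref = ndvi[int(doys[0])]
    cube = np.stack([ndvi[int(d)].data for d in doys])  # (T, nr, nc)
    T, nr, nc = cube.shape

    with np.errstate(invalid="ignore"):
        above = cube > threshold
    ever = above.any(axis=0)

    first_above = np.argmax(above, axis=0)
    greenup = np.where(ever, doys[first_above], np.nan)

    max_idx = np.nanargmax(np.where(np.isnan(cube), -np.inf, cube), axis=0)
    maxgrowth = np.where(ever, doys[max_idx], np.nan)

    t_idx = np.arange(T)[:, None, None]
    below_after = (cube < threshold) & (t_idx > max_idx[None, :, :])
    any_after = below_after.any(axis=0)
    first_below = np.argmax(below_after, axis=0)
    senescence = np.where(ever & any_after, doys[first_below], np.nan)

    mk = lambda a: Raster(a.astype(float), ref.cell_size, ref.x0, ref.y0, nodata=np.nan)
    return mk(greenup), mk(maxgrowth), mk(senescence)


# ---------------------------------------------------------------------------
# distance to coast


def distance_to_coast(coast_mask: Raster) -> Raster:
    """Euclidean distance (m) from each cell center to the nearest coast cell."""
    mask = coast_mask.data.astype(bool)
    if not mask.any():
        raise ValueError("coast mask has no coast cells")
    d = ndimage.distance_transform_edt(~mask) * coast_mask.cell_size
    return Raster(d, coast_mask.cell_size, coast_mask.x0, coast_mask.y0, nodata=np.nan)


# ---------------------------------------------------------------------------
# stack assembly


def attach_standard_layers(stack: LandscapeStack, max_block: int = 32, density_classes=None) -> dict:
    """Compute and attach the standard covariate layers to a stack.

    Adds ``elevation`` (alias of the DEM), ``vrm``, ``dist_coast``,
    phenology dates, and per-class density layers at each class's TTLQV
    scale.  Returns the dict of TTLQV scales (m) per class name.
    """
    stack.add_layer("vrm", vrm(stack.dem))
    stack.add_layer("dist_coast", distance_to_coast(stack.coast_mask))
    if stack.ndvi:
        g, m, s = ndvi_phenology(stack.ndvi)
        stack.add_layer("greenup_date", g)
        stack.add_layer("maxgrowth_date", m)
        stack.add_layer("senescence_date", s)
    scales = {}
    names = density_classes if density_classes is not None else stack.class_names
    for name in names:
        k = stack.class_names.index(name)
        if not np.any(stack.veg_class.data == k):
            continue
        scale_m = ttlqv_scale(stack.veg_class, k, max_block=max_block)
        scales[name] = scale_m
        stack.add_layer(f"density_{name}", moving_window_density(stack.veg_class, k, scale_m))
    return scales


# ---------------------------------------------------------------------------
# design matrices


@dataclass
class DesignSpec:
    """Which covariates enter a design matrix and how they are transformed."""

    covariates: tuple = ("elevation", "dist_coast", "vrm")
    include_patch_dummies: bool = True
    reference_class: str = "sedge_grass_meadow"
    squared_terms: tuple = ()
    log_vars: tuple = ("elevation", "dist_coast")
    sqrt_vars: tuple = ("vrm",)
    standardize: bool = True

    #: map design-column name -> stack layer name where they differ
    layer_aliases: dict = field(default_factory=lambda: {"elevation": "dem"})


@dataclass
class CovariateTable:
    """Design matrix of used and available points with transform metadata."""

    frame: pd.DataFrame
    covariate_names: tuple
    transforms: dict  # col -> {"transform": str, "mean": float, "sd": float}
    n_excluded: int = 0

    def design_matrix(self, columns=None):
        cols = list(columns) if columns is not None else list(self.covariate_names)
        return self.frame[cols].to_numpy(float), cols

    @property
    def used(self) -> np.ndarray:
        return self.frame["used"].to_numpy(int)


def build_design(points: pd.DataFrame, stack: LandscapeStack, spec: DesignSpec | None = None,
                 stats: dict | None = None) -> CovariateTable:
    """Sample covariates at points and assemble the standardized design.

    Vegetation patch type enters as one-hot dummies with the reference
    class (sedge-grass meadow) omitted; elevation and distance-to-coast are
    log transformed with a ``log(x + cell_size)`` zero guard, ruggedness is
    square-root transformed; continuous covariates are then z-standardized
    over the full table (used + available of the season being fit), unless
    ``stats`` provides stored means/SDs from a fitting sample (as needed
    when predicting).  Squared terms are added after standardization.
    Points on water or no-data are excluded and counted.
    """
    spec = spec or DesignSpec()
    pts = points.reset_index(drop=True)
    x = pts["x"].to_numpy(float)
    y = pts["y"].to_numpy(float)
    grid = stack.grid
    row, col = grid.xy_to_rowcol(x, y)
    inside = (row >= 0) & (row < grid.nrows) & (col >= 0) & (col < grid.ncols)
    row_c = np.clip(row, 0, grid.nrows - 1)
    col_c = np.clip(col, 0, grid.ncols - 1)
    on_land = stack.land[row_c, col_c] & inside

    out = pts.loc[on_land].reset_index(drop=True).copy()
    r, c = row_c[on_land], col_c[on_land]
    cov_cols: list[str] = []
    transforms: dict[str, dict] = {}

    if spec.include_patch_dummies:
        codes = stack.veg_class.data[r, c]
        for k, name in enumerate(stack.class_names):
            if name == spec.reference_class:
                continue
            coln = f"patch_{name}"
            out[coln] = (codes == k).astype(float)
            cov_cols.append(coln)
            transforms[coln] = {"transform": "none", "mean": 0.0, "sd": 1.0}

    bad = np.zeros(len(out), dtype=bool)
    for name in spec.covariates:
        layer = stack.layer(spec.layer_aliases.get(name, name))
        vals = layer.data[r, c].astype(float)
        vals = np.where(layer.is_nodata(vals), np.nan, vals)
        tr = "none"
        if name in spec.log_vars:
            vals = np.log(vals + stack.cell_size)
            tr = f"log(x+{stack.cell_size:g})"
        elif name in spec.sqrt_vars:
            vals = np.sqrt(np.clip(vals, 0.0, None))
            tr = "sqrt"
        bad |= ~np.isfinite(vals)
        if spec.standardize:
            if stats and name in stats:
                mu, sd = stats[name]["mean"], stats[name]["sd"]
            else:
                mu = float(np.nanmean(vals))
                sd = float(np.nanstd(vals))
            sd = sd if sd > 0 else 1.0
            vals = (vals - mu) / sd
        else:
            mu, sd = 0.0, 1.0
        out[name] = vals
        cov_cols.append(name)
        transforms[name] = {"transform": tr, "mean": mu, "sd": sd}

    for name in spec.squared_terms:
        if name not in out.columns:
            continue
        coln = f"{name}_sq"
        out[coln] = out[name] ** 2
        cov_cols.append(coln)
        transforms[coln] = {"transform": "square_of_standardized", "mean": 0.0, "sd": 1.0}

    n_excluded = int((~on_land).sum() + bad.sum())
    out = out.loc[~bad].reset_index(drop=True)
    return CovariateTable(out, tuple(cov_cols), transforms, n_excluded)


# ---------------------------------------------------------------------------
# VIF


def vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factor per column: 1/(1 - R^2_j) with intercept."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    out = np.empty(k)
    for j in range(k):
        yj = X[:, j]
        Z = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ coef
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot <= 0:
            out[j] = 1.0
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_prune(table, threshold: float = 3.0):
    """Iteratively drop the highest-VIF column while any exceeds threshold.

    Accepts a CovariateTable or a numeric DataFrame; returns
    ``(retained_columns, drop_log)`` where drop_log lists (column, vif) in
    drop order.  Perfectly collinear columns have infinite VIF and go first.
    """
    if isinstance(table, CovariateTable):
        df = table.frame[list(table.covariate_names)]
    else:
        df = table
    cols = list(df.columns)
    drop_log: list[tuple[str, float]] = []
    # constant columns are unestimable; remove them before the VIF loop
    for c in list(cols):
        if np.std(df[c].to_numpy(float)) == 0:
            drop_log.append((c, np.inf))
            cols.remove(c)
    while len(cols) >= 2:
        v = vif(df[cols].to_numpy(float))
        worst = int(np.argmax(v))
        if v[worst] > threshold:
            drop_log.append((cols[worst], float(v[worst])))
            cols.pop(worst)
        else:
            break
    return cols, drop_log
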