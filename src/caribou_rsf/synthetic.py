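"""Synthetic landscapes, weather series, and GPS tracks with known selection.

The real inputs to a summer resource-selection analysis for an arctic
caribou herd — a classified 30 m vegetation map, a DEM, NDVI composites,
hourly weather from two stations, and multi-year GPS collar fixes — are
proprietary or herd-specific.  This module generates stand-ins with the
same statistical structure and, crucially, *known* selection coefficients,
so every downstream estimator can be tested for parameter recovery.

Landscape model: a Gaussian random field is thresholded at class quantiles,
which hits target class proportions exactly (up to cell rounding) while
keeping classes spatially clumped.  Movement model: step lengths are
gamma-distributed, turning angles von Mises; each step the animal chooses
among K candidate endpoints with probability proportional to exp(beta' x),
the data-generating mirror of a step-selection design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .preprocessing import TrackSet
from .raster import LandscapeStack, Raster

__all__ = [
    "CLASS_NAMES",
    "DEFAULT_CLASS_PROPORTIONS",
    "SyntheticConfig",
    "TruthBundle",
    "generate_landscape",
    "simulate_weather",
    "simulate_tracks",
    "simulate_mixed_logistic",
    "truth_covariates",
    "sample_covariates",
]

#: Nine tundra vegetation classes of the study scheme, in legend order.
CLASS_NAMES = (
    "flooded",
    "carex_aquatilis",
    "riverine",
    "wet_tundra",
    "sedge_grass_meadow",
    "tussock_tundra",
    "moss_lichen",
    "dwarf_shrub",
    "low_shrub",
)

#: Areal proportions of the nine classes across the study region
#: (dwarf shrub 43%, tussock tundra 27%, ... moss-lichen 1%).
DEFAULT_CLASS_PROPORTIONS = (0.07, 0.02, 0.05, 0.05, 0.06, 0.27, 0.01, 0.43, 0.04)


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study system.

    Defaults emulate the study design: 30 m vegetation cells, 2-h GPS fix
    interval (3 h in the first collar years), mean 2-h step ~300 m, a
    vegetation mosaic with ~120 m autocorrelation grain (finer than a
    step, so candidate endpoints sample nearly independent habitat), low
    relief (<60 m), ~5% lake cover, and a 2.6% rate of injected bad fixes
    split between 2D fixes and high-PDOP records.
    """

    grid_nrows: int = 250
    grid_ncols: int = 250
    cell_size: float = 30.0
    class_proportions: tuple = DEFAULT_CLASS_PROPORTIONS
    spatial_range: float = 120.0
    n_animals: int = 8
    n_steps_per_animal: int = 300
    fix_interval: float = 2.0
    step_scale: float = 300.0
    turn_concentration: float = 0.5
    true_beta: dict = field(default_factory=dict)
    re_sd_animal: float = 0.5
    re_sd_year: float = 0.3
    seed: int = 0
    # secondary knobs
    n_candidates: int = 30
    rate_2d: float = 0.015
    rate_high_pdop: float = 0.011
    lake_fraction: float = 0.05
    relief: float = 60.0
    n_years: int = 3
    start: datetime = datetime(2004, 6, 1, tzinfo=timezone.utc)

    def __post_init__(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if p.ndim != 1 or len(p) != len(CLASS_NAMES):
            raise ValueError(f"class_proportions must have {len(CLASS_NAMES)} entries")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must be non-negative and sum to 1")
        for name in ("grid_nrows", "grid_ncols", "n_animals", "n_steps_per_animal", "n_candidates", "n_years"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.step_scale <= 0:
            raise ValueError("step_scale must be positive")
        if self.fix_interval <= 0:
            raise ValueError("fix_interval must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named randomness stream."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class TruthBundle:
    """Ground truth recorded during track simulation, for recovery tests."""

    true_beta: dict
    realized_step_lengths: np.ndarray
    realized_bearings: np.ndarray
    per_animal_intercepts: dict
    per_year_intercepts: dict

    def __post_init__(self) -> None:
        b = np.asarray(self.realized_bearings, dtype=float)
        # wrap into [-pi, pi)
        self.realized_bearings = np.mod(b + np.pi, 2 * np.pi) - np.pi

    def to_json_dict(self) -> dict:
        return {
            "true_beta": dict(self.true_beta),
            "per_animal_intercepts": {str(k): float(v) for k, v in self.per_animal_intercepts.items()},
            "per_year_intercepts": {str(k): float(v) for k, v in self.per_year_intercepts.items()},
            "n_steps": int(len(self.realized_step_lengths)),
        }


# ---------------------------------------------------------------------------
# landscape


def _grf(rng: np.random.Generator, shape: tuple[int, int], sigma_cells: float) -> np.ndarray:
    """Smoothed white noise, re-standardized; sigma in cell units."""
    z = rng.standard_normal(shape)
    f = gaussian_filter(z, sigma=max(sigma_cells, 1e-9), mode="reflect")
    return (f - f.mean()) / max(f.std(), 1e-12)


def _mosaic_grf(rng: np.random.Generator, shape: tuple[int, int], sigma_cells: float) -> np.ndarray:
    """Band-pass (difference-of-Gaussians) random field with a mosaic grain.

    Low-pass fields have no characteristic alternation scale, so quadrat
    variance rises monotonically on them; subtracting a broader smooth
    gives the patterned-ground / polygon-mosaic structure of real tundra,
    with patch alternation at roughly ``sigma_cells``.
    """
    z = rng.standard_normal(shape)
    s = max(sigma_cells, 1e-9)
    f = gaussian_filter(z, sigma=s, mode="reflect") - 0.8 * gaussian_filter(z, sigma=2.5 * s, mode="reflect")
    return (f - f.mean()) / max(f.std(), 1e-12)


def generate_landscape(config: SyntheticConfig) -> LandscapeStack:
    """Generate a co-registered synthetic landscape.

    Vegetation: GRF thresholded at the class-proportion quantiles over land
    cells (water carved out first from a coarser field).  DEM: smooth field
    plus a gentle inland rise, scaled to ``relief``.  NDVI: 10-day
    composites of a Gaussian seasonal curve whose peak day and amplitude
    vary smoothly in space, crossing the 0.1 growing-season threshold.
    Coast: the northern (row 0) edge.
    """
    rng = config.rng(1)
    shape = (config.grid_nrows, config.grid_ncols)
    cs = config.cell_size
    sigma = config.spatial_range / cs
    p = np.asarray(config.class_proportions, dtype=float)

    # water bodies from a coarser field; keep the coastal row on land
    lake_field = _grf(rng, shape, 2.0 * sigma)
    if config.lake_fraction > 0:
        thr = np.quantile(lake_field, 1.0 - config.lake_fraction)
        water = lake_field > thr
    else:
        water = np.zeros(shape, dtype=bool)
    water[0, :] = False
    land = ~water

    n_land = int(land.sum())
    # smallest positive class must get at least one cell
    min_pos = p[p > 0].min()
    if round(min_pos * n_land) < 1:
        raise ValueError(
            f"grid too small to realize class proportions: {n_land} land cells, "
            f"smallest class proportion {min_pos:g}"
        )

    veg_field = _mosaic_grf(rng, shape, sigma)
    veg = np.full(shape, -1, dtype=int)
    vals = veg_field[land]
    order = np.argsort(vals, kind="stable")
    cum = np.round(np.cumsum(p) * n_land).astype(int)
    cum[-1] = n_land
    codes = np.empty(n_land, dtype=int)
    start = 0
    for k, stop in enumerate(cum):
        codes[order[start:stop]] = k
        start = stop
    veg[land] = codes

    # DEM: smooth relief + inland (southward) rise; coastal plain at ~0
    rough = _grf(rng, shape, 3.0 * sigma)
    rows = np.arange(shape[0])[:, None] / max(shape[0] - 1, 1)
    dem = 0.5 * config.relief * (rough - rough.min()) / max(np.ptp(rough), 1e-12)
    dem = dem + 0.5 * config.relief * rows * np.ones(shape)

    # NDVI: Gaussian season, peak day-of-year and amplitude vary smoothly
    peak = 200.0 + 12.0 * _grf(rng, shape, 2.0 * sigma)
    amp = 0.6 + 0.12 * _grf(rng, shape, 2.0 * sigma)
    amp = np.clip(amp, 0.3, 0.9)
    composite_doys = list(range(121, 274, 10))  # May 1 .. Sep 28
    ndvi = {}
    for doy in composite_doys:
        layer = -0.02 + amp * np.exp(-0.5 * ((doy - peak) / 32.0) ** 2)
        layer[water] = np.nan
        ndvi[doy] = Raster(layer, cs, nodata=np.nan)

    precip_f = _grf(rng, shape, 4.0 * sigma)
    precip = 40.0 + 12.0 * precip_f

    coast = np.zeros(shape, dtype=bool)
    coast[0, :] = True

    mk = lambda a, nodata=-9999.0: Raster(a, cs, nodata=nodata)
    stack = LandscapeStack(
        veg_class=mk(veg, nodata=-1),
        dem=mk(dem),
        water_mask=mk(water),
        coast_mask=mk(coast),
        class_names=CLASS_NAMES,
        ndvi=ndvi,
        precip=mk(precip),
    )
    return stack


# ---------------------------------------------------------------------------
# weather


def simulate_weather(config: SyntheticConfig, start: datetime, end: datetime) -> pd.DataFrame:
    """Hourly temperature/wind series for two stations.

    Diurnal cycles plus AR(1) synoptic noise give temperatures spanning
    <6 to >18 degC and winds spanning calm (exact zeros) to >9 m/s, so all
    corner regions of the insect-activity indices occur in a summer month.
    """
    if not end > start:
        raise ValueError("end must be after start")
    rng = config.rng(2)
    hours = int(np.ceil((end - start).total_seconds() / 3600.0))
    times = [start + timedelta(hours=h) for h in range(hours)]
    hod = np.array([t.hour + t.minute / 60.0 for t in times])

    frames = []
    for station in ("STN_A", "STN_B"):
        # synoptic anomalies: warm spells are calm (high pressure), windy
        # events are cool — anomalies negatively correlated (r ~ -0.4)
        e_t = _ar1(rng, hours, rho=0.97, sd_innov=1.3)
        e_w_own = _ar1(rng, hours, rho=0.95, sd_innov=0.8)
        sd_t = 1.3 / np.sqrt(1 - 0.97**2)
        sd_w = 0.8 / np.sqrt(1 - 0.95**2)
        e_w = -0.4 * (e_t / sd_t) * sd_w + np.sqrt(1 - 0.4**2) * e_w_own
        # diurnal cycles: temperature peaks ~16:00, wind ~15:00
        temp = 11.0 + 5.0 * np.sin(2 * np.pi * (hod - 4.0) / 24.0 - np.pi / 2) + e_t
        wind = 3.3 + 1.5 * np.sin(2 * np.pi * (hod - 3.0) / 24.0 - np.pi / 2) + e_w
        wind = np.clip(wind, 0.0, None)
        wind[wind < 0.4] = 0.0
        frames.append(
            pd.DataFrame(
                {
                    "station_id": station,
                    "timestamp": pd.to_datetime(times, utc=True),
                    "temp_c": np.round(temp, 2),
                    "wind_ms": np.round(wind, 2),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _ar1(rng: np.random.Generator, n: int, rho: float, sd_innov: float) -> np.ndarray:
    stat_sd = sd_innov / np.sqrt(1 - rho**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, stat_sd)
    innov = rng.normal(0.0, sd_innov, size=n)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov[i]
    return x


# ---------------------------------------------------------------------------
# covariate lookup shared by the simulator and recovery tests


def truth_covariates(stack: LandscapeStack, names) -> dict[str, np.ndarray]:
    """Per-cell covariate arrays for the named selection covariates.

    Vegetation class names map to 0/1 indicators; ``elevation``,
    ``dist_coast`` and ``precip`` map to the continuous layers standardized
    over land cells (so selection coefficients are per-SD, the same scale
    the estimators report).
    """
    out: dict[str, np.ndarray] = {}
    land = stack.land
    for name in names:
        if name in stack.class_names:
            k = stack.class_names.index(name)
            out[name] = (stack.veg_class.data == k).astype(float)
        elif name == "elevation":
            out[name] = _std_land(stack.dem.data, land)
        elif name == "dist_coast":
            d = distance_transform_edt(~stack.coast_mask.data.astype(bool)) * stack.cell_size
            out[name] = _std_land(d, land)
        elif name == "precip":
            out[name] = _std_land(stack.precip.data, land)
        else:
            raise KeyError(f"unknown selection covariate {name!r}")
    return out


def _std_land(a: np.ndarray, land: np.ndarray) -> np.ndarray:
    mu = a[land].mean()
    sd = a[land].std()
    return (a - mu) / max(sd, 1e-12)


def sample_covariates(stack: LandscapeStack, names, x, y) -> pd.DataFrame:
    """Covariate values (as in :func:`truth_covariates`) at point locations."""
    cov = truth_covariates(stack, names)
    row, col = stack.grid.xy_to_rowcol(x, y)
    return pd.DataFrame({name: arr[row, col] for name, arr in cov.items()})


# ---------------------------------------------------------------------------
# tracks


def simulate_tracks(stack: LandscapeStack, config: SyntheticConfig):
    """Simulate GPS tracks by candidate-endpoint step selection.

    Each step, every animal draws ``n_candidates`` endpoints from
    gamma step lengths and von Mises turns, rejects water/out-of-grid
    candidates (reflecting proposals at the raster edge), and picks one
    with probability proportional to exp(beta' x).  Fixes are stamped at
    ``fix_interval`` hours; a configured fraction receive 2D or high-PDOP
    noise flags so screening has something to remove.

    Returns ``(TrackSet, TruthBundle)``; the TrackSet holds *raw* fixes,
    screening is downstream.
    """
    cfg = config
    rng = cfg.rng(3)
    beta_names = list(cfg.true_beta.keys())
    beta = np.array([cfg.true_beta[k] for k in beta_names], dtype=float)
    cov = truth_covariates(stack, beta_names) if beta_names else {}

    A = cfg.n_animals
    K = cfg.n_candidates
    grid = stack.grid
    xmin, ymin, xmax, ymax = grid.bounds
    land = stack.land

    # start positions on land
    land_rows, land_cols = np.nonzero(land)
    idx = rng.integers(0, len(land_rows), size=A)
    px, py = grid.rowcol_to_xy(land_rows[idx], land_cols[idx])
    px, py = np.asarray(px, dtype=float), np.asarray(py, dtype=float)
    bearing = rng.uniform(-np.pi, np.pi, size=A)

    years = cfg.start.year + (np.arange(A) % cfg.n_years)
    animal_ids = np.array([f"C{i + 1:03d}" for i in range(A)])
    a_int = rng.normal(0.0, cfg.re_sd_animal, size=A)
    y_vals = np.unique(years)
    y_int = {int(y): float(v) for y, v in zip(y_vals, rng.normal(0.0, cfg.re_sd_year, size=len(y_vals)))}

    shape_k = 2.0
    scale0 = cfg.step_scale / shape_k

    xs = np.empty((A, cfg.n_steps_per_animal + 1))
    ys = np.empty((A, cfg.n_steps_per_animal + 1))
    xs[:, 0], ys[:, 0] = px, py
    step_lengths = []
    step_bearings = []

    for t in range(1, cfg.n_steps_per_animal + 1):
        pos_x, pos_y = xs[:, t - 1].copy(), ys[:, t - 1].copy()
        chosen_x = np.empty(A)
        chosen_y = np.empty(A)
        chosen_b = np.empty(A)
        pending = np.arange(A)
        scale = np.full(A, scale0)
        for attempt in range(100):
            if len(pending) == 0:
                break
            m = len(pending)
            lengths = rng.gamma(shape_k, scale[pending, None], size=(m, K))
            turns = rng.vonmises(0.0, cfg.turn_concentration, size=(m, K))
            cand_b = bearing[pending, None] + turns
            cx = pos_x[pending, None] + lengths * np.cos(cand_b)
            cy = pos_y[pending, None] + lengths * np.sin(cand_b)
            cx = _reflect(cx, xmin, xmax)
            cy = _reflect(cy, ymin, ymax)
            row, col = grid.xy_to_rowcol(cx, cy)
            row = np.clip(row, 0, grid.nrows - 1)
            col = np.clip(col, 0, grid.ncols - 1)
            valid = land[row, col]
            any_valid = valid.any(axis=1)

            if any_valid.any():
                sub = pending[any_valid]
                if beta_names:
                    score = np.zeros((len(sub), K))
                    rsub = row[any_valid]
                    csub = col[any_valid]
                    for j, name in enumerate(beta_names):
                        score += beta[j] * cov[name][rsub, csub]
                else:
                    score = np.zeros((len(sub), K))
                score[~valid[any_valid]] = -np.inf
                score -= score.max(axis=1, keepdims=True)
                w = np.exp(score)
                w /= w.sum(axis=1, keepdims=True)
                u = rng.random(len(sub))
                pick = (np.cumsum(w, axis=1) < u[:, None]).sum(axis=1)
                rows_local = np.arange(len(sub))
                chosen_x[sub] = cx[any_valid][rows_local, pick]
                chosen_y[sub] = cy[any_valid][rows_local, pick]
                chosen_b[sub] = np.arctan2(
                    chosen_y[sub] - pos_y[sub], chosen_x[sub] - pos_x[sub]
                )
            pending = pending[~any_valid]
            scale[pending] *= 1.5  # widen the proposal for stuck animals
        else:
            if len(pending):
                raise RuntimeError(
                    f"no valid candidate endpoints after 100 attempts for animals {pending}"
                )
        xs[:, t], ys[:, t] = chosen_x, chosen_y
        dl = np.hypot(chosen_x - xs[:, t - 1], chosen_y - ys[:, t - 1])
        step_lengths.append(dl)
        step_bearings.append(chosen_b)
        bearing = chosen_b

    # assemble fixes
    n_fix = cfg.n_steps_per_animal + 1
    recs = []
    for i in range(A):
        t0 = cfg.start.replace(year=int(years[i]))
        times = pd.to_datetime(
            [t0 + timedelta(hours=cfg.fix_interval * t) for t in range(n_fix)], utc=True
        )
        recs.append(
            pd.DataFrame(
                {
                    "animal_id": animal_ids[i],
                    "timestamp": times,
                    "x": xs[i],
                    "y": ys[i],
                }
            )
        )
    fixes = pd.concat(recs, ignore_index=True)

    n = len(fixes)
    u = rng.random(n)
    fix_dim = np.where(u < cfg.rate_2d, "2D", "3D")
    pdop = rng.uniform(1.0, 6.0, size=n)
    bad_pdop = (u >= cfg.rate_2d) & (u < cfg.rate_2d + cfg.rate_high_pdop)
    pdop[bad_pdop] = rng.uniform(10.5, 20.0, size=int(bad_pdop.sum()))
    fixes["fix_dim"] = fix_dim
    fixes["pdop"] = np.round(pdop, 2)

    meta = pd.DataFrame(
        {
            "animal_id": animal_ids,
            "year": years,
            "parturient": rng.choice(["yes", "no"], size=A),
            "excluded_herd_switch": False,
        }
    )
    truth = TruthBundle(
        true_beta=dict(cfg.true_beta),
        realized_step_lengths=np.concatenate(step_lengths) if step_lengths else np.empty(0),
        realized_bearings=np.concatenate(step_bearings) if step_bearings else np.empty(0),
        per_animal_intercepts={aid: float(v) for aid, v in zip(animal_ids, a_int)},
        per_year_intercepts=y_int,
    )
    return TrackSet(fixes=fixes, meta=meta), truth


def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (triangular fold; handles far misses)."""
    span = hi - lo
    v = np.mod(v - lo, 2 * span)
    v = np.where(v > span, 2 * span - v, v)
    return v + lo


# ---------------------------------------------------------------------------
# clustered binary data for mixed-model recovery tests


def simulate_mixed_logistic(
    n_groups: int = 50,
    n_per_group: int = 40,
    beta: dict | None = None,
    intercept: float = 0.0,
    re_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli observations with a group random intercept.

    A minimal data generator for checking the mixed logistic estimator:
    y_ij ~ Bernoulli(logit^-1(b0 + u_i + x_ij' beta)), u_i ~ N(0, re_sd^2).
    """
    beta = {"x1": 1.0, "x2": -0.5} if beta is None else beta
    rng = np.random.default_rng(seed)
    names = list(beta.keys())
    b = np.array([beta[k] for k in names])
    n = n_groups * n_per_group
    X = rng.standard_normal((n, len(names)))
    groups = np.repeat(np.arange(n_groups), n_per_group)
    u = rng.normal(0.0, re_sd, size=n_groups)
    eta = intercept + u[groups] + X @ b
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    df = pd.DataFrame(X, columns=names)
    df["y"] = y
    df["animal_id"] = [f"G{g:03d}" for g in groups]
    return df
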