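"""End-to-end orchestration: preprocess, covariates, designs, fits, maps.

``run_pipeline`` executes the full two-scale analysis from files on disk
(GPS fix CSV, weather CSV, raster stack directory) and writes fits,
validation results, prediction surfaces, and a reproducibility manifest.
``make_demo_inputs`` materializes a complete synthetic study (landscape,
weather, tracks with known selection coefficients) so the pipeline can be
run end-to-end without any proprietary data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariates as cov
from . import insects, models, preprocessing as prep, sampling, validation
from .raster import read_landscape_stack
from .synthetic import SyntheticConfig, generate_landscape, simulate_tracks, simulate_weather

log = logging.getLogger("caribou_rsf")

__all__ = ["RunConfig", "load_config", "run_pipeline", "make_demo_inputs", "run_demo"]

#: Selection coefficients used by the demo simulation (per-SD / indicator scale).
DEMO_TRUE_BETA = {"sedge_grass_meadow": 1.0, "wet_tundra": -0.6, "dist_coast": -0.4}


@dataclass
class RunConfig:
    """All file paths, thresholds, and seeds of one analysis run."""

    fixes_csv: str
    weather_csv: str
    stack_dir: str
    out_dir: str
    parturition_csv: str | None = None
    pdop_max: float = 10.0
    min_move_m: float = 25.0
    insect_threshold: float = 0.5
    insect_lookback_h: float = 12.0
    vif_threshold: float = 3.0
    isopleth: float = 0.95
    n_per_used: int = 5
    kfold_k: int = 5
    kfold_bins: int = 10
    ttlqv_max_block: int = 32
    seed: int = 0
    landscape_covariates: tuple = ("elevation", "dist_coast", "vrm")
    patch_covariates: tuple = ("elevation", "dist_coast", "vrm")

    def validate_paths(self) -> None:
        for name in ("fixes_csv", "weather_csv", "stack_dir"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    return RunConfig(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _analysis_groups(fixes: pd.DataFrame):
    """Split season-labelled fixes into the eight analysis groups."""
    groups = {}
    for season, g in fixes.groupby("season", sort=False):
        if season == "calving":
            for status in ("yes", "no"):
                sub = g.loc[g["parturient"] == status]
                tag = "calving_parturient" if status == "yes" else "calving_nonparturient"
                groups[tag] = sub
        elif season in ("mosquito", "oestrid_fly"):
            for state in ("high", "low"):
                sub = g.loc[g["insect_state"] == state]
                groups[f"{season}_{state}"] = sub
        elif season == "off_season":
            continue
        else:
            groups[season] = g
    return {k: v for k, v in groups.items() if len(v)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full two-scale analysis; returns the run manifest."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "started_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "inputs": {
            "fixes_csv": _sha256(Path(config.fixes_csv)),
            "weather_csv": _sha256(Path(config.weather_csv)),
        },
        "stages": {},
        "groups": {},
    }

    # -- preprocessing ------------------------------------------------------
    raw = prep.read_fixes_csv(config.fixes_csv)
    trackset, report = prep.screen_fixes(raw, pdop_max=config.pdop_max)
    if config.parturition_csv:
        part = pd.read_csv(config.parturition_csv)
        merged = trackset.meta.drop(columns=["parturient"]).merge(
            part[["animal_id", "year", "parturient"]], on=["animal_id", "year"], how="left")
        merged["parturient"] = merged["parturient"].fillna("unknown")
        trackset = prep.TrackSet(fixes=trackset.fixes, meta=merged)
    trackset = prep.filter_sedentary(trackset, min_move=config.min_move_m)
    trackset = prep.assign_seasons(trackset)
    report.to_json(out / "screen_report.json")
    manifest["stages"]["screening"] = {
        "n_raw": report.n_input,
        "n_retained_screen": report.n_retained,
        "removal_fraction": report.removal_fraction,
        "n_after_sedentary": len(trackset.fixes),
    }
    log.info("screening: %d -> %d fixes (%.2f%% removed)", report.n_input,
             report.n_retained, 100 * report.removal_fraction)

    fixes = trackset.analysis_fixes().copy()
    meta = trackset.meta.set_index(["animal_id", "year"]) if len(trackset.meta) else None
    if meta is not None and "parturient" in meta.columns:
        yrs = fixes["timestamp"].dt.year
        key = pd.MultiIndex.from_arrays([fixes["animal_id"], yrs])
        part = meta["parturient"].reindex(key).to_numpy()
        fixes["parturient"] = np.where(pd.isna(part), "unknown", part)
    else:
        fixes["parturient"] = "unknown"

    # -- insect classification ---------------------------------------------
    weather = pd.read_csv(config.weather_csv, parse_dates=["timestamp"])
    mosq = insects.InsectIndexParams(species="mosquito", temp_lo=6.0, wind_hi=6.0,
                                     threshold=config.insect_threshold,
                                     lookback_hours=config.insect_lookback_h)
    fly = insects.InsectIndexParams(species="fly", temp_lo=13.0, wind_hi=9.0,
                                    threshold=config.insect_threshold,
                                    lookback_hours=config.insect_lookback_h)
    fixes["insect_state"] = "low"
    for season, params in (("mosquito", mosq), ("oestrid_fly", fly)):
        m = fixes["season"] == season
        if m.any():
            fixes.loc[m, "insect_state"] = insects.classify_fixes(fixes.loc[m, "timestamp"], weather, params)
    n_unknown = int((fixes["insect_state"] == "unknown").sum())
    fixes = fixes.loc[fixes["insect_state"] != "unknown"].reset_index(drop=True)
    manifest["stages"]["insect_classification"] = {"n_unknown_excluded": n_unknown}

    # -- covariate stack ----------------------------------------------------
    stack = read_landscape_stack(config.stack_dir)
    scales = cov.attach_standard_layers(stack, max_block=config.ttlqv_max_block)
    manifest["stages"]["ttlqv_scales_m"] = {k: float(v) for k, v in scales.items()}
    landmask = stack.water_mask.copy_with(stack.land)

    density_cols = tuple(f"density_{n}" for n in scales)
    landscape_spec = cov.DesignSpec(
        covariates=tuple(config.landscape_covariates) + density_cols
        + (("greenup_date", "maxgrowth_date") if "greenup_date" in stack.layers else ())
        + (("precip",) if stack.precip is not None else ()),
        layer_aliases={"elevation": "dem"},
    )
    patch_spec = cov.DesignSpec(covariates=tuple(config.patch_covariates),
                                layer_aliases={"elevation": "dem"})

    # -- per-group fits -----------------------------------------------------
    fixes["year"] = fixes["timestamp"].dt.year
    for tag, used in _analysis_groups(fixes).items():
        entry: dict = {"n_used_fixes": int(len(used))}
        try:
            entry.update(_fit_group(tag, used, stack, landmask, landscape_spec,
                                    patch_spec, config, rng, out))
        except Exception as e:  # keep partial outputs, record the stage failure
            entry["error"] = f"{type(e).__name__}: {e}"
            log.warning("group %s failed: %s", tag, e)
        manifest["groups"][tag] = entry

    manifest["finished_utc"] = datetime.now(timezone.utc).isoformat(timespec="seconds")
    man_for_disk = dict(manifest)
    (out / "manifest.json").write_text(json.dumps(man_for_disk, indent=2, default=str))
    return manifest


def _fit_group(tag, used, stack, landmask, landscape_spec, patch_spec, config, rng, out: Path) -> dict:
    """Landscape and patch fits for one season/status/insect group."""
    entry: dict = {}
    used_pts = used[["animal_id", "timestamp", "x", "y", "season", "year"]].copy()

    # landscape scale: range -> 1:1 availability -> GLMM
    if len(used_pts) >= 30:
        rpoly = sampling.kde_range(used_pts, level=config.isopleth,
                                   cell_size=stack.cell_size, season=tag)
        table = sampling.build_landscape_table(used_pts, rpoly, landmask, rng)
        design = cov.build_design(table, stack, landscape_spec)
        keep, drops = cov.vif_prune(design, threshold=config.vif_threshold)
        entry["vif_dropped"] = [c for c, _ in drops]
        keep, sparse = _drop_sparse_dummies(design.frame, keep)
        entry["sparse_dropped"] = sparse
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = models.fit_mixed_logistic(design.frame, keep, groups=("animal_id", "year"))
        entry["landscape"] = fit.to_json_dict()
        (out / f"fit_landscape_{tag}.json").write_text(json.dumps(fit.to_json_dict(), indent=2))

        n_animals = design.frame["animal_id"].nunique()
        if n_animals >= config.kfold_k:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                val = validation.kfold_validate(design.frame, keep, k=config.kfold_k,
                                                bins=config.kfold_bins, seed=rng)
            entry["kfold"] = val.to_json_dict()
        surf = validation.predict_surface(fit, stack, design.transforms, landscape_spec, season=tag)
        surf.raster.write_ascii(out / f"w_{tag}.asc")
        validation.classify_surface(surf).write_ascii(out / f"w_{tag}_classed.asc")
        entry["surface"] = f"w_{tag}.asc"

    # patch scale: 5:1 matched steps -> conditional logistic -> robust SE
    steps = sampling.sample_available_steps(used, n_per_used=config.n_per_used,
                                            landscape=stack, seed=rng)
    if len(steps) >= 50 * (config.n_per_used + 1):
        pdesign = cov.build_design(steps, stack, patch_spec)
        # strata losing rows to water/no-data must be rebalanced
        frame = _rebalance_strata(pdesign.frame, config.n_per_used)
        keep_p, drops_p = cov.vif_prune(frame[list(pdesign.covariate_names)],
                                        threshold=config.vif_threshold)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pfit = models.fit_conditional_logistic(frame, keep_p)
            lag = models.residual_lag(pfit, frame, keep_p)
            rfit = models.robust_refit(pfit, frame, keep_p, lag=lag)
        entry["patch"] = rfit.to_json_dict()
        (out / f"fit_patch_{tag}.json").write_text(json.dumps(rfit.to_json_dict(), indent=2))
    return entry


def _drop_sparse_dummies(frame: pd.DataFrame, cols, min_count: int = 8):
    """Drop indicator columns observed in fewer than ``min_count`` rows per
    response level; such categories are separation-prone and inestimable."""
    keep, dropped = [], []
    y = frame["used"].to_numpy()
    for c in cols:
        v = frame[c].to_numpy(float)
        if set(np.unique(v)) <= {0.0, 1.0}:
            n1 = int(v[y == 1].sum())
            n0 = int(v[y == 0].sum())
            if min(n0, n1) < min_count:
                dropped.append(c)
                continue
        keep.append(c)
    return keep, dropped


def _rebalance_strata(frame: pd.DataFrame, n_per_used: int) -> pd.DataFrame:
    """Drop strata that lost their used row or all available rows."""
    g = frame.groupby("stratum_id")["used"]
    ok = (g.sum() == 1) & (g.count() >= 2)
    return frame.loc[frame["stratum_id"].map(ok)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# synthetic demo


def make_demo_inputs(out_dir: str | Path, seed: int = 0, n_animals: int = 8,
                     n_steps: int = 1284, grid: int = 160,
                     true_beta: dict | None = None) -> dict:
    """Write a complete synthetic input set (stack, fixes, weather, truth).

    The default track length (1284 two-hour steps) spans the whole summer
    calendar, calving through late summer.  Returns the paths plus the
    ground-truth coefficients.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(
        grid_nrows=grid, grid_ncols=grid,
        n_animals=n_animals, n_steps_per_animal=n_steps,
        true_beta=dict(true_beta if true_beta is not None else DEMO_TRUE_BETA),
        seed=seed,
    )
    stack = generate_landscape(cfg)
    stack.write(out / "stack")
    trackset, truth = simulate_tracks(stack, cfg)
    prep.write_fixes_csv(trackset.fixes, out / "fixes.csv")
    trackset.meta.to_csv(out / "animal_years.csv", index=False)

    years = sorted(trackset.fixes["timestamp"].dt.year.unique())
    frames = []
    for yr in years:
        frames.append(simulate_weather(
            cfg, datetime(int(yr), 5, 25, tzinfo=timezone.utc),
            datetime(int(yr), 9, 20, tzinfo=timezone.utc)))
    weather = pd.concat(frames, ignore_index=True)
    weather.to_csv(out / "weather.csv", index=False)
    (out / "truth.json").write_text(json.dumps(truth.to_json_dict(), indent=2))
    return {
        "fixes_csv": str(out / "fixes.csv"),
        "weather_csv": str(out / "weather.csv"),
        "stack_dir": str(out / "stack"),
        "parturition_csv": str(out / "animal_years.csv"),
        "true_beta": dict(cfg.true_beta),
    }


def run_demo(out_dir: str | Path, seed: int = 0, n_animals: int = 8,
             n_steps: int = 1284, grid: int = 160) -> dict:
    """Generate synthetic inputs and run the full pipeline on them."""
    out = Path(out_dir)
    inputs = make_demo_inputs(out / "inputs", seed=seed, n_animals=n_animals,
                              n_steps=n_steps, grid=grid)
    config = RunConfig(
        fixes_csv=inputs["fixes_csv"],
        weather_csv=inputs["weather_csv"],
        stack_dir=inputs["stack_dir"],
        parturition_csv=inputs["parturition_csv"],
        out_dir=str(out / "results"),
        seed=seed,
    )
    manifest = run_pipeline(config)
    manifest["true_beta"] = inputs["true_beta"]
    (Path(config.out_dir) / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
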