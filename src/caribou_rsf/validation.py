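"""k-fold cross-validation and relative-probability-of-use surfaces.

Validation follows the used-point binning approach: folds partition
*animals* (so serially correlated points from one animal never span the
train/test split); the model fitted on the training folds scores the
withheld used and available points; available-point score quantiles define
equal-area bins; and the Spearman rank correlation between bin rank and
the area-adjusted frequency of withheld used points measures predictive
capacity.

Mapping applies the logistic form w(x) = exp(b0 + sum b_i x_i) / (1 +
exp(b0 + sum b_i x_i)) per land pixel — a relative probability of use in
[0, 1] — with water left as no-data.  Patch-scale fits have no intercept
(it is conditioned out), so their surfaces use b0 = 0 and are interpreted
strictly relatively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import spearmanr

from .covariates import DesignSpec
from .models import FitResult, RobustFit, fit_mixed_logistic
from .raster import LandscapeStack, Raster

__all__ = [
    "ValidationResult",
    "PredictionSurface",
    "kfold_validate",
    "predict_surface",
    "classify_surface",
]


@dataclass
class ValidationResult:
    k: int
    rho_mean: float
    p_value: float
    per_fold_rho: list
    bins: int

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not -1.0 <= self.rho_mean <= 1.0:
            raise ValueError("rho_mean outside [-1, 1]")

    def to_json_dict(self) -> dict:
        return {
            "k": self.k,
            "rho_mean": float(self.rho_mean),
            "p_value": float(self.p_value),
            "per_fold_rho": [float(r) for r in self.per_fold_rho],
            "bins": self.bins,
        }


@dataclass
class PredictionSurface:
    """w(x) raster in [0, 1] over land; water/no-data masked."""

    raster: Raster
    season: str = ""
    model: str = ""
    intercept_used: bool = True


def kfold_validate(table, covariates=None, k: int = 5, bins: int = 10,
                   seed: int | np.random.Generator = 0, fitter=None,
                   animal_col: str = "animal_id", response: str = "used") -> ValidationResult:
    """Animal-partitioned k-fold validation of an RSF.

    ``fitter(train_frame) -> FitResult`` defaults to a plain logistic fit on
    the given covariates.  Folds with no withheld used point are skipped
    (reducing k with a warning).  The p-value is a one-sided (increasing)
    Spearman test on the fold-averaged area-adjusted frequencies.
    """
    from .covariates import CovariateTable

    if isinstance(table, CovariateTable):
        covariates = covariates or list(table.covariate_names)
        table = table.frame
    covariates = list(covariates)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    animals = np.array(sorted(table[animal_col].astype(str).unique()))
    if len(animals) < k:
        raise ValueError(f"need at least k={k} animals for animal-partitioned folds")
    perm = rng.permutation(len(animals))
    folds = [animals[perm[i::k]] for i in range(k)]
    if fitter is None:
        fitter = lambda df: fit_mixed_logistic(df, covariates, response=response, groups=())

    beta_cols = None
    rhos = []
    freq_rows = []
    for fold_animals in folds:
        test_mask = table[animal_col].astype(str).isin(fold_animals)
        train = table.loc[~test_mask]
        test = table.loc[test_mask]
        if test[response].sum() == 0 or train[response].sum() == 0:
            warnings.warn("fold without used points skipped; k reduced", stacklevel=2)
            continue
        fit = fitter(train)
        beta_cols = [c for c in fit.beta.index if c != "intercept"]
        score = test[beta_cols].to_numpy(float) @ fit.beta[beta_cols].to_numpy()
        avail = score[test[response].to_numpy() == 0]
        used = score[test[response].to_numpy() == 1]
        edges = np.quantile(avail, np.linspace(0, 1, bins + 1))
        edges[0], edges[-1] = -np.inf, np.inf
        used_counts = np.histogram(used, bins=edges)[0].astype(float)
        avail_counts = np.clip(np.histogram(avail, bins=edges)[0].astype(float), 1.0, None)
        adj = (used_counts / used_counts.sum()) / (avail_counts / avail_counts.sum())
        rho = spearmanr(np.arange(1, bins + 1), adj).statistic
        rhos.append(float(rho))
        freq_rows.append(adj)

    if len(rhos) < 2:
        raise ValueError("fewer than 2 usable folds")
    mean_adj = np.mean(freq_rows, axis=0)
    res = spearmanr(np.arange(1, bins + 1), mean_adj)
    # one-sided test for an increasing relationship
    p = res.pvalue / 2.0 if res.statistic > 0 else 1.0 - res.pvalue / 2.0
    return ValidationResult(
        k=len(rhos),
        rho_mean=float(np.mean(rhos)),
        p_value=float(p),
        per_fold_rho=rhos,
        bins=bins,
    )


def predict_surface(fit, stack: LandscapeStack, transforms: dict,
                    spec: DesignSpec | None = None, season: str = "") -> PredictionSurface:
    """Map a fitted RSF over the landscape as w(x) in [0, 1].

    ``transforms`` is the per-column metadata stored by the design builder
    (transform name, training mean and SD), so pixels are scaled exactly as
    the fitting sample was.  Patch-scale fits carry no intercept; b0 = 0 is
    used and recorded via ``intercept_used=False``.
    """
    base = fit.fit if isinstance(fit, RobustFit) else fit
    spec = spec or DesignSpec()
    grid = stack.grid
    land = stack.land
    eta = np.zeros(grid.shape, dtype=float)
    b0 = float(base.beta.get("intercept", 0.0))
    intercept_used = "intercept" in base.beta.index

    std_cache: dict[str, np.ndarray] = {}

    def standardized_layer(name: str) -> np.ndarray:
        if name in std_cache:
            return std_cache[name]
        layer = stack.layer(spec.layer_aliases.get(name, name))
        vals = layer.data.astype(float)
        vals = np.where(layer.is_nodata(vals), np.nan, vals)
        meta = transforms.get(name)
        if meta is None:
            raise KeyError(f"no transform metadata for covariate {name!r}")
        tr = meta["transform"]
        if tr.startswith("log"):
            vals = np.log(vals + stack.cell_size)
        elif tr == "sqrt":
            vals = np.sqrt(np.clip(vals, 0.0, None))
        sd = meta["sd"] if meta["sd"] > 0 else 1.0
        out = (vals - meta["mean"]) / sd
        std_cache[name] = out
        return out

    for name, coef in base.beta.items():
        if name == "intercept":
            continue
        if name.startswith("patch_"):
            cls = name[len("patch_"):]
            if cls not in stack.class_names:
                raise KeyError(f"covariate {name!r}: class {cls!r} not in stack")
            k = stack.class_names.index(cls)
            eta += coef * (stack.veg_class.data == k)
        elif name.endswith("_sq"):
            eta += coef * standardized_layer(name[:-3]) ** 2
        else:
            eta += coef * standardized_layer(name)

    w = expit(b0 + eta)
    w = np.where(land, w, np.nan)
    return PredictionSurface(
        raster=Raster(w, grid.cell_size, grid.x0, grid.y0, nodata=np.nan),
        season=season,
        model=base.model,
        intercept_used=intercept_used,
    )


def classify_surface(surface: PredictionSurface, n_classes: int = 10) -> Raster:
    """Equal-quantile classes over land cells; class n = highest w.

    Water/no-data cells get class 0.  A constant surface collapses to a
    single class with a warning.
    """
    r = surface.raster
    w = r.data
    land = np.isfinite(w)
    vals = w[land]
    if vals.size == 0:
        raise ValueError("surface has no land cells")
    if np.ptp(vals) == 0:
        warnings.warn("constant surface: single class", stacklevel=2)
        out = np.zeros(r.shape, dtype=np.uint8)
        out[land] = 1
        return Raster(out, r.cell_size, r.x0, r.y0, nodata=0)
    edges = np.quantile(vals, np.linspace(0, 1, n_classes + 1))[1:-1]
    classes = np.searchsorted(edges, vals, side="right") + 1
    out = np.zeros(r.shape, dtype=np.uint8)
    out[land] = classes.astype(np.uint8)
    return Raster(out, r.cell_size, r.x0, r.y0, nodata=0)
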