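"""Self-contained recovery and calibration experiments.

Each function generates its own synthetic inputs with the package's
generators, runs the estimator under test, and returns summary numbers.
They back both the acceptance test suite and ``scripts/acceptance.py``:
everything is recomputed from scratch at call time, seeded through a
single integer.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import expit

from .models import (
    fit_conditional_logistic,
    fit_mixed_logistic,
    residual_lag,
    robust_refit,
)
from .preprocessing import screen_fixes
from .sampling import sample_available_steps
from .synthetic import (
    SyntheticConfig,
    generate_landscape,
    sample_covariates,
    simulate_mixed_logistic,
    simulate_tracks,
)
from .validation import kfold_validate

__all__ = [
    "ssf_recovery",
    "glmm_recovery",
    "kfold_discrimination",
    "screening_loss",
    "kde_isopleth_coverage",
]

#: Step-selection coefficients recovered in the SSF experiment
#: (per-indicator scale on three vegetation classes).
SSF_TRUE_BETA = {"tussock_tundra": 1.0, "dwarf_shrub": -0.5, "wet_tundra": 0.3}


def ssf_recovery(n_datasets: int = 20, n_animals: int = 20, n_steps: int = 500,
                 true_beta: dict | None = None, seed: int = 0) -> dict:
    """Parameter recovery of the full patch-scale pipeline.

    Per dataset: simulate tracks on a fresh landscape with known selection
    coefficients, build the 5:1 matched availability design by empirical
    rate/bearing resampling, fit the conditional logistic model, measure
    the residual correlation lag, and compute robust standard errors by
    the split-refit rule.  Coverage counts 95% CIs (beta +/- 1.96 robust
    SE, the analysis's own inference rule) that contain the truth.
    """
    true_beta = dict(true_beta or SSF_TRUE_BETA)
    names = list(true_beta)
    truth = np.array([true_beta[k] for k in names])
    ests, covered = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_datasets):
            cfg = SyntheticConfig(grid_nrows=250, grid_ncols=250,
                                  n_animals=n_animals, n_steps_per_animal=n_steps,
                                  true_beta=true_beta, seed=seed * 1000 + rep)
            stack = generate_landscape(cfg)
            tracks, _ = simulate_tracks(stack, cfg)
            fixes = tracks.fixes[["animal_id", "timestamp", "x", "y"]]
            table = sample_available_steps(fixes, n_per_used=5, landscape=stack,
                                           seed=seed * 1000 + rep + 500)
            covs = sample_covariates(stack, names, table["x"].to_numpy(), table["y"].to_numpy())
            df = pd.concat([table.reset_index(drop=True), covs], axis=1)
            fit = fit_conditional_logistic(df, names)
            lag = residual_lag(fit, df, names)
            rob = robust_refit(fit, df, names, lag=lag)
            est = fit.beta.to_numpy()
            se = rob.se_robust.to_numpy()
            ests.append(est)
            covered.append((np.abs(est - truth) <= 1.96 * se))
    ests = np.asarray(ests)
    covered = np.asarray(covered)
    return {
        "names": names,
        "true": truth,
        "mean_estimates": ests.mean(axis=0),
        "mean_abs_bias": np.abs(ests.mean(axis=0) - truth),
        "coverage": float(covered.mean()),
        "n_datasets": n_datasets,
        "n_strata_per_dataset": n_animals * (n_steps - 1),
    }


def glmm_recovery(n_reps: int = 20, n_groups: int = 50, n_per_group: int = 40,
                  re_sd: float = 1.0, seed: int = 0) -> dict:
    """Random-intercept recovery for the Laplace mixed logistic fit.

    Also checks the nesting limit: with the random-intercept SD at its
    boundary value of zero, the mixed machinery must reproduce the pooled
    logistic fit.  (A freely estimated SD on null data is positive on
    roughly half of datasets — for any correct ML implementation — and
    then the fixed effects legitimately drift by a few thousandths, so
    the limit is checked at the boundary, where it is exact.)
    """
    import statsmodels.api as sm

    beta = {"x1": 1.0, "x2": -0.5}
    df0 = simulate_mixed_logistic(n_groups=n_groups, n_per_group=n_per_group,
                                  beta=beta, re_sd=0.0, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mixed0 = fit_mixed_logistic(df0, list(beta), response="y", groups=("animal_id",),
                                    re_sd_fixed={"animal_id": 0.0})
        pooled = sm.Logit(df0["y"], sm.add_constant(df0[list(beta)])).fit(disp=0)
        sd0_max_diff = float(np.abs(mixed0.beta.to_numpy() - pooled.params.to_numpy()).max())

        ests, sds = [], []
        for rep in range(n_reps):
            df = simulate_mixed_logistic(n_groups=n_groups, n_per_group=n_per_group,
                                         beta=beta, re_sd=re_sd, seed=seed * 100 + rep + 1)
            f = fit_mixed_logistic(df, list(beta), response="y", groups=("animal_id",))
            ests.append(f.beta[list(beta)].to_numpy())
            sds.append(f.re_sd["animal_id"])
    mean_beta = np.mean(ests, axis=0)
    return {
        "sd0_max_diff": sd0_max_diff,
        "mean_beta": mean_beta,
        "beta_max_abs_error": float(np.abs(mean_beta - np.array([1.0, -0.5])).max()),
        "mean_re_sd": float(np.mean(sds)),
        "re_sd_error": float(abs(np.mean(sds) - re_sd)),
        "n_reps": n_reps,
        "n_obs": n_groups * n_per_group,
    }


def _selection_table(rng, beta=(2.0, -1.0), n=4000, n_animals=10, shuffle=False):
    X = rng.normal(size=(n, 2))
    used = (rng.random(n) < expit(X @ np.asarray(beta))).astype(int)
    df = pd.DataFrame(X, columns=["x1", "x2"])
    df["used"] = used
    df["animal_id"] = rng.choice([f"A{i}" for i in range(n_animals)], n)
    if shuffle:
        perm = rng.permutation(n)
        df[["x1", "x2"]] = df[["x1", "x2"]].to_numpy()[perm]
    return df


def kfold_discrimination(n_reps: int = 20, seed: int = 0) -> dict:
    """k-fold validation on model-true data vs shuffled-covariate nulls.

    Strong selection simulated exactly from the logistic RSF form must
    validate with high Spearman rho; destroying the covariate-use link by
    row shuffling must drop |rho| to noise; the paired comparison counts
    how often the true-model rho beats its shuffled twin.
    """
    rho_true, rho_null, wins = [], [], 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_reps):
            rng = np.random.default_rng(seed * 100 + rep)
            t = kfold_validate(_selection_table(rng), ["x1", "x2"], k=5, seed=rng)
            s = kfold_validate(_selection_table(rng, shuffle=True), ["x1", "x2"], k=5, seed=rng)
            rho_true.append(t.rho_mean)
            rho_null.append(s.rho_mean)
            wins += t.rho_mean > s.rho_mean
    return {
        "rho_true_mean": float(np.mean(rho_true)),
        "rho_shuffled_mean": float(np.mean(rho_null)),
        "paired_wins": int(wins),
        "n_reps": n_reps,
    }


def screening_loss(seed: int = 0, n_animals: int = 10, n_steps: int = 5999,
                   grid: int = 160) -> dict:
    """Fraction of fixes removed by 2D/PDOP screening on synthetic tracks.

    The generator injects its configured 2.6% of bad fixes; screening must
    find them back.
    """
    cfg = SyntheticConfig(grid_nrows=grid, grid_ncols=grid, seed=seed,
                          n_animals=n_animals, n_steps_per_animal=n_steps)
    stack = generate_landscape(cfg)
    tracks, _ = simulate_tracks(stack, cfg)
    _, report = screen_fixes(tracks.fixes)
    return {
        "removal_fraction": report.removal_fraction,
        "injected_fraction": cfg.rate_2d + cfg.rate_high_pdop,
        "n_fixes": report.n_input,
    }


def kde_isopleth_coverage(n: int = 10000, level: float = 0.95, seed: int = 0) -> dict:
    """Containment of a bivariate normal sample by its KDE isopleth."""
    from .sampling import kde_range

    rng = np.random.default_rng(seed)
    pts = pd.DataFrame({"x": rng.normal(0, 1000, n), "y": rng.normal(0, 700, n)})
    rp = kde_range(pts, level)
    frac = float(rp.contains(pts["x"].to_numpy(), pts["y"].to_numpy()).mean())
    return {"coverage": frac, "level": level, "n_points": n}
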