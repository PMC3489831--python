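"""Selection model fitting at both scales.

Landscape scale: logistic regression with crossed random intercepts for
animal and year, maximized by a Laplace approximation to the marginal
likelihood (penalized IRLS inner loop, profiled outer optimization over
the random-effect SDs) — the same approximation glmer uses by default.

Patch scale: conditional logistic regression over matched strata (one used
location + its matched available locations), maximized by Newton-Raphson
on the exact conditional likelihood
``sum_s [beta' x_used - log sum_j exp(beta' x_j)]``.

Serial autocorrelation in the matched design is handled by summing
deviance residuals per stratum, measuring the residual correlation lag,
thinning strata into two interleaved groups at that lag, refitting on
each, and averaging the two covariance matrices (a robust covariance
giving adjusted standard errors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "SeparationError",
    "ConvergenceError",
    "FitResult",
    "RobustFit",
    "fit_conditional_logistic",
    "fit_mixed_logistic",
    "all_subsets_aic",
    "quadratic_screen",
    "deviance_residuals",
    "residual_lag",
    "robust_refit",
]


class SeparationError(RuntimeError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class FitResult:
    """Coefficients, covariance, and fit statistics from one model fit."""

    beta: pd.Series
    vcov_naive: np.ndarray
    loglik: float
    k: int
    model: str
    n_obs: int
    n_strata: int = 0
    re_sd: dict = field(default_factory=dict)
    gradient_norm: float = np.nan
    converged: bool = True

    @property
    def se_naive(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov_naive)), index=self.beta.index)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    def to_json_dict(self) -> dict:
        return {
            "model": self.model,
            "beta": {k: float(v) for k, v in self.beta.items()},
            "se_naive": {k: float(v) for k, v in self.se_naive.items()},
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "k": int(self.k),
            "re_sd": {k: float(v) for k, v in self.re_sd.items()},
            "converged": bool(self.converged),
        }


@dataclass
class RobustFit:
    """A base fit plus autocorrelation-robust covariance.

    ``significant`` flags coefficients whose 95% CI (beta +/- 1.96 robust
    SE) excludes zero.
    """

    fit: FitResult
    vcov_robust: np.ndarray
    residual_lag: int
    fallback_naive: bool = False

    @property
    def beta(self) -> pd.Series:
        return self.fit.beta

    @property
    def se_robust(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov_robust)), index=self.fit.beta.index)

    @property
    def significant(self) -> pd.Series:
        lo = self.beta - 1.96 * self.se_robust
        hi = self.beta + 1.96 * self.se_robust
        return (lo > 0) | (hi < 0)

    def to_json_dict(self) -> dict:
        d = self.fit.to_json_dict()
        d["se_robust"] = {k: float(v) for k, v in self.se_robust.items()}
        d["residual_lag"] = int(self.residual_lag)
        d["significant"] = {k: bool(v) for k, v in self.significant.items()}
        return d


# ---------------------------------------------------------------------------
# conditional logistic


def _prepare_strata(df: pd.DataFrame, covariates, strata_col: str, response: str):
    d = df.sort_values(strata_col, kind="stable").reset_index(drop=True)
    X = d[list(covariates)].to_numpy(float)
    y = d[response].to_numpy(float)
    sid = d[strata_col].to_numpy()
    change = np.empty(len(d), dtype=bool)
    change[0] = True
    change[1:] = sid[1:] != sid[:-1]
    starts = np.flatnonzero(change)
    counts = np.diff(np.append(starts, len(d)))
    used_per = np.add.reduceat(y, starts)
    if np.any(used_per != 1):
        raise ValueError("every stratum must contain exactly one used row")
    if np.any(counts < 2):
        raise ValueError("every stratum must contain at least one available row")
    return d, X, y, starts, counts


def _clogit_ll_grad_hess(beta, X, y, starts, counts, want_hess=True):
    eta = X @ beta
    m = np.maximum.reduceat(eta, starts)
    ex = np.exp(eta - np.repeat(m, counts))
    s = np.add.reduceat(ex, starts)
    w = ex / np.repeat(s, counts)
    lse = m + np.log(s)
    ll = float(eta[y == 1].sum() - lse.sum())
    wx = w[:, None] * X
    xbar = np.add.reduceat(wx, starts, axis=0)
    grad = X[y == 1].sum(axis=0) - xbar.sum(axis=0)
    if not want_hess:
        return ll, grad, None
    h_neg = X.T @ wx - xbar.T @ xbar  # negative Hessian, PSD
    return ll, grad, h_neg


def fit_conditional_logistic(table, covariates=None, strata_col: str = "stratum_id",
                             response: str = "used", tol: float = 1e-8,
                             max_iter: int = 100) -> FitResult:
    """Fit the matched-strata conditional logistic model by Newton-Raphson.

    ``table`` is a DataFrame (or CovariateTable) with one used row and >= 1
    available rows per stratum.  Iterates until the gradient norm is below
    ``tol``.  Raises :class:`SeparationError` when a covariate is constant
    within every stratum (inestimable) or the estimates diverge.
    """
    from .covariates import CovariateTable

    if isinstance(table, CovariateTable):
        covariates = covariates or table.covariate_names
        table = table.frame
    if covariates is None:
        raise ValueError("covariates must be given for a plain DataFrame")
    names = list(covariates)
    d, X, y, starts, counts = _prepare_strata(table, names, strata_col, response)

    # estimability: a column constant within every stratum carries no signal
    for j, nm in enumerate(names):
        col = X[:, j]
        rng_within = np.maximum.reduceat(col, starts) - np.minimum.reduceat(col, starts)
        if np.all(rng_within == 0):
            raise SeparationError(f"covariate {nm!r} is constant within every stratum")
        if np.any(rng_within == 0):
            warnings.warn(
                f"covariate {nm!r} is constant in {int((rng_within == 0).sum())} strata "
                "(those strata contribute no information for it)",
                stacklevel=2,
            )

    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, h_neg = _clogit_ll_grad_hess(beta, X, y, starts, counts)
    for _ in range(max_iter):
        gnorm = float(np.linalg.norm(grad))
        if gnorm < tol:
            break
        try:
            step = np.linalg.solve(h_neg + 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError as e:
            raise SeparationError(f"singular information matrix: {e}") from e
        # backtracking line search on the conditional log-likelihood
        t = 1.0
        for _ in range(40):
            ll_new, grad_new, h_new = _clogit_ll_grad_hess(beta + t * step, X, y, starts, counts)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        ll, grad, h_neg = ll_new, grad_new, h_new
        if np.max(np.abs(beta)) > 50:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise SeparationError(f"estimates diverging; separation suspected in {worst!r}")
    gnorm = float(np.linalg.norm(grad))
    if gnorm >= tol:
        raise ConvergenceError(f"Newton did not converge: gradient norm {gnorm:.3g}")
    vcov = np.linalg.inv(h_neg + 1e-12 * np.eye(p))
    return FitResult(
        beta=pd.Series(beta, index=names),
        vcov_naive=vcov,
        loglik=ll,
        k=p,
        model="conditional_logistic",
        n_obs=len(d),
        n_strata=len(starts),
        gradient_norm=gnorm,
    )


# ---------------------------------------------------------------------------
# mixed logistic (Laplace)


def fit_mixed_logistic(table, covariates=None, response: str = "used",
                       groups=("animal_id", "year"), tol: float = 1e-8,
                       max_inner: int = 100, re_sd_fixed: dict | None = None) -> FitResult:
    """Random-intercept logistic regression via the Laplace approximation.

    Crossed Gaussian random intercepts, one per factor in ``groups``
    (factors absent from the table, or with a single level, are dropped).
    The spherical parametrization eta = b0 + X beta + sum_f sd_f Z_f v_f
    with penalty ||v||^2/2 keeps the boundary sd = 0 well behaved, where
    the model reduces exactly to pooled logistic regression.

    ``re_sd_fixed`` pins the random-effect SDs (by factor name) instead of
    estimating them — the boundary value 0 gives the exact pooled nesting
    limit; other values support sensitivity analyses.
    """
    from .covariates import CovariateTable

    if isinstance(table, CovariateTable):
        covariates = covariates or table.covariate_names
        table = table.frame
    if covariates is None:
        raise ValueError("covariates must be given for a plain DataFrame")
    names = list(covariates)
    X = table[names].to_numpy(float)
    y = table[response].to_numpy(float)
    n, p = X.shape
    if len(np.unique(y)) < 2:
        raise SeparationError("response has a single level")

    factors = []
    for g in groups:
        if g not in table.columns:
            continue
        codes, levels = pd.factorize(table[g], sort=True)
        if len(levels) >= 2:
            factors.append((g, codes, len(levels)))
    q = [nf for _, _, nf in factors]
    qtot = int(sum(q))
    Xf = np.column_stack([np.ones(n), X])  # fixed part with intercept
    pf = p + 1

    def z_matrix():
        Z = np.zeros((n, qtot))
        off = 0
        for _, codes, nf in factors:
            Z[np.arange(n), off + codes] = 1.0
            off += nf
        return Z

    Z = z_matrix() if factors else np.zeros((n, 0))

    state = {"phi": np.zeros(pf + qtot)}

    def _newton(A, P, phi, free, ll_pen=-np.inf):
        """Maximize the penalized Bernoulli loglik over phi[free] (others fixed)."""
        for _ in range(max_inner):
            eta = A @ phi
            mu = expit(eta)
            g_full = A.T @ (y - mu) - P * phi
            g_vec = g_full[free]
            if np.linalg.norm(g_vec) < tol:
                break
            w = np.clip(mu * (1 - mu), 1e-10, None)
            Af = A[:, free]
            H = (Af * w[:, None]).T @ Af + np.diag(P[free])
            try:
                step = np.linalg.solve(H, g_vec)
            except np.linalg.LinAlgError as e:
                raise SeparationError(f"singular penalized information: {e}") from e
            t = 1.0
            for _ in range(40):
                cand = phi.copy()
                cand[free] = phi[free] + t * step
                ll_new = _bernoulli_ll(y, A @ cand) - 0.5 * np.sum(cand[pf:] ** 2)
                if ll_new >= ll_pen - 1e-12:
                    break
                t *= 0.5
            phi = cand
            ll_pen = ll_new
        return phi

    def _laplace_at(A, P, phi):
        eta = A @ phi
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        H = (A * w[:, None]).T @ A + np.diag(P)
        ll_pen = _bernoulli_ll(y, eta) - 0.5 * np.sum(phi[pf:] ** 2)
        if qtot:
            _, logdet = np.linalg.slogdet(H[pf:, pf:])
            return ll_pen - 0.5 * logdet, H, mu
        return ll_pen, H, mu

    def _design(sds):
        lam = (np.concatenate([np.full(nf, sd) for sd, (_, _, nf) in zip(sds, factors)])
               if factors else np.zeros(0))
        A = np.column_stack([Xf, Z * lam]) if qtot else Xf
        P = np.zeros(A.shape[1])
        P[pf:] = 1.0  # unit penalty on the spherical random effects
        return A, P

    all_free = np.ones(pf + qtot, dtype=bool)
    v_free = np.zeros(pf + qtot, dtype=bool)
    v_free[pf:] = True

    def profile_obj(s):
        A, P = _design(np.abs(s))
        state["phi"] = _newton(A, P, state["phi"].copy(), all_free)
        return -_laplace_at(A, P, state["phi"])[0]

    refined = False
    if re_sd_fixed is not None:
        sds = np.array([float(re_sd_fixed.get(name, 0.0)) for name, _, _ in factors])
    elif factors:
        res = minimize(profile_obj, x0=np.full(len(factors), 0.8), method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 200 * len(factors)})
        sds = np.abs(res.x)
        # joint Laplace refinement over (beta, sd) with v profiled out, as in
        # glmer's default Laplace; only worthwhile at low fixed dimension
        if pf + len(factors) <= 12:
            def joint_obj(par):
                s = np.abs(par[pf:])
                A, P = _design(s)
                phi = state["phi"].copy()
                phi[:pf] = par[:pf]
                state["phi"] = _newton(A, P, phi, v_free)
                return -_laplace_at(A, P, state["phi"])[0]

            x0 = np.concatenate([state["phi"][:pf], sds])
            res2 = minimize(joint_obj, x0=x0, method="Nelder-Mead",
                            options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 500 * len(x0)})
            sds = np.abs(res2.x[pf:])
            phi = state["phi"].copy()
            phi[:pf] = res2.x[:pf]
            state["phi"] = phi
            refined = True
    else:
        sds = np.zeros(0)

    A, P = _design(sds)
    final_free = v_free if refined else all_free
    state["phi"] = _newton(A, P, state["phi"].copy(), final_free)
    phi = state["phi"]
    if np.max(np.abs(phi[:pf])) > 50:
        worst = (["intercept"] + names)[int(np.argmax(np.abs(phi[:pf])))]
        raise SeparationError(f"estimates diverging; separation suspected in {worst!r}")
    ll, H, mu = _laplace_at(A, P, phi)
    g_full = A.T @ (y - mu) - P * phi
    gnorm = float(np.linalg.norm(g_full[final_free]))
    vcov_fix = np.linalg.inv(H)[:pf, :pf]
    if gnorm > 1e-4:
        raise ConvergenceError(f"inner optimization did not converge: gradient norm {gnorm:.3g}")
    idx = ["intercept"] + names
    k = pf + len(factors)
    return FitResult(
        beta=pd.Series(phi[:pf], index=idx),
        vcov_naive=vcov_fix,
        loglik=float(ll),
        k=k,
        model="mixed_logistic",
        n_obs=n,
        re_sd={name: float(sd) for (name, _, _), sd in zip(factors, sds)},
        gradient_norm=gnorm,
    )


def _bernoulli_ll(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable sum of y*eta - log(1 + exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


# ---------------------------------------------------------------------------
# model selection


def all_subsets_aic(table, blocks: dict, fitter=None, strata_col: str = "stratum_id",
                    response: str = "used"):
    """Fit every non-empty covariate-block subset and rank by AIC.

    ``blocks`` maps block name -> list of design columns (vegetation enters
    as one block of dummies).  Ties are broken toward fewer parameters.
    Returns ``(best_columns, ranking_frame)``; failed fits are recorded
    with a warning and excluded from the ranking.
    """
    if len(blocks) > 20:
        raise ValueError("too many candidate blocks (combinatorial guard)")
    fitter = fitter or (lambda cols: fit_conditional_logistic(
        table, covariates=cols, strata_col=strata_col, response=response))
    rows = []
    block_names = list(blocks)
    for r in range(1, len(block_names) + 1):
        for combo in combinations(block_names, r):
            cols = [c for b in combo for c in blocks[b]]
            try:
                fit = fitter(cols)
                rows.append({"blocks": combo, "columns": tuple(cols), "k": fit.k,
                             "aic": fit.aic, "loglik": fit.loglik})
            except (SeparationError, ConvergenceError, ValueError) as e:
                warnings.warn(f"subset {combo} failed to fit: {e}", stacklevel=2)
    if not rows:
        raise RuntimeError("no candidate model could be fitted")
    rank = pd.DataFrame(rows).sort_values(["aic", "k"], kind="stable").reset_index(drop=True)
    best = list(rank.loc[0, "columns"])
    return best, rank


def quadratic_screen(table, columns, response: str = "used", delta_aic: float = 2.0):
    """Decide which continuous covariates need a squared term.

    For each column, compares single-variable logistic fits (intercept +
    linear vs intercept + linear + quadratic); the square term is kept when
    it improves AIC by more than ``delta_aic``.  Returns
    ``(squared_columns, log_frame)``.
    """
    import statsmodels.api as sm

    from .covariates import CovariateTable

    if isinstance(table, CovariateTable):
        table = table.frame
    y = table[response].to_numpy(float)
    chosen = []
    log = []
    for colname in columns:
        x = table[colname].to_numpy(float)
        if np.std(x) == 0:
            log.append({"column": colname, "delta_aic": np.nan, "squared": False, "note": "constant, skipped"})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lin = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            quad = sm.Logit(y, sm.add_constant(np.column_stack([x, x**2]))).fit(disp=0)
        d = lin.aic - quad.aic
        sq = bool(d > delta_aic)
        if sq:
            chosen.append(colname)
        log.append({"column": colname, "delta_aic": float(d), "squared": sq, "note": ""})
    return chosen, pd.DataFrame(log)


# ---------------------------------------------------------------------------
# autocorrelation-robust standard errors


def deviance_residuals(fit: FitResult, table, covariates=None, strata_col: str = "stratum_id",
                       response: str = "used") -> np.ndarray:
    """Per-row Bernoulli deviance residuals under the fitted model.

    For the conditional model, fitted probabilities are the within-stratum
    softmax of the linear predictor; for the mixed/plain model, the
    logistic of the linear predictor (fixed effects only).
    """
    from .covariates import CovariateTable

    if isinstance(table, CovariateTable):
        covariates = covariates or table.covariate_names
        table = table.frame
    names = [c for c in fit.beta.index if c != "intercept"]
    X = table[names].to_numpy(float)
    y = table[response].to_numpy(float)
    if fit.model == "conditional_logistic":
        d = table.sort_index()
        sid = d[strata_col].to_numpy()
        order = np.argsort(sid, kind="stable")
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        Xs = X[order]
        ys = y[order]
        sids = sid[order]
        change = np.empty(len(d), dtype=bool)
        change[0] = True
        change[1:] = sids[1:] != sids[:-1]
        starts = np.flatnonzero(change)
        counts = np.diff(np.append(starts, len(d)))
        eta = Xs @ fit.beta[names].to_numpy()
        m = np.maximum.reduceat(eta, starts)
        ex = np.exp(eta - np.repeat(m, counts))
        s = np.add.reduceat(ex, starts)
        p = ex / np.repeat(s, counts)
        p = p[inv]
    else:
        eta = X @ fit.beta[names].to_numpy()
        if "intercept" in fit.beta.index:
            eta = eta + fit.beta["intercept"]
        p = expit(eta)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    dev = -2.0 * (y * np.log(p) + (1 - y) * np.log(1 - p))
    return np.sign(y - p) * np.sqrt(np.clip(dev, 0.0, None))


def residual_lag(fit: FitResult, table, covariates=None, strata_col: str = "stratum_id",
                 animal_col: str = "animal_id", time_col: str = "timestamp",
                 response: str = "used", max_lag: int = 20) -> int:
    """Correlation lag of stratum-summed deviance residuals.

    Residuals are summed per stratum, centered by an intercept-only mixed
    model grouped by animal (random animal means removed), ordered in time
    within each animal, and the empirical ACF is computed per animal.  The
    lag is the smallest L with ACF(L) inside the +/-1.96/sqrt(m) white-noise
    band; the maximum over animals is returned (>= 1).  Animals with fewer
    than 10 strata contribute lag 1 with a warning.
    """
    from statsmodels.tsa.stattools import acf

    from .covariates import CovariateTable

    if isinstance(table, CovariateTable):
        covariates = covariates or table.covariate_names
        table = table.frame
    dev = deviance_residuals(fit, table, covariates, strata_col, response)
    d = table.copy()
    d["_dev"] = dev
    per = (
        d.groupby([animal_col, strata_col], sort=False)
        .agg(dev_sum=("_dev", "sum"), t=(time_col, "first"))
        .reset_index()
        .sort_values([animal_col, "t"], kind="stable")
    )
    per["dev_sum"] = _center_by_group(per["dev_sum"].to_numpy(), per[animal_col].to_numpy())

    lags = []
    for animal, g in per.groupby(animal_col, sort=False):
        r = g["dev_sum"].to_numpy(float)
        m = len(r)
        if m < 10:
            warnings.warn(f"animal {animal}: only {m} strata; lag reported as 1", stacklevel=2)
            lags.append(1)
            continue
        nlags = min(max_lag, m - 1)
        if np.std(r) == 0:
            lags.append(1)
            continue
        a = acf(r, nlags=nlags, fft=True)
        band = 1.96 / np.sqrt(m)
        lag = next((L for L in range(1, nlags + 1) if abs(a[L]) < band), nlags)
        lags.append(max(lag, 1))
    return int(max(lags)) if lags else 1


def _center_by_group(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Residuals of an intercept-only random-intercept model of the values.

    Falls back to group-mean centering if the REML fit fails (the two agree
    up to shrinkage of the group means).
    """
    import statsmodels.api as sm

    df = pd.DataFrame({"v": values, "g": groups})
    if df["g"].nunique() < 2:
        return values - values.mean()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM(df["v"], np.ones((len(df), 1)), groups=df["g"]).fit(reml=True)
        return np.asarray(md.resid, dtype=float)
    except Exception:
        means = df.groupby("g")["v"].transform("mean")
        return (df["v"] - means).to_numpy()


def robust_refit(fit: FitResult, table, covariates=None, lag: int = 1,
                 strata_col: str = "stratum_id", animal_col: str = "animal_id",
                 time_col: str = "timestamp", response: str = "used",
                 fitter=None) -> RobustFit:
    """Split strata into two lag-spaced interleaved groups, refit, average.

    Strata are ordered in time within each animal and assigned to groups in
    alternating blocks of length ``lag``; the robust covariance is the
    average of the two group-fit covariance matrices (each evaluated at its
    own estimates).  If either group cannot be fitted, the naive covariance
    is returned with ``fallback_naive=True``.
    """
    from .covariates import CovariateTable

    if lag < 1:
        raise ValueError("lag must be >= 1")
    if isinstance(table, CovariateTable):
        covariates = covariates or table.covariate_names
        table = table.frame
    names = [c for c in fit.beta.index if c != "intercept"]
    covariates = covariates or names

    per = (
        table.groupby([animal_col, strata_col], sort=False)
        .agg(t=(time_col, "first"))
        .reset_index()
        .sort_values([animal_col, "t"], kind="stable")
    )
    per["rank"] = per.groupby(animal_col, sort=False).cumcount()
    per["grp"] = (per["rank"] // lag) % 2
    key = per.set_index([animal_col, strata_col])["grp"]
    grp = table.set_index([animal_col, strata_col]).index.map(key).to_numpy()

    if fitter is None:
        if fit.model == "conditional_logistic":
            fitter = lambda df: fit_conditional_logistic(
                df, covariates=covariates, strata_col=strata_col, response=response)
        else:
            fitter = lambda df: fit_mixed_logistic(df, covariates=covariates, response=response)

    vcovs = []
    for g in (0, 1):
        sub = table.loc[grp == g]
        try:
            f = fitter(sub)
            vcovs.append(f.vcov_naive)
        except Exception as e:
            warnings.warn(f"group {g} refit failed ({e}); falling back to naive covariance",
                          stacklevel=2)
            return RobustFit(fit=fit, vcov_robust=fit.vcov_naive, residual_lag=lag,
                             fallback_naive=True)
    vcov_robust = 0.5 * (vcovs[0] + vcovs[1])
    return RobustFit(fit=fit, vcov_robust=vcov_robust, residual_lag=lag)
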