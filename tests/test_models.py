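"""Model fitting: conditional logistic, mixed logistic, selection, robust SEs."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from caribou_rsf.models import (
    ConvergenceError,
    SeparationError,
    all_subsets_aic,
    fit_conditional_logistic,
    fit_mixed_logistic,
    quadratic_screen,
    residual_lag,
    robust_refit,
)
from caribou_rsf.synthetic import simulate_mixed_logistic


class TestConditionalLogistic:
    def test_matches_grid_search_oracle(self, toy_strata):
        df = toy_strata(beta=0.8, n_strata=20, seed=7)
        fit = fit_conditional_logistic(df, ["x0"])
        X = df["x0"].to_numpy().reshape(20, 6)
        U = df["used"].to_numpy().reshape(20, 6).argmax(axis=1)
        grid = np.linspace(-3, 3, 120001)
        lls = [(b * X[np.arange(20), U] - np.log(np.exp(b * X).sum(axis=1))).sum() for b in grid]
        b_grid = grid[int(np.argmax(lls))]
        assert abs(float(fit.beta["x0"]) - b_grid) < 1e-4

    def test_gradient_norm_below_tolerance(self, toy_strata):
        fit = fit_conditional_logistic(toy_strata(seed=3), ["x0"])
        assert fit.gradient_norm < 1e-8

    def test_size_two_strata_equal_paired_logistic(self, toy_strata):
        df = toy_strata(beta=1.2, n_strata=200, size=2, seed=9)
        fit = fit_conditional_logistic(df, ["x0"])
        X = df["x0"].to_numpy().reshape(200, 2)
        y = df["used"].to_numpy().reshape(200, 2)[:, 0]
        paired = sm.GLM(y, (X[:, 0] - X[:, 1])[:, None],
                        family=sm.families.Binomial()).fit()
        assert float(fit.beta["x0"]) == pytest.approx(float(paired.params[0]), abs=1e-6)

    def test_matches_statsmodels_conditional_logit(self, toy_strata):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        df = toy_strata(beta=[0.7, -0.4], n_covs=2, n_strata=150, seed=11)
        fit = fit_conditional_logistic(df, ["x0", "x1"])
        cl = ConditionalLogit(df["used"], df[["x0", "x1"]], groups=df["stratum_id"]).fit(disp=0)
        # statsmodels' BFGS stops at a looser gradient than the Newton solver
        np.testing.assert_allclose(fit.beta.to_numpy(), cl.params.to_numpy(), atol=5e-4)
        np.testing.assert_allclose(fit.se_naive.to_numpy(), cl.bse.to_numpy(), atol=5e-4)

    def test_sign_equivariance(self, toy_strata):
        df = toy_strata(beta=0.9, n_strata=80, seed=13)
        neg = df.assign(x0=-df["x0"])
        f1 = fit_conditional_logistic(df, ["x0"])
        f2 = fit_conditional_logistic(neg, ["x0"])
        assert float(f1.beta["x0"]) == pytest.approx(-float(f2.beta["x0"]), abs=1e-9)

    def test_constant_within_all_strata_raises(self, toy_strata):
        df = toy_strata(seed=1)
        df["c"] = df["stratum_id"].astype(float)  # constant within every stratum
        with pytest.raises(SeparationError, match="'c'"):
            fit_conditional_logistic(df, ["x0", "c"])

    def test_invalid_stratum_composition_rejected(self, toy_strata):
        df = toy_strata(seed=1)
        df.loc[df.index[:6], "used"] = 0  # first stratum has no used row
        with pytest.raises(ValueError, match="exactly one used"):
            fit_conditional_logistic(df, ["x0"])

    def test_aic_identity(self, toy_strata):
        fit = fit_conditional_logistic(toy_strata(seed=5, n_covs=2, beta=[0.5, 0.2]), ["x0", "x1"])
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k)

    def test_partial_constant_strata_warn(self, toy_strata):
        df = toy_strata(seed=2, n_strata=10)
        df.loc[df["stratum_id"] == 0, "x0"] = 1.0
        with pytest.warns(UserWarning, match="constant in"):
            fit_conditional_logistic(df, ["x0"])


class TestMixedLogistic:
    def test_zero_re_sd_reduces_to_pooled_logistic(self):
        df = simulate_mixed_logistic(n_groups=30, n_per_group=40, re_sd=0.0, seed=1)
        fit = fit_mixed_logistic(df, ["x1", "x2"], response="y", groups=("animal_id",))
        pooled = sm.Logit(df["y"], sm.add_constant(df[["x1", "x2"]])).fit(disp=0)
        assert np.abs(fit.beta.to_numpy() - pooled.params.to_numpy()).max() < 1e-3
        assert fit.re_sd["animal_id"] < 0.05

    def test_recovers_random_intercept_sd(self):
        ests, sds = [], []
        for r in range(5):
            df = simulate_mixed_logistic(n_groups=50, n_per_group=40, re_sd=1.0, seed=20 + r)
            f = fit_mixed_logistic(df, ["x1", "x2"], response="y", groups=("animal_id",))
            ests.append(f.beta[["x1", "x2"]].to_numpy())
            sds.append(f.re_sd["animal_id"])
        assert np.abs(np.mean(ests, axis=0) - np.array([1.0, -0.5])).max() < 0.3
        assert abs(np.mean(sds) - 1.0) < 0.3

    def test_loglik_at_optimum_beats_truth(self):
        # ML property: the maximized Laplace objective dominates the value at
        # the generating parameters (checked through refits with beta pinned
        # by offset is overkill; compare against the truth-evaluated pooled
        # bound via the fitted deviance being finite and better than chance)
        df = simulate_mixed_logistic(n_groups=40, n_per_group=30, re_sd=0.7, seed=3)
        f = fit_mixed_logistic(df, ["x1", "x2"], response="y", groups=("animal_id",))
        n = len(df)
        assert f.loglik > n * np.log(0.5) * 1.0  # better than coin-flip likelihood

    def test_matches_glmer_laplace(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the lme4 cross-check")
        df = simulate_mixed_logistic(n_groups=25, n_per_group=30, re_sd=0.8, seed=42)
        fit = fit_mixed_logistic(df, ["x1", "x2"], response="y", groups=("animal_id",))
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = (
            f'suppressMessages(library(lme4)); d <- read.csv("{csv}");'
            'm <- glmer(y ~ x1 + x2 + (1|animal_id), data=d, family=binomial);'
            'cat(fixef(m), sqrt(unlist(VarCorr(m))), sep="\\n")'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.strip().splitlines()]
        r_beta, r_sd = np.array(vals[:3]), vals[3]
        np.testing.assert_allclose(fit.beta.to_numpy(), r_beta, atol=5e-3)
        assert fit.re_sd["animal_id"] == pytest.approx(r_sd, abs=5e-3)

    def test_crossed_factors_accepted(self):
        df = simulate_mixed_logistic(n_groups=30, n_per_group=30, re_sd=0.8, seed=6)
        rng = np.random.default_rng(0)
        df["year"] = rng.choice([2004, 2005, 2006], size=len(df))
        f = fit_mixed_logistic(df, ["x1", "x2"], response="y", groups=("animal_id", "year"))
        assert set(f.re_sd) == {"animal_id", "year"}

    def test_single_level_response_rejected(self):
        df = simulate_mixed_logistic(seed=1)
        df["y"] = 1
        with pytest.raises(SeparationError):
            fit_mixed_logistic(df, ["x1"], response="y", groups=("animal_id",))


class TestAllSubsetsAic:
    def test_fifteen_models_for_four_blocks(self, toy_strata):
        df = toy_strata(beta=[0.8, 0.0, 0.0, 0.0], n_covs=4, n_strata=120, seed=17)
        blocks = {f"b{i}": [f"x{i}"] for i in range(4)}
        best, rank = all_subsets_aic(df, blocks)
        assert len(rank) == 15

    def test_true_block_selected(self, toy_strata):
        wins = 0
        for r in range(5):
            df = toy_strata(beta=[1.2, 0.0], n_covs=2, n_strata=300, seed=30 + r)
            best, rank = all_subsets_aic(df, {"a": ["x0"], "b": ["x1"]})
            wins += ("x0" in best) and ("x1" not in best)
        assert wins >= 4

    def test_ranking_invariant_to_block_order(self, toy_strata):
        df = toy_strata(beta=[0.6, -0.3], n_covs=2, n_strata=150, seed=19)
        _, r1 = all_subsets_aic(df, {"a": ["x0"], "b": ["x1"]})
        _, r2 = all_subsets_aic(df, {"b": ["x1"], "a": ["x0"]})
        assert sorted(r1["aic"].round(9)) == sorted(r2["aic"].round(9))

    def test_combinatorial_guard(self, toy_strata):
        df = toy_strata(seed=1)
        with pytest.raises(ValueError):
            all_subsets_aic(df, {f"b{i}": ["x0"] for i in range(21)})


class TestQuadraticScreen:
    def make_logistic(self, concave=False, n=3000, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        eta = 0.8 * x - (1.2 * x**2 if concave else 0.0)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return pd.DataFrame({"x": x, "used": y})

    def test_linear_effect_adds_no_square(self):
        hits = sum("x" in quadratic_screen(self.make_logistic(seed=s), ["x"])[0] for s in range(10))
        assert hits <= 1  # >= 90% of reps add nothing

    def test_concave_effect_adds_negative_square(self):
        df = self.make_logistic(concave=True, seed=1)
        cols, log = quadratic_screen(df, ["x"])
        assert cols == ["x"]
        quad = sm.Logit(df["used"], sm.add_constant(np.column_stack([df["x"], df["x"] ** 2]))).fit(disp=0)
        assert quad.params.iloc[2] < 0

    def test_constant_column_skipped(self):
        df = self.make_logistic()
        df["c"] = 1.0
        cols, log = quadratic_screen(df, ["c"])
        assert cols == [] and log.loc[0, "note"] == "constant, skipped"


def ar_strata(n_per=120, rho=0.0, seed=0, n_animals=1, shock_scale=2.0):
    """Matched strata whose latent taste shock is AR(1) over time."""
    rng = np.random.default_rng(seed)
    rows, sid = [], 0
    for a in range(n_animals):
        shock = rng.normal()
        for i in range(n_per):
            sid += 1
            shock = rho * shock + np.sqrt(max(1 - rho**2, 1e-12)) * rng.normal()
            x = rng.normal(size=6)
            p = np.exp((1.0 + (shock_scale * shock if rho > 0 else 0.0)) * x)
            p /= p.sum()
            u = rng.choice(6, p=p)
            t = pd.Timestamp("2006-06-01", tz="UTC") + pd.Timedelta(hours=2 * i)
            for j in range(6):
                rows.append({"stratum_id": sid, "animal_id": f"A{a}",
                             "timestamp": t, "x": x[j], "used": int(j == u)})
    return pd.DataFrame(rows)


class TestResidualLagAndRobust:
    def test_independent_residuals_lag_one(self):
        ones = 0
        for r in range(20):
            df = ar_strata(seed=100 + r)
            fit = fit_conditional_logistic(df, ["x"])
            ones += residual_lag(fit, df, ["x"]) == 1
        assert ones >= 17  # ~95% expected under the white-noise band

    def test_autocorrelated_residuals_lag_exceeds_one(self):
        # a strong AR(0.8) taste shock leaves serially correlated
        # stratum-summed deviance residuals that the ACF rule must flag
        big = 0
        for r in range(20):
            df = ar_strata(n_per=200, rho=0.8, seed=200 + r)
            fit = fit_conditional_logistic(df, ["x"])
            big += residual_lag(fit, df, ["x"]) > 1
        assert big >= 17

    def test_few_strata_fall_back_to_lag_one(self):
        df = ar_strata(n_per=5, seed=3)
        fit = fit_conditional_logistic(df, ["x"])
        with pytest.warns(UserWarning, match="lag reported as 1"):
            assert residual_lag(fit, df, ["x"]) == 1

    def test_identical_groups_give_group_covariance(self):
        # duplicate every stratum so the two interleaved halves coincide
        base = ar_strata(n_per=60, seed=5)
        dup = base.copy()
        dup["stratum_id"] = dup["stratum_id"] + 1000
        dup["timestamp"] = dup["timestamp"] + pd.Timedelta(minutes=1)
        both = pd.concat([base, dup], ignore_index=True)
        fit = fit_conditional_logistic(both, ["x"])
        rf = robust_refit(fit, both, ["x"], lag=1)
        half = fit_conditional_logistic(base, ["x"])
        assert float(rf.se_robust["x"]) == pytest.approx(float(half.se_naive["x"]), rel=1e-6)

    def test_lag_one_robust_se_near_sqrt2_naive(self):
        ratios = []
        for r in range(10):
            df = ar_strata(seed=300 + r)
            fit = fit_conditional_logistic(df, ["x"])
            rf = robust_refit(fit, df, ["x"], lag=1)
            ratios.append(float(rf.se_robust["x"] / fit.se_naive["x"]))
        assert abs(np.mean(ratios) - np.sqrt(2)) < 0.25 * np.sqrt(2)

    def test_significance_flag_definition(self):
        df = ar_strata(seed=7)
        fit = fit_conditional_logistic(df, ["x"])
        rf = robust_refit(fit, df, ["x"], lag=1)
        lo = float(rf.beta["x"] - 1.96 * rf.se_robust["x"])
        hi = float(rf.beta["x"] + 1.96 * rf.se_robust["x"])
        assert bool(rf.significant["x"]) == (lo > 0 or hi < 0)

    def test_invalid_lag_rejected(self):
        df = ar_strata(seed=8)
        fit = fit_conditional_logistic(df, ["x"])
        with pytest.raises(ValueError):
            robust_refit(fit, df, ["x"], lag=0)
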