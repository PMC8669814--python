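"""MANCOVA, compositional regression, influence screening, robust refits."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from wakecomp.cohort import (
    OutcomeModel,
    calibrate_ilr_dispersion,
    default_config,
    generate_cohort,
    sample_compositions,
    sample_covariates,
    simulate_outcomes,
)
from wakecomp.models import (
    CompositionalRegression,
    ConvergenceError,
    EstimationError,
    MANCOVA_COVARIATES,
    adjusted_r2,
    code_covariates,
    fit_compositional_mancova,
    fit_compositional_regression,
    fit_mm,
    influence_screen,
)
from wakecomp.preprocess import build_analysis_table
from wakecomp.simplex import close, ilr_forward, make_default_sbp


@pytest.fixture(scope="module")
def complete_table():
    tab, _ = generate_cohort(default_config(n=200, seed=3, missing_rates={}))
    return build_analysis_table(tab)


class TestMancova:
    def test_published_df_shape(self):
        tab, _ = generate_cohort(default_config(n=589, seed=1, missing_rates={}))
        ana = build_analysis_table(tab)
        m = fit_compositional_mancova(
            ana[["ilr1", "ilr2"]].to_numpy(), ana["group"].to_numpy(), ana
        )
        # intercept + group + age + sex + 3 income dummies + ethnicity = 8
        assert m.design_rank == 8
        assert (m.df1, m.df2) == (2, 580)
        assert 0 < m.wilks_lambda <= 1

    def test_identical_groups_lambda_one(self):
        # both groups carry the exact same response rows -> no group effect
        rng = np.random.default_rng(0)
        half = rng.normal(size=(30, 2))
        ilr = np.vstack([half, half])
        group = np.array(["TD"] * 30 + ["rDCD"] * 30)
        m = fit_compositional_mancova(ilr, group)
        assert m.wilks_lambda == pytest.approx(1.0)
        assert m.f_stat == pytest.approx(0.0, abs=1e-10)

    def test_matches_statsmodels_manova(self, complete_table):
        ana = complete_table
        mine = fit_compositional_mancova(
            ana[["ilr1", "ilr2"]].to_numpy(), ana["group"].to_numpy(), ana
        )
        from statsmodels.multivariate.manova import MANOVA

        C = code_covariates(ana, MANCOVA_COVARIATES)
        C.columns = [f"c{i}" for i in range(C.shape[1])]
        C["grp"] = (ana["group"] == "rDCD").astype(float)
        df = pd.concat([ana[["ilr1", "ilr2"]], C], axis=1)
        mv = MANOVA.from_formula(
            "ilr1 + ilr2 ~ " + " + ".join(C.columns), data=df
        )
        stat = mv.mv_test().results["grp"]["stat"].loc["Wilks' lambda"]
        assert mine.wilks_lambda == pytest.approx(stat["Value"], abs=1e-10)
        assert mine.f_stat == pytest.approx(stat["F Value"], rel=1e-9)
        assert mine.df2 == int(stat["Den DF"])

    def test_rank_deficient_design_rejected(self, complete_table):
        ana = complete_table.copy()
        ana["group"] = ana["sex"].map({"male": "rDCD", "female": "TD"})
        with pytest.raises(EstimationError, match="collinear|rank"):
            fit_compositional_mancova(
                ana[["ilr1", "ilr2"]].to_numpy(), ana["group"].to_numpy(),
                ana,
            )

    def test_nonbinary_group_rejected(self):
        with pytest.raises(EstimationError):
            fit_compositional_mancova(
                np.zeros((9, 2)), np.array(list("abcabcabc"))
            )


class TestCompositionalRegression:
    def test_pivot_rotation_invariance(self, complete_table):
        fits = {
            p: CompositionalRegression(pivot=p, robust=False).fit(
                complete_table, "externalizing_t"
            )
            for p in ("SB", "LPA", "MVPA")
        }
        ref = fits["SB"].ols_
        for p in ("LPA", "MVPA"):
            r = fits[p].ols_
            assert np.max(np.abs(r.fittedvalues - ref.fittedvalues)) < 1e-10
            assert r.r2 == pytest.approx(ref.r2, abs=1e-12)
            assert r.adj_r2 == pytest.approx(ref.adj_r2, abs=1e-12)
        # first-pivot coefficients across the three rotations sum to zero
        total = sum(f.ols_.params["ilr1"] for f in fits.values())
        assert total == pytest.approx(0.0, abs=1e-10)

    def test_constant_outcome_zero_slopes(self, complete_table):
        y = pd.Series(np.full(len(complete_table), 7.0), name="const_y")
        est = CompositionalRegression(robust=False).fit(complete_table, y)
        slopes = est.ols_.params.drop("const")
        assert np.allclose(slopes, 0, atol=1e-10)
        assert est.ols_.r2 == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_recovery_exact(self, complete_table):
        tab = complete_table
        y = 3.0 - 2.0 * tab["ilr1"] + 0.5 * tab["ilr2"]
        est = CompositionalRegression(robust=False).fit(tab, y)
        assert est.ols_.params["ilr1"] == pytest.approx(-2.0, abs=1e-9)
        assert est.ols_.params["ilr2"] == pytest.approx(0.5, abs=1e-9)

    def test_planted_effect_recovery(self):
        """Mean ilr1 estimate over replicates near the planted -5.24."""
        disp = calibrate_ilr_dispersion()
        model = {"o": OutcomeModel(mean=45.55, ilr1=-5.24, ilr2=1.77824,
                                   group_rdcd=4.03, noise_sd=9.0)}
        est_vals = []
        rng = np.random.default_rng(17)
        for _ in range(40):
            n = 589
            s = int(rng.integers(1 << 31))
            cov = sample_covariates(n, seed=s)
            mins = sample_compositions(n, close((62.33, 27.75, 9.92), 1),
                                       disp, seed=s + 1)
            z = ilr_forward(mins / mins.sum(1, keepdims=True),
                            make_default_sbp())
            y = simulate_outcomes(z, cov, model, seed=s + 2)["o"]
            tab = cov.copy()
            tab[["sb_min", "lpa_min", "mvpa_min"]] = mins
            fit = fit_compositional_regression(y, tab, "SB", robust=False)
            est_vals.append(fit.ols_.params["ilr1"])
        se_mc = np.std(est_vals, ddof=1) / np.sqrt(len(est_vals))
        assert abs(np.mean(est_vals) - (-5.24)) < max(3 * se_mc, 0.5)

    def test_prediction_matches_fitted(self, complete_table):
        est = CompositionalRegression(robust=False).fit(
            complete_table, "internalizing_t"
        )
        pred = est.predict(complete_table)
        assert np.allclose(pred, est.ols_.fittedvalues, atol=1e-10)

    def test_fitted_plus_residual_reproduces_outcome(self, complete_table):
        est = CompositionalRegression(robust=False).fit(
            complete_table, "internalizing_t"
        )
        y = complete_table["internalizing_t"].to_numpy()
        assert np.allclose(est.ols_.fittedvalues + est.ols_.resid, y)


class TestInfluence:
    def _fit(self, n=40, seed=0, outlier=False):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({"const": 1.0, "x1": rng.normal(size=n),
                          "x2": rng.normal(size=n)})
        y = 1 + X["x1"].to_numpy() - 2 * X["x2"].to_numpy() + rng.normal(size=n)
        if outlier:
            y[0] += 15.0
        ols = sm.OLS(y, X).fit()
        from wakecomp.models import _result_from_arrays

        Q, _ = np.linalg.qr(np.asarray(X, float))
        basis = make_default_sbp()
        return _result_from_arrays(
            ols.params.to_numpy(), ols.cov_params().to_numpy(), ols.resid,
            ols.fittedvalues, np.sum(Q * Q, axis=1),
            float(np.sqrt(ols.mse_resid)), y, "ols", "SB", basis, X.columns,
        ), X, y

    def test_threshold_is_four_over_n(self, complete_table):
        est = CompositionalRegression(robust=False).fit(
            complete_table, "externalizing_t"
        )
        assert est.influence_.threshold == pytest.approx(4 / len(complete_table))
        tab589, _ = generate_cohort(default_config(n=589, seed=2,
                                                   missing_rates={}))
        e = CompositionalRegression(robust=False).fit(
            build_analysis_table(tab589), "externalizing_t"
        )
        assert e.influence_.threshold == pytest.approx(0.006791, abs=5e-7)

    def test_leave_one_out_oracle(self):
        """Closed-form Cook's distance equals the brute-force refit version."""
        fit, X, y = self._fit(n=40, seed=1)
        rep = influence_screen(fit)
        Xa = np.asarray(X, float)
        p = Xa.shape[1]
        s2 = fit.resid_sd**2
        beta_full = fit.params.to_numpy()
        XtX = Xa.T @ Xa
        d_loo = np.empty(len(y))
        for i in range(len(y)):
            keep = np.ones(len(y), bool)
            keep[i] = False
            beta_i, *_ = np.linalg.lstsq(Xa[keep], y[keep], rcond=None)
            diff = beta_full - beta_i
            d_loo[i] = diff @ XtX @ diff / (p * s2)
        assert np.max(np.abs(rep.cooks_d - d_loo)) < 1e-8

    def test_matches_statsmodels_cooks_distance(self):
        fit, X, y = self._fit(n=60, seed=2, outlier=True)
        rep = influence_screen(fit)
        sm_d = sm.OLS(y, X).fit().get_influence().cooks_distance[0]
        assert np.allclose(rep.cooks_d, sm_d, atol=1e-10)
        assert 0 in rep.flagged

    def test_duplicating_rows_shrinks_and_preserves_order(self):
        fit, X, y = self._fit(n=30, seed=3)
        rep = influence_screen(fit)
        X2 = pd.concat([X, X], ignore_index=True)
        y2 = np.concatenate([y, y])
        ols2 = sm.OLS(y2, X2).fit()
        from wakecomp.models import _result_from_arrays

        Q, _ = np.linalg.qr(np.asarray(X2, float))
        fit2 = _result_from_arrays(
            ols2.params.to_numpy(), ols2.cov_params().to_numpy(), ols2.resid,
            ols2.fittedvalues, np.sum(Q * Q, axis=1),
            float(np.sqrt(ols2.mse_resid)), y2, "ols", "SB", fit.basis,
            X2.columns,
        )
        rep2 = influence_screen(fit2)
        ratio = rep2.cooks_d[:30] / rep.cooks_d
        assert np.all(ratio < 1.0)
        # analytic change: h' = h/2 exactly, residuals unchanged, so
        # D'/D = (1/2) ((1-h)/(1-h/2))^2 (s/s')^2 -> ~1/2 at small leverage
        h = fit.leverage
        s_ratio = (fit.resid_sd / fit2.resid_sd) ** 2
        expected = 0.5 * ((1 - h) / (1 - h / 2)) ** 2 * s_ratio
        assert np.allclose(ratio, expected, atol=1e-10)
        assert np.allclose(fit2.leverage[:30], h / 2, atol=1e-12)


class TestRobustRegression:
    def test_clean_data_close_to_ols(self):
        rng = np.random.default_rng(5)
        diffs = []
        for rep in range(5):
            n = 500
            X = pd.DataFrame({"const": 1.0, "x1": rng.normal(size=n),
                              "x2": rng.normal(size=n)})
            y = 1 + 2 * X["x1"].to_numpy() - X["x2"].to_numpy() + rng.normal(size=n)
            ols = sm.OLS(y, X).fit()
            beta, *_ = fit_mm(y, X, seed=rep)
            diffs.append(np.abs(beta - ols.params.to_numpy())
                         / ols.bse.to_numpy())
        # 95%-efficiency MM vs OLS: difference sd ~ sqrt(1/0.95 - 1) ~ 0.23 SE
        assert np.mean(diffs) < 0.3
        assert np.max(diffs) < 0.8

    def test_gross_outlier_downweighted(self):
        rng = np.random.default_rng(6)
        n = 100
        X = pd.DataFrame({"const": 1.0, "x1": rng.normal(size=n)})
        y = 1 + 2 * X["x1"].to_numpy() + rng.normal(size=n) * 0.5
        y_cont = y.copy()
        y_cont[0] += 30.0
        beta_clean, *_ = fit_mm(y, X, seed=0)
        beta_cont, scale, w, _ = fit_mm(y_cont, X, seed=0)
        ols_cont = sm.OLS(y_cont, X).fit().params.to_numpy()
        assert w[0] < 0.05
        assert np.max(np.abs(beta_cont - beta_clean)) < \
            np.max(np.abs(ols_cont - beta_clean))

    def test_exact_linear_data(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"const": 1.0, "x1": rng.normal(size=50)})
        y = 3.0 - 1.5 * X["x1"].to_numpy()
        beta, scale, w, cov = fit_mm(y, X, seed=0)
        assert np.allclose(beta, (3.0, -1.5), atol=1e-10)
        assert scale == 0.0
        assert np.allclose(X.to_numpy() @ beta, y)

    def test_matches_mass_rlm_oracle(self):
        """Frozen oracle: R MASS::rlm(method='MM') on the same fixture."""
        rng = np.random.default_rng(42)
        n = 60
        x1 = rng.normal(0, 1, n)
        x2 = rng.normal(0, 1, n)
        y = 2.0 + 1.5 * x1 - 0.8 * x2 + rng.normal(0, 0.5, n)
        y[rng.choice(n, 6, replace=False)] += 12.0
        X = pd.DataFrame({"const": 1.0, "x1": x1, "x2": x2})
        beta, *_ = fit_mm(y, X, seed=0)
        mass = (1.93249527, 1.54615718, -0.75553883)
        assert np.max(np.abs(beta - mass)) < 0.02

    def test_nonconvergence_raises_with_iterate(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame({"const": 1.0, "x1": rng.normal(size=80)})
        y = rng.normal(size=80) * 5
        with pytest.raises(ConvergenceError) as exc:
            fit_mm(y, X, seed=0, max_iter=1, tol=1e-14)
        assert exc.value.last_coef is not None

    def test_auto_trigger_on_contaminated_cohort(self, complete_table):
        tab = complete_table.copy()
        tab.loc[:4, "externalizing_t"] += 60.0
        est = CompositionalRegression(robust="auto").fit(tab, "externalizing_t")
        assert est.result_.method == "mm"
        assert est.robust_.weights[:5].max() < 0.05


class TestAdjustedR2:
    def test_formula_example(self):
        assert adjusted_r2(0.10, 589, 9) == pytest.approx(
            1 - 0.9 * 588 / 579, abs=1e-12
        )

    def test_bounds(self):
        assert adjusted_r2(0.0, 100, 5) <= 0.0
        assert adjusted_r2(1.0, 100, 5) == pytest.approx(1.0)

    def test_undefined_rejected(self):
        with pytest.raises(EstimationError):
            adjusted_r2(0.5, 10, 9)
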