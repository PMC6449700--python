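import json
import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from driverattn.lme import (
    ModelFit,
    ModelSpec,
    NotNestedError,
    fit_lme,
    likelihood_ratio_test,
    lrt_pvalue,
    model_search,
    nakagawa_r2,
)
from driverattn.simulate import GeneratorConfig, generate_trial_table

INTER_SPEC = ModelSpec(
    ("alpha_db", "rmssd", "period"), order=1, extra_interactions=("alpha_db:rmssd",)
)
ADD_SPEC = ModelSpec(("alpha_db", "rmssd", "period"), order=1)


def make_table(seed=3, n_participants=8, **overrides) -> pd.DataFrame:
    cfg = GeneratorConfig(n_participants=n_participants, seed=seed, **overrides)
    table, _ = generate_trial_table(cfg)
    return table


class TestModelSpec:
    def test_order3_expansion_count(self):
        spec = ModelSpec(("a", "b", "c", "d"), order=3)
        # 4 mains + 6 pairs + 4 triples
        assert len(spec.term_names()) == 14

    def test_five_term_order3_count(self):
        spec = ModelSpec(("a", "b", "c", "d", "e"), order=3)
        assert len(spec.term_names()) == 25

    def test_nesting(self):
        assert ADD_SPEC.nests_within(INTER_SPEC)
        assert not INTER_SPEC.nests_within(ADD_SPEC)


class TestFitLme:
    def test_reduces_to_ols_without_random_variance(self):
        # residuals demeaned within participant and trial leave no
        # between-group variance: the components hit the zero boundary and
        # the GLS fit must coincide with OLS
        table = make_table(sd_participant=1e-9, sd_trial=1e-9, miss_rate=0.0)
        resid = table["rt"] - table["linpred"]
        resid = resid - resid.groupby(table["participant"]).transform("mean")
        resid = resid - resid.groupby(table["trial"]).transform("mean")
        table = table.assign(rt=table["linpred"] + resid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lme(table, INTER_SPEC)
        # components land at the boundary (negligible against the ~22,500
        # ms^2 residual), so GLS must coincide with OLS
        assert fit.var_participant < 0.01 and fit.var_trial < 0.01
        d = table.copy()
        for v in ("alpha_db", "rmssd"):
            d[v] = (d[v] - d[v].mean()) / d[v].std(ddof=1)
        d["period"] = d["period"] - d["period"].mean()
        X = sm.add_constant(
            pd.DataFrame(
                dict(alpha_db=d.alpha_db, rmssd=d.rmssd, period=d.period,
                     inter=d.alpha_db * d.rmssd)
            )
        )
        ols = sm.OLS(d.rt, X).fit()
        assert fit.coefficients["alpha_db"] == pytest.approx(ols.params["alpha_db"], abs=1e-4)
        assert fit.coefficients["alpha_db:rmssd"] == pytest.approx(ols.params["inter"], abs=1e-4)

    def test_aic_bic_definitions(self):
        fit = fit_lme(make_table(), ADD_SPEC)
        k = fit.k_params
        assert fit.aic == pytest.approx(-2 * fit.llf + 2 * k)
        assert fit.bic == pytest.approx(-2 * fit.llf + k * np.log(fit.n_obs))
        assert k == fit.k_fixed + 3  # two variance components + residual

    def test_variance_recovery_at_scale(self):
        # participant sd 100 ms, residual sd 150 ms at the default study size
        table = make_table(seed=11, n_participants=25)
        fit = fit_lme(table, INTER_SPEC)
        assert np.sqrt(fit.var_participant) == pytest.approx(100.0, rel=0.45)
        assert np.sqrt(fit.var_residual) == pytest.approx(150.0, rel=0.1)

    def test_listwise_missing_rows_dropped(self):
        table = make_table(miss_rate=0.2)
        fit = fit_lme(table, ADD_SPEC)
        assert fit.n_obs == int(table["rt"].notna().sum())

    def test_needs_two_participants(self):
        table = make_table()
        solo = table[table.participant == "P01"]
        with pytest.raises(ValueError, match="participants"):
            fit_lme(solo, ADD_SPEC)


class TestLikelihoodRatio:
    def test_self_comparison_is_null_result(self):
        table = make_table()
        fit = fit_lme(table, ADD_SPEC)
        res = likelihood_ratio_test(fit, fit)
        assert res.chi_square == 0.0 and res.p == 1.0

    def test_paper_scale_pvalue(self):
        assert lrt_pvalue(5.251, 1) == pytest.approx(0.0219, abs=5e-5)

    def test_non_nested_refused(self):
        table = make_table()
        a = fit_lme(table, ModelSpec(("alpha_db", "period"), order=2))
        b = fit_lme(table, ModelSpec(("rmssd", "period"), order=1))
        with pytest.raises(NotNestedError):
            likelihood_ratio_test(a, b)

    def test_different_rows_refused(self):
        t1 = make_table(seed=3)
        t2 = make_table(seed=4)
        full = fit_lme(t1, INTER_SPEC)
        null = fit_lme(t2, ADD_SPEC)
        with pytest.raises(NotNestedError, match="rows"):
            likelihood_ratio_test(full, null)

    def test_affine_rescaling_invariance(self):
        table = make_table()
        full = fit_lme(table, INTER_SPEC)
        null = fit_lme(table, ADD_SPEC)
        base = likelihood_ratio_test(full, null).chi_square

        scaled = table.copy()
        scaled["alpha_db"] = scaled["alpha_db"] * 1000.0 + 5.0
        full_s = fit_lme(scaled, INTER_SPEC)
        null_s = fit_lme(scaled, ADD_SPEC)
        assert likelihood_ratio_test(full_s, null_s).chi_square == pytest.approx(
            base, abs=1e-4
        )


class TestAgainstLme4:
    def test_ml_fit_matches_lme4(self, tmp_path):
        """Independent oracle: identical ML log-likelihood and fixed effects
        from lme4 on the same prepared data."""
        table = make_table(seed=21, n_participants=6)
        fit = fit_lme(table, INTER_SPEC)

        from driverattn.lme import prepare_model_frame

        df = prepare_model_frame(table, INTER_SPEC)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        out = tmp_path / "out.json"
        rscript = f"""
        suppressMessages(library(lme4)); suppressMessages(library(jsonlite))
        d <- read.csv("{csv}")
        m <- lmer(rt ~ alpha_db + rmssd + period + alpha_db:rmssd +
                  (1|participant) + (1|trial), d, REML=FALSE)
        res <- list(llf=logLik(m)[1], fixef=as.list(fixef(m)),
                    vc=as.data.frame(VarCorr(m))$vcov)
        write(toJSON(res, digits=12, auto_unbox=TRUE), "{out}")
        """
        subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True)
        ref = json.loads(out.read_text())
        assert fit.llf == pytest.approx(ref["llf"], abs=1e-3)
        assert fit.coefficients["alpha_db:rmssd"] == pytest.approx(
            ref["fixef"]["alpha_db:rmssd"], abs=1e-3
        )
        assert fit.coefficients["Intercept"] == pytest.approx(
            ref["fixef"]["(Intercept)"], abs=1e-3
        )


class TestNakagawaR2:
    def test_formula_arithmetic(self):
        fit = ModelFit(
            spec=ADD_SPEC, coefficients={"Intercept": 0.0}, std_errors={},
            var_participant=3.0, var_trial=1.0, var_residual=4.0,
            llf=0.0, aic=0.0, bic=0.0, n_obs=10, k_params=4,
            converged=True, var_fixed=2.0,
        )
        r2 = nakagawa_r2(fit)
        assert r2.marginal == pytest.approx(0.2)
        assert r2.conditional == pytest.approx(0.6)

    def test_null_model_has_zero_marginal(self):
        table = make_table()
        # beta all zero except intercept -> fixed predictor variance ~ 0
        cfg = GeneratorConfig(n_participants=8, seed=9)
        cfg.beta_vector = {"intercept": 900.0}
        t, _ = generate_trial_table(cfg)
        fit = fit_lme(t, ADD_SPEC)
        r2 = nakagawa_r2(fit)
        assert r2.marginal < 0.02
        assert 0.0 <= r2.marginal <= r2.conditional <= 1.0

    def test_known_variance_partition(self):
        # fixed ~10%, random ~40%, residual ~50% of total variance; the
        # decomposition is recovered in the mean over replicate studies
        total = 200.0 ** 2
        marg, cond = [], []
        for rep in range(20):
            cfg = GeneratorConfig(n_participants=25, seed=130 + rep, miss_rate=0.0)
            cfg.beta_vector = {"intercept": 900.0, "alpha": np.sqrt(0.1 * total)}
            cfg.sd_participant = np.sqrt(0.3 * total)
            cfg.sd_trial = np.sqrt(0.1 * total)
            cfg.sd_resid = np.sqrt(0.5 * total)
            t, _ = generate_trial_table(cfg)
            r2 = nakagawa_r2(fit_lme(t, ModelSpec(("alpha_db",), order=1)))
            marg.append(r2.marginal)
            cond.append(r2.conditional)
        assert np.mean(marg) == pytest.approx(0.10, abs=0.03)
        assert np.mean(cond) == pytest.approx(0.50, abs=0.05)


@pytest.fixture(scope="module")
def report():
    """Model sequence on one study, forcing the lnX-dropped branch that the
    reduced-model df contract describes."""
    table = make_table(seed=17, n_participants=10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model_search(table, drop_ln_x=True)


class TestModelSearch:
    def test_structural_contract(self, report):
        models = report["models"]
        for m in ("alpha_db", "mean_rr", "rmssd", "ln_x"):
            assert f"{m}_x_period" in models
        for key in ("full_order3", "reduced_order3", "reduced_additive"):
            assert key in models
        assert set(report["lrt"]) >= {
            "alpha_db_x_period_vs_additive",
            "ln_x_contribution",
            "reduced_order3_vs_additive",
            "beyond_alpha_x_rmssd",
            "beyond_alpha_x_period",
            "beyond_rmssd_x_period",
        }

    def test_lrt_degrees_of_freedom(self, report):
        assert report["lrt"]["alpha_db_x_period_vs_additive"]["df"] == 1
        # five-term vs four-term order-3 expansions differ by 11 lnX terms
        assert report["lrt"]["ln_x_contribution"]["df"] == 11
        assert report["lrt"]["reduced_order3_vs_additive"]["df"] == 10
        for pair in ("alpha_x_rmssd", "alpha_x_period", "rmssd_x_period"):
            assert report["lrt"][f"beyond_{pair}"]["df"] == 9

    def test_r2_bounds(self, report):
        r2 = report["r2"]
        assert 0.0 <= r2["marginal"] <= r2["conditional"] <= 1.0

    def test_deterministic(self):
        table = make_table(seed=19, n_participants=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = json.dumps(model_search(table), sort_keys=True)
            b = json.dumps(model_search(table), sort_keys=True)
        assert a == b
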