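"""Interactive linear mixed-effects RT models with crossed random intercepts.

The response is reaction time (ms) to unreliable-automation arrows; fixed
effects are pre-stimulus physiological features (Pz alpha dB, meanRR, RMSSD,
lnX) and the time period, expanded to interactions up to order three.
Random intercepts for participant and for trial index (1–10 within a
period) are crossed, fitted here as variance components within a single
group. Continuous physiological predictors are z-scored before the
interaction expansion (interaction coefficients are otherwise
scale-dependent); the time period enters as a centered numeric covariate.

Nested models are compared by likelihood-ratio tests on ML fits (REML
likelihoods are not comparable across fixed-effect structures), and
variance explained is summarized with the Nakagawa marginal/conditional R²
decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2
import statsmodels.formula.api as smf

CONTINUOUS_PREDICTORS = ("alpha_db", "mean_rr", "rmssd", "ln_x", "ln_y")
FULL_TERMS = ("alpha_db", "mean_rr", "rmssd", "ln_x", "period")
REDUCED_TERMS = ("alpha_db", "mean_rr", "rmssd", "period")


@dataclass
class ModelSpec:
    """Fixed-effect structure of one RT model.

    ``main_terms`` are feature-table columns; all interactions among them up
    to ``order`` are included, plus any ``extra_interactions`` (":"-joined
    main terms) — the latter allow 'additive plus one tested interaction'
    nulls.
    """

    main_terms: Tuple[str, ...]
    order: int = 1
    extra_interactions: Tuple[str, ...] = ()
    response: str = "rt"
    estimation: str = "ML"  # LRTs of fixed effects require ML
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.order not in (1, 2, 3):
            raise ValueError("interaction order must be 1, 2 or 3")
        if self.estimation not in ("ML", "REML"):
            raise ValueError("estimation must be 'ML' or 'REML'")
        for extra in self.extra_interactions:
            for part in extra.split(":"):
                if part not in self.main_terms:
                    raise ValueError(f"{extra!r} uses a non-main term")

    def term_names(self) -> List[str]:
        """Expanded fixed-effect terms (without the intercept)."""
        names: List[str] = []
        for k in range(1, self.order + 1):
            for combo in combinations(self.main_terms, k):
                names.append(":".join(combo))
        for extra in self.extra_interactions:
            canon = ":".join(sorted(extra.split(":"), key=self.main_terms.index))
            if canon not in names:
                names.append(canon)
        return names

    def formula(self) -> str:
        rhs = " + ".join(self.term_names())
        return f"{self.response} ~ {rhs}" if rhs else f"{self.response} ~ 1"

    def nests_within(self, other: "ModelSpec") -> bool:
        return set(self.term_names()) <= set(other.term_names())


@dataclass
class ModelFit:
    """Fitted mixed model: coefficients, variance components, fit indices."""

    spec: ModelSpec
    coefficients: Dict[str, float]
    std_errors: Dict[str, float]
    var_participant: float
    var_trial: float
    var_residual: float
    llf: float
    aic: float
    bic: float
    n_obs: int
    k_params: int
    converged: bool
    var_fixed: float  # variance of the fixed-effect predictor over fitted rows
    data_fingerprint: Tuple = field(default=(), repr=False)

    @property
    def k_fixed(self) -> int:
        return len(self.coefficients)

    def to_dict(self) -> dict:
        return dict(
            formula=self.spec.formula(),
            estimation=self.spec.estimation,
            coefficients=self.coefficients,
            std_errors=self.std_errors,
            variance_components=dict(
                participant=self.var_participant,
                trial=self.var_trial,
                residual=self.var_residual,
            ),
            loglik=self.llf,
            aic=self.aic,
            bic=self.bic,
            n_obs=self.n_obs,
            k_params=self.k_params,
            converged=self.converged,
        )


@dataclass
class LRTResult:
    chi_square: float
    df: int
    p: float
    full: str = ""
    null: str = ""

    def to_dict(self) -> dict:
        return dict(chi_square=self.chi_square, df=self.df, p=self.p,
                    full=self.full, null=self.null)


@dataclass
class R2Result:
    marginal: float
    conditional: float


class NotNestedError(ValueError):
    """The two fits are not a valid nested ML pair on the same rows."""


def prepare_model_frame(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Listwise-complete rows with standardized continuous predictors.

    Continuous physiological predictors are z-scored over the retained rows;
    ``period`` is centered (numeric 1..P coding). ``participant`` and
    ``trial`` grouping columns are carried through.
    """
    cols = list(dict.fromkeys(list(spec.main_terms) + [spec.response]))
    needed = cols + ["participant", "trial"]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    df = table[needed].dropna(subset=cols).copy()
    if df["participant"].nunique() < 2 or df["trial"].nunique() < 2:
        raise ValueError("need >=2 participants and >=2 trial indices")
    for c in spec.main_terms:
        if c == "period":
            df[c] = df[c].astype(float) - df[c].astype(float).mean()
        elif spec.standardize and c in CONTINUOUS_PREDICTORS:
            sd = df[c].std(ddof=1)
            if sd == 0:
                raise ValueError(f"predictor {c!r} is constant")
            df[c] = (df[c] - df[c].mean()) / sd
    return df


def fit_lme(table: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit one mixed model with crossed participant/trial random intercepts.

    Estimation is ML by default so fits can enter fixed-effect LRTs; REML is
    available for variance reporting. Non-convergence is flagged on the
    result (downstream LRTs refuse flagged fits); zero variance components
    are allowed with a warning.
    """
    df = prepare_model_frame(table, spec)
    vc = {"participant": "0 + C(participant)", "trial": "0 + C(trial)"}
    model = smf.mixedlm(
        spec.formula(), df, groups=np.ones(len(df)), vc_formula=vc, re_formula="0"
    )
    # the profiled likelihood has flat ridges where a single optimizer can
    # report convergence short of the optimum; always multi-start and keep
    # the best likelihood (verified against lme4 fits of the same models)
    candidates = []
    for tier in (("lbfgs", "powell"), ("cg", "nm")):
        for method in tier:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = model.fit(reml=(spec.estimation == "REML"), method=method)
                except Exception:
                    continue
            if np.isfinite(res.llf):
                candidates.append(res)
        if any(c.converged for c in candidates):
            break
    if not candidates:
        raise RuntimeError(f"mixed-model fit failed for {spec.formula()!r}")
    result = max(candidates, key=lambda r: r.llf)
    converged = bool(result.converged)

    fe = dict(zip(result.model.exog_names, np.asarray(result.fe_params, dtype=float)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bse = np.asarray(result.bse_fe, dtype=float)
    se = dict(zip(result.model.exog_names, bse))
    vcomp = dict(zip(result.model.exog_vc.names, np.asarray(result.vcomp, dtype=float)))
    var_p = float(vcomp.get("participant", 0.0))
    var_t = float(vcomp.get("trial", 0.0))
    scale = float(result.scale)
    if min(var_p, var_t) <= 0.0:
        warnings.warn("singular fit: a variance component is (near) zero")
    k = len(fe) + len(vcomp) + 1
    llf = float(result.llf)
    n = int(len(df))
    fixed_pred = result.model.exog @ np.asarray(result.fe_params)
    fit = ModelFit(
        spec=spec,
        coefficients=fe,
        std_errors=se,
        var_participant=var_p,
        var_trial=var_t,
        var_residual=scale,
        llf=llf,
        aic=-2.0 * llf + 2.0 * k,
        bic=-2.0 * llf + k * np.log(n),
        n_obs=n,
        k_params=k,
        converged=converged,
        var_fixed=float(np.var(fixed_pred)),
        data_fingerprint=(n, round(float(df[spec.response].sum()), 6)),
    )
    return fit


def likelihood_ratio_test(full: ModelFit, null: ModelFit) -> LRTResult:
    """χ² = 2·(llf_full − llf_null) on the difference in fixed-effect count.

    Both fits must be converged ML fits of nested fixed-effect structures on
    identical rows; the random structure is held fixed across the pair, so
    variance-component boundary issues do not arise.
    """
    if full.spec.estimation != "ML" or null.spec.estimation != "ML":
        raise NotNestedError("LRTs of fixed effects require ML fits")
    if not null.spec.nests_within(full.spec):
        raise NotNestedError("null model terms do not nest within the full model")
    if full.data_fingerprint != null.data_fingerprint:
        raise NotNestedError("fits use different rows; refit on common cases")
    if not (full.converged and null.converged):
        raise NotNestedError("refusing LRT on a non-converged fit")
    df_diff = full.k_fixed - null.k_fixed
    stat = max(0.0, 2.0 * (full.llf - null.llf))
    if df_diff == 0:
        # self-comparison of one fixed-effect structure: no evidence either way
        return LRTResult(chi_square=stat, df=0, p=1.0,
                         full=full.spec.formula(), null=null.spec.formula())
    return LRTResult(
        chi_square=stat,
        df=df_diff,
        p=lrt_pvalue(stat, df_diff),
        full=full.spec.formula(),
        null=null.spec.formula(),
    )


def lrt_pvalue(chi_square: float, df: int) -> float:
    """Upper-tail chi-square probability for a likelihood-ratio statistic."""
    if chi_square < 0 or df < 1:
        raise ValueError("need chi_square >= 0 and df >= 1")
    return float(chi2.sf(chi_square, df))


def nakagawa_r2(fit: ModelFit) -> R2Result:
    """Nakagawa variance decomposition of a mixed model.

    marginal = σ²_fixed / (σ²_fixed + σ²_participant + σ²_trial + σ²_resid);
    conditional adds the random-intercept variances to the numerator.
    σ²_fixed is the variance of the fixed-effect linear predictor over the
    fitted rows.
    """
    if not fit.converged:
        raise ValueError("R² undefined for a non-converged fit")
    total = fit.var_fixed + fit.var_participant + fit.var_trial + fit.var_residual
    if total <= 0:
        raise ValueError("zero total variance; R² undefined")
    marginal = fit.var_fixed / total
    conditional = (fit.var_fixed + fit.var_participant + fit.var_trial) / total
    return R2Result(marginal=float(marginal), conditional=float(conditional))


# ---------------------------------------------------------------------------
# the model sequence of the analysis

SINGLE_MEASURES = ("alpha_db", "mean_rr", "rmssd", "ln_x")
TESTED_PAIRS = ("alpha_db:rmssd", "alpha_db:period", "rmssd:period")


def model_search(table: pd.DataFrame, drop_ln_x: Optional[bool] = None) -> dict:
    """Run the full RT model sequence and return one JSON-ready report.

    Fits, in order: the four single-measure × period interactive models
    (each with its additive null and LRT); the full five-term order-3 model;
    the reduced four-term model with lnX dropped (by default when lnX is not
    significant in the full model, mirroring the reported procedure; pass
    ``drop_ln_x`` to force either branch); the reduced model's additive null
    (LRT, 10 df); and the three sub-interaction LRTs, each against an
    'additive + tested pair' null (9 df).
    """
    fits: Dict[str, ModelFit] = {}
    lrts: Dict[str, LRTResult] = {}

    for m in SINGLE_MEASURES:
        inter = fit_lme(table, ModelSpec((m, "period"), order=2))
        addit = fit_lme(table, ModelSpec((m, "period"), order=1))
        fits[f"{m}_x_period"] = inter
        fits[f"{m}_plus_period"] = addit
        lrts[f"{m}_x_period_vs_additive"] = likelihood_ratio_test(inter, addit)

    full = fit_lme(table, ModelSpec(FULL_TERMS, order=3))
    fits["full_order3"] = full

    four_term = fit_lme(table, ModelSpec(REDUCED_TERMS, order=3))
    lrts["ln_x_contribution"] = likelihood_ratio_test(full, four_term)
    if drop_ln_x is None:
        # lnX is dropped when its terms contribute nothing by LRT
        drop_ln_x = lrts["ln_x_contribution"].p > 0.05
    reduced_terms = REDUCED_TERMS if drop_ln_x else FULL_TERMS
    reduced = four_term if drop_ln_x else full
    fits["reduced_order3"] = reduced
    additive = fit_lme(table, ModelSpec(reduced_terms, order=1))
    fits["reduced_additive"] = additive
    lrts["reduced_order3_vs_additive"] = likelihood_ratio_test(reduced, additive)

    for pair in TESTED_PAIRS:
        if not set(pair.split(":")) <= set(reduced_terms):
            continue
        null = fit_lme(
            table, ModelSpec(tuple(reduced_terms), order=1, extra_interactions=(pair,))
        )
        key = pair.replace("alpha_db", "alpha").replace(":", "_x_")
        fits[f"additive_plus_{key}"] = null
        lrts[f"beyond_{key}"] = likelihood_ratio_test(reduced, null)

    r2 = nakagawa_r2(reduced)
    return dict(
        dropped_ln_x=bool(drop_ln_x),
        models={k: f.to_dict() for k, f in fits.items()},
        lrt={k: r.to_dict() for k, r in lrts.items()},
        r2=dict(marginal=r2.marginal, conditional=r2.conditional),
    )


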