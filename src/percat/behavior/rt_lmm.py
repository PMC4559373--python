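"""Linear mixed models for reaction times (correct trials only).

RT (ms) is modeled as beta_0 + beta_bias * x_bias + beta_slope * x_slope
(discriminability staircase) or beta_0 + beta_bias * x_bias +
beta_cont * x_cont (level contrast), with participant-level random effects
on every coefficient.  Estimation is statsmodels MixedLM (REML); inference
is the same Monte-Carlo scheme as the accuracy model.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .probit_glmm import GlmmFit, mc_inference

__all__ = ["fit_rt_lmm"]


def fit_rt_lmm(
    coded: pd.DataFrame,
    formula_variant: str = "slope",
    n_mc: int = 10_000,
    seed: int = 0,
    *,
    participant_col: str = "participant",
) -> GlmmFit:
    """Fit the RT linear mixed model to coded correct trials.

    ``coded`` must carry participant, rt_ms, x_bias and x_slope or x_cont
    columns (see :func:`percat.behavior.coding.code_trials` with
    model="rt").  With a single participant the model degrades to OLS.
    """
    import statsmodels.api as sm

    third = {"slope": "x_slope", "contrast": "x_cont"}.get(formula_variant)
    if third is None:
        raise ValueError(f"unknown formula_variant {formula_variant!r}")
    names = ["beta_0", "beta_bias", third.replace("x_", "beta_")]
    rt = coded["rt_ms"].to_numpy(float)
    if np.isnan(rt).any():
        raise ValueError("rt_ms contains missing values")
    if np.ptp(rt) == 0 and len(rt) > 1:
        # degenerate but well-defined: all effects 0, intercept = the value
        beta = np.array([rt[0], 0.0, 0.0])
        params, se, ci, p = mc_inference(beta, np.zeros((3, 3)), names, n_mc, seed)
        return GlmmFit(
            params=params, se=se, ci=ci, p=p,
            random_effect_sds={n: 0.0 for n in names},
            vcov=np.zeros((3, 3)), n_mc=n_mc, seed=seed, n_obs=len(rt),
            n_participants=coded[participant_col].nunique(), loglik=np.nan,
            model="rt_constant",
        )
    X = np.column_stack(
        [np.ones(len(coded)), coded["x_bias"].to_numpy(float), coded[third].to_numpy(float)]
    )
    groups = coded[participant_col].to_numpy()
    n_participants = len(pd.unique(groups))

    if n_participants < 2:
        res = sm.OLS(rt, X).fit()
        beta = np.asarray(res.params, float)
        vcov = np.asarray(res.cov_params(), float)
        params, se, ci, p = mc_inference(beta, vcov, names, n_mc, seed)
        return GlmmFit(
            params=params, se=se, ci=ci, p=p,
            random_effect_sds={n: 0.0 for n in names},
            vcov=vcov, n_mc=n_mc, seed=seed, n_obs=len(rt),
            n_participants=1, loglik=float(res.llf), model="rt_ols",
        )

    # independent (diagonal) participant random effects on all coefficients:
    # random intercept plus one variance component per regressor
    df = pd.DataFrame(
        {"rt_ms": rt, "x_bias": X[:, 1], "x_third": X[:, 2], "participant": groups}
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary variance warnings are expected
        model = sm.regression.mixed_linear_model.MixedLM.from_formula(
            "rt_ms ~ x_bias + x_third",
            groups="participant",
            re_formula="1",
            vc_formula={"x_bias": "0 + x_bias", "x_third": "0 + x_third"},
            data=df,
        )
        res = model.fit(reml=True, method=["lbfgs", "powell"])
    beta = np.asarray(res.fe_params, float)
    vcov = np.asarray(res.cov_params())[: len(names), : len(names)]
    params, se, ci, p = mc_inference(
        beta, vcov, names, n_mc, seed, df=n_participants - 1
    )
    vc = dict(zip(model.exog_vc.names, np.clip(res.vcomp, 0, None)))
    re_sds = {
        names[0]: float(np.sqrt(max(np.asarray(res.cov_re)[0, 0], 0.0))),
        names[1]: float(np.sqrt(vc.get("x_bias", 0.0))),
        names[2]: float(np.sqrt(vc.get("x_third", 0.0))),
    }
    return GlmmFit(
        params=params,
        se=se,
        ci=ci,
        p=p,
        random_effect_sds=re_sds,
        vcov=vcov,
        n_mc=n_mc,
        seed=seed,
        n_obs=len(rt),
        n_participants=n_participants,
        loglik=float(res.llf),
        converged=bool(res.converged),
        model="rt_lmm",
    )
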