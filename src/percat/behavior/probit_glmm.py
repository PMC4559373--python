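"""Probit generalized linear mixed model via the Laplace approximation.

Model: y_ij ~ Bernoulli(Phi(x_ij' (beta + b_i))), b_i ~ N(0, diag(sigma^2)),
with a participant-level random effect on every coefficient (bias,
sensitivity, and the slope or contrast term).  The marginal likelihood is
approximated by a per-participant Laplace integral (as in lme4's default for
GLMMs); fixed effects and random-effect SDs are estimated by maximizing it
with L-BFGS-B on (beta, log sigma).

Inference is Monte-Carlo: n_mc draws from the asymptotic N(beta_hat, V)
sampling distribution of the fixed effects give percentile confidence
intervals and two-tailed p-values (floored at 1/n_mc).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_ndtr

__all__ = ["GlmmFit", "fit_probit_glmm", "mc_inference"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class GlmmFit:
    """Fixed effects with Monte-Carlo CIs/p-values and random-effect SDs."""

    params: dict[str, float]
    se: dict[str, float]
    ci: dict[str, tuple[float, float]]
    p: dict[str, float]
    random_effect_sds: dict[str, float]
    vcov: np.ndarray
    n_mc: int
    seed: int
    n_obs: int
    n_participants: int
    loglik: float
    converged: bool = True
    separation: bool = False
    model: str = "probit_glmm"
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"{self.model}: {self.n_obs} trials, {self.n_participants} participant(s), "
            f"loglik {self.loglik:.2f}, n_mc={self.n_mc}"
        ]
        for name, est in self.params.items():
            lo, hi = self.ci[name]
            lines.append(
                f"  {name:<10s} {est:9.4f}  SE {self.se[name]:7.4f}  "
                f"CI [{lo:8.4f}, {hi:8.4f}]  p {self.p[name]:.4g}  "
                f"RE-SD {self.random_effect_sds.get(name, 0.0):.4f}"
            )
        if self.separation:
            lines.append("  WARNING: fitted probabilities at 0/1 (separation)")
        return "\n".join(lines)


def mc_inference(
    beta: np.ndarray,
    vcov: np.ndarray,
    names: list[str],
    n_mc: int,
    seed: int,
    df: float | None = None,
) -> tuple[dict, dict, dict, dict]:
    """Percentile CIs and two-tailed sign-crossing p-values from MC draws.

    Draws come from the asymptotic sampling distribution of the fixed
    effects; with ``df`` set (participants - 1 for mixed fits) a
    multivariate-t is used instead of a normal — the standard small-sample
    correction for effects whose information accrues per participant.
    """
    rng = np.random.default_rng(seed)
    vcov = np.asarray(vcov, dtype=float)
    # symmetrize to tolerate round-off in numerical Hessians
    vcov = (vcov + vcov.T) / 2.0
    draws = rng.multivariate_normal(beta, vcov, size=n_mc, method="svd")
    if df is not None and np.isfinite(df) and df > 0:
        scale = np.sqrt(df / rng.chisquare(df, size=n_mc))
        draws = beta + (draws - beta) * scale[:, None]
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    p_pos = (draws > 0).mean(axis=0)
    p_two = np.maximum(2.0 * np.minimum(p_pos, 1.0 - p_pos), 1.0 / n_mc)
    params = dict(zip(names, beta))
    se = dict(zip(names, np.sqrt(np.clip(np.diag(vcov), 0, None))))
    ci = {n: (float(lo[i]), float(hi[i])) for i, n in enumerate(names)}
    p = dict(zip(names, p_two))
    return params, se, ci, p


def _lam(z: np.ndarray) -> np.ndarray:
    """phi(z)/Phi(z), numerically stable for large negative z."""
    return np.exp(-0.5 * z * z - _LOG_SQRT_2PI - log_ndtr(z))


class _Laplace:
    """Per-participant Laplace marginal log-likelihood with warm starts."""

    def __init__(self, Xs: list[np.ndarray], ss: list[np.ndarray]):
        self.Xs = Xs
        self.ss = ss  # +/-1 response signs
        self.q = Xs[0].shape[1]
        self.b_cache = [np.zeros(self.q) for _ in Xs]

    def _pen_ll(self, X, s, beta, d_inv, b) -> float:
        z = s * (X @ (beta + b))
        return float(log_ndtr(z).sum() - 0.5 * np.dot(b * d_inv, b))

    def _mode(self, i: int, beta: np.ndarray, d_inv: np.ndarray):
        X, s = self.Xs[i], self.ss[i]
        b = self.b_cache[i].copy()
        f = self._pen_ll(X, s, beta, d_inv, b)
        H = None
        for _ in range(60):
            z = s * (X @ (beta + b))
            lam = _lam(z)
            g = X.T @ (s * lam) - d_inv * b
            w = lam * (z + lam)  # = -d^2 logPhi / d eta^2 >= 0
            H = X.T @ (w[:, None] * X) + np.diag(d_inv)
            try:
                delta = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(H, g, rcond=None)[0]
            step = 1.0
            while step > 1e-6:
                b_new = b + step * delta
                f_new = self._pen_ll(X, s, beta, d_inv, b_new)
                if f_new >= f - 1e-12:
                    break
                step /= 2.0
            if f_new < f - 1e-12:
                break  # no improving step; accept current mode
            b, f = b_new, f_new
            if np.max(np.abs(g)) < 1e-8:
                break
        self.b_cache[i] = b
        # Hessian at the accepted mode
        z = s * (X @ (beta + b))
        lam = _lam(z)
        w = lam * (z + lam)
        H = X.T @ (w[:, None] * X) + np.diag(d_inv)
        return b, f, H

    def neg_marginal_ll(self, params: np.ndarray) -> float:
        beta = params[: self.q]
        log_sigma = params[self.q :]
        sigma2 = np.exp(2.0 * log_sigma)
        d_inv = 1.0 / sigma2
        total = 0.0
        for i in range(len(self.Xs)):
            b, f, H = self._mode(i, beta, d_inv)
            sign, logdet_H = np.linalg.slogdet(H)
            if sign <= 0:
                return 1e10
            total += f - log_sigma.sum() - 0.5 * logdet_H
        return -total

    def max_abs_linpred(self, params: np.ndarray) -> float:
        beta = params[: self.q]
        d_inv = np.exp(-2.0 * params[self.q :])
        worst = 0.0
        for i in range(len(self.Xs)):
            b, _, _ = self._mode(i, beta, d_inv)
            worst = max(worst, float(np.abs(self.Xs[i] @ (beta + b)).max()))
        return worst


def _design(coded: pd.DataFrame, formula_variant: str):
    third = {"slope": "x_slope", "contrast": "x_cont"}.get(formula_variant)
    if third is None:
        raise ValueError(f"unknown formula_variant {formula_variant!r}")
    names = ["beta_bias", "beta_sens", third.replace("x_", "beta_")]
    X = np.column_stack(
        [
            np.ones(len(coded)),
            coded["x_sens"].to_numpy(float),
            coded[third].to_numpy(float),
        ]
    )
    for col, name in zip(X.T[1:], names[1:]):
        if np.ptp(col) == 0:
            raise ValueError(f"design column {name} is constant")
    return X, names


def fit_probit_glmm(
    coded: pd.DataFrame,
    formula_variant: str = "slope",
    n_mc: int = 10_000,
    seed: int = 0,
    *,
    participant_col: str = "participant",
) -> GlmmFit:
    """Fit the accuracy probit model to coded trials.

    ``coded`` must carry participant, y, x_sens and x_slope (variant "slope")
    or x_cont (variant "contrast") columns — see
    :func:`percat.behavior.coding.code_trials`.  With >= 2 participants all
    coefficients get participant-level Gaussian random effects (Laplace
    marginal likelihood); with a single participant the random effects are
    dropped and a plain probit GLM is fit.
    """
    X, names = _design(coded, formula_variant)
    y = coded["y"].to_numpy(int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("y must be binary")
    groups = coded[participant_col].to_numpy()
    participants = pd.unique(groups)

    if len(participants) < 2:
        return _fit_single(X, y, names, n_mc, seed)

    Xs = [X[groups == p] for p in participants]
    ss = [2.0 * y[groups == p] - 1.0 for p in participants]
    lap = _Laplace(Xs, ss)

    # initialize fixed effects from the pooled GLM
    beta0 = _pooled_probit(X, y)
    x0 = np.concatenate([beta0, np.log(np.full(len(names), 0.3))])
    bounds = [(None, None)] * len(names) + [(np.log(1e-3), np.log(5.0))] * len(names)
    res = minimize(
        lap.neg_marginal_ll,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-10},
    )
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise RuntimeError(f"probit GLMM optimizer failed: {res.message}\n{res}")

    q = len(names)
    beta_hat = res.x[:q]
    sigma_hat = np.exp(res.x[q:])

    from statsmodels.tools.numdiff import approx_hess

    hess = approx_hess(res.x, lap.neg_marginal_ll)
    vcov_full = _safe_inv(hess)
    vcov = vcov_full[:q, :q]

    params, se, ci, p = mc_inference(
        beta_hat, vcov, names, n_mc, seed, df=len(participants) - 1
    )
    return GlmmFit(
        params=params,
        se=se,
        ci=ci,
        p=p,
        random_effect_sds=dict(zip(names, sigma_hat)),
        vcov=vcov,
        n_mc=n_mc,
        seed=seed,
        n_obs=len(y),
        n_participants=len(participants),
        loglik=-res.fun,
        converged=bool(res.success),
        separation=lap.max_abs_linpred(res.x) > 8.0,
        diagnostics={"optimizer_message": str(res.message), "n_iter": int(res.nit)},
    )


def _pooled_probit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    import statsmodels.api as sm

    model = sm.GLM(y, X, family=sm.families.Binomial(sm.families.links.Probit()))
    try:
        return np.asarray(model.fit(maxiter=100).params, dtype=float)
    except Exception:
        return np.zeros(X.shape[1])


def _fit_single(X, y, names, n_mc, seed) -> GlmmFit:
    import statsmodels.api as sm

    model = sm.GLM(y, X, family=sm.families.Binomial(sm.families.links.Probit()))
    res = model.fit(maxiter=200)
    beta = np.asarray(res.params, float)
    vcov = np.asarray(res.cov_params(), float)
    params, se, ci, p = mc_inference(beta, vcov, names, n_mc, seed)
    fitted = res.fittedvalues
    return GlmmFit(
        params=params,
        se=se,
        ci=ci,
        p=p,
        random_effect_sds={n: 0.0 for n in names},
        vcov=vcov,
        n_mc=n_mc,
        seed=seed,
        n_obs=len(y),
        n_participants=1,
        loglik=float(res.llf),
        converged=bool(res.converged),
        separation=bool(np.any((fitted < 1e-10) | (fitted > 1 - 1e-10))),
        model="probit_glm",
    )


def _safe_inv(hess: np.ndarray) -> np.ndarray:
    try:
        inv = np.linalg.inv(hess)
        if np.all(np.diag(inv) > 0):
            return inv
    except np.linalg.LinAlgError:
        pass
    return np.linalg.pinv((hess + hess.T) / 2.0)
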