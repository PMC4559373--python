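"""Derived sensitivities, nonparametric A', and rank correlation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .probit_glmm import GlmmFit

__all__ = ["SensitivityPair", "derived_sensitivities", "aprime", "rank_correlation"]


@dataclass(frozen=True)
class SensitivityPair:
    """Task sensitivities implied by a contrast-variant fit."""

    basic: float
    superordinate: float


def derived_sensitivities(fit: GlmmFit | Mapping[str, float]) -> SensitivityPair:
    """basic = beta_sens - 0.5*beta_cont; superordinate = beta_sens + 0.5*beta_cont."""
    params = fit.params if isinstance(fit, GlmmFit) else fit
    if "beta_cont" not in params:
        raise ValueError("derived sensitivities need a contrast-variant fit")
    sens, cont = params["beta_sens"], params["beta_cont"]
    return SensitivityPair(basic=sens - 0.5 * cont, superordinate=sens + 0.5 * cont)


def aprime(hit_rate: float, fa_rate: float) -> float:
    """Nonparametric sensitivity A' (Pollack & Norman piecewise formula).

    A' = 0.5 when hit = fa; 1.0 for a perfect observer.  The formula is
    applied symmetrically when the false-alarm rate exceeds the hit rate.
    """
    h, f = float(hit_rate), float(fa_rate)
    if not (0.0 <= h <= 1.0 and 0.0 <= f <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    if h == f:
        return 0.5
    if h > f:
        return 0.5 + ((h - f) * (1.0 + h - f)) / (4.0 * h * (1.0 - f))
    return 0.5 - ((f - h) * (1.0 + f - h)) / (4.0 * f * (1.0 - h))


def rank_correlation(
    model_scores: Mapping[str, float] | Sequence[float],
    behavior: Mapping[str, float] | Sequence[float],
    *,
    method: str = "asymptotic",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rank correlation between model and behavioral task scores.

    Mappings are aligned on their common keys; sequences positionally.
    ``method="permutation"`` gives an exact-style permutation p-value for
    small task counts.  Ties get mid-ranks.  Requires >= 4 paired tasks and
    non-constant vectors.
    """
    if isinstance(model_scores, Mapping) and isinstance(behavior, Mapping):
        keys = sorted(set(model_scores) & set(behavior))
        x = np.array([model_scores[k] for k in keys], float)
        y = np.array([behavior[k] for k in keys], float)
    else:
        x = np.asarray(list(model_scores), float)
        y = np.asarray(list(behavior), float)
        if len(x) != len(y):
            raise ValueError("score sequences must have equal length")
    if len(x) < 4:
        raise ValueError("need >= 4 paired tasks")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")

    rho, p = stats.spearmanr(x, y)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            r, _ = stats.spearmanr(x, rng.permutation(y))
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    elif method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p)
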