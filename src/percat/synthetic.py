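"""Synthetic study materials: oriented-noise scene textures and simulated observers.

Images are inverse-filtered white noise: a category is a smooth gain surface
over orientation and spatial frequency, applied to the noise spectrum.  The
gist descriptor is exactly an orientation/scale energy summary, so the
separability parameter ``delta`` (which scales the log-gain contrast between
categories) maps monotonically onto descriptor-space margin: delta = 0 makes
all categories draw from one distribution; large delta makes them linearly
separable.

Observers are the generative twins of the analysis models: responses are
Bernoulli draws through the probit accuracy model and RTs are Gaussian draws
from the linear RT model, with participant-level Gaussian random effects on
every parameter and a hard response deadline (RT past the deadline becomes
an omitted response — censoring, not resampling).

The exported observer presets are calibrated, by closed-form probit and
censored-Gaussian algebra, to the behavioral summary statistics of the study
conditions they emulate (mean accuracy, censored mean RT, no-response rate,
and the generating slope/contrast coefficients); docs/methods.md shows the
derivations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .behavior.coding import SLOPE_LADDER
from .gist import ImageStimulus, preprocess

__all__ = [
    "SyntheticCategorySpec",
    "SyntheticObserverSpec",
    "make_category_spec",
    "category_pair",
    "category_pools",
    "generate_images",
    "exp1_trial_table",
    "exp2_trial_table",
    "exp1_observer",
    "exp2_observer",
    "simulate_observer",
]


@dataclass
class SyntheticCategorySpec:
    """Generating distribution of one scene category.

    ``orientation_gain`` (length = number of orientation bands) and
    ``frequency_gain`` (length = number of scale bands) are positive
    multipliers on band energy; ``separability`` (delta) scales their
    log-contrast, so delta = 0 collapses every category onto the same
    white-noise distribution.
    """

    name: str
    superordinate: str  # natural | manmade
    orientation_gain: np.ndarray
    frequency_gain: np.ndarray
    separability: float = 1.0
    texture_noise_sd: float = 25.0

    def __post_init__(self) -> None:
        self.orientation_gain = np.asarray(self.orientation_gain, float)
        self.frequency_gain = np.asarray(self.frequency_gain, float)
        if np.any(self.orientation_gain <= 0) or np.any(self.frequency_gain <= 0):
            raise ValueError("band gains must be positive")
        if self.separability < 0:
            raise ValueError("separability must be >= 0")
        if self.texture_noise_sd <= 0:
            raise ValueError("texture_noise_sd must be positive")


def make_category_spec(
    name: str,
    superordinate: str,
    peak_orientation: int,
    peak_scale: int = 1,
    *,
    orientation_bands: int = 8,
    scale_bands: int = 4,
    gain: float = 4.0,
    concentration: float = 1.0,
    separability: float = 1.0,
    texture_noise_sd: float = 25.0,
) -> SyntheticCategorySpec:
    """Category with energy concentrated around one orientation and scale.

    ``gain`` is the peak-to-trough band-energy ratio at delta = 1;
    ``concentration`` sharpens (>1) or broadens (<1) the orientation tuning.
    """
    k = np.arange(orientation_bands)
    # pi-periodic distance between band k and the peak band
    d = np.minimum(
        np.abs(k - peak_orientation), orientation_bands - np.abs(k - peak_orientation)
    ) / (orientation_bands / 2.0)
    og = np.exp(np.log(gain) * (1.0 - d) ** concentration)
    fg = np.ones(scale_bands)
    fg[peak_scale] = gain ** 0.5
    return SyntheticCategorySpec(
        name=name,
        superordinate=superordinate,
        orientation_gain=og / np.exp(np.mean(np.log(og))),  # unit geometric mean
        frequency_gain=fg / np.exp(np.mean(np.log(fg))),
        separability=separability,
        texture_noise_sd=texture_noise_sd,
    )


def category_pair(delta: float, **kwargs) -> list[SyntheticCategorySpec]:
    """Two orthogonally tuned categories at separability ``delta``."""
    return [
        make_category_spec("cat_a", "natural", 0, separability=delta, **kwargs),
        make_category_spec("cat_b", "manmade", 4, separability=delta, **kwargs),
    ]


def category_pools(
    n_natural: int = 5,
    n_manmade: int = 7,
    delta: float = 1.0,
    *,
    include_basic_target: bool = True,
) -> list[SyntheticCategorySpec]:
    """Pools of distinct categories for combination searches.

    Natural categories tile the lower orientation bands at coarse scales,
    man-made ones the upper bands at finer scales (echoing the oblique,
    carpentered-world statistics of real scene classes); an extra
    "forest"-like basic target shares the natural family's tuning.
    """
    specs = []
    for i in range(n_natural):
        specs.append(
            make_category_spec(
                f"nat_{i}", "natural", peak_orientation=i % 4, peak_scale=(2 + i) % 4,
                separability=delta,
            )
        )
    for j in range(n_manmade):
        specs.append(
            make_category_spec(
                f"man_{j}", "manmade", peak_orientation=4 + j % 4, peak_scale=j % 4,
                separability=delta,
            )
        )
    if include_basic_target:
        specs.append(
            make_category_spec(
                "basic_target", "natural", peak_orientation=2, peak_scale=1,
                separability=delta, concentration=2.0,
            )
        )
    return specs


def _gain_mask(
    spec: SyntheticCategorySpec, size: int
) -> np.ndarray:
    """Smooth frequency-domain amplitude mask exp(delta * log-gain surface)."""
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.rfftfreq(size)[None, :]
    f = np.hypot(fy, fx)
    theta = np.mod(np.arctan2(fy, fx), np.pi)

    n_or = len(spec.orientation_gain)
    log_og = np.log(spec.orientation_gain)
    # circular (pi-periodic) linear interpolation of log orientation gain
    pos = theta / (np.pi / n_or)
    lo = np.floor(pos).astype(int) % n_or
    hi = (lo + 1) % n_or
    w = pos - np.floor(pos)
    log_orient = (1 - w) * log_og[lo] + w * log_og[hi]

    n_sc = len(spec.frequency_gain)
    centers_f = np.log2(1.0 / 8.0) - np.arange(n_sc)  # log2 of 1/8, 1/16, ...
    with np.errstate(divide="ignore"):
        lf = np.log2(np.maximum(f, 1e-9))
    log_fg = np.log(spec.frequency_gain)
    # linear interpolation over log2 frequency, clamped at the band ends
    log_freq = np.interp(-lf, -centers_f, log_fg)  # negate for ascending x

    mask = np.exp(spec.separability * (log_orient + log_freq))
    mask[0, 0] = 0.0  # DC handled by brightness normalization
    return mask


def generate_images(
    specs: Sequence[SyntheticCategorySpec],
    n_per_category: int,
    size: int = 256,
    seed: int = 0,
    *,
    target_mean: float = 128.0,
) -> list[ImageStimulus]:
    """Inverse-filtered white-noise textures with category band structure.

    Each image is white Gaussian noise shaped in the frequency domain by its
    category's gain mask, scaled to the category's texture contrast
    (``texture_noise_sd`` intensity units), then brightness-normalized to
    ``target_mean`` via the standard preprocessing.
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    out: list[ImageStimulus] = []
    ss = np.random.SeedSequence(seed).spawn(len(specs))
    for spec, child in zip(specs, ss):
        rng = np.random.default_rng(child)
        mask = _gain_mask(spec, size)
        for k in range(n_per_category):
            noise = rng.standard_normal((size, size))
            shaped = np.fft.irfft2(np.fft.rfft2(noise) * mask, s=(size, size))
            sd = shaped.std()
            if sd > 0:
                shaped = shaped * (spec.texture_noise_sd / sd)
            raw = shaped + target_mean
            stim = preprocess(
                raw,
                target_mean,
                id=f"{spec.name}_{k:04d}",
                basic_category=spec.name,
                superordinate_category=spec.superordinate,
                size=size,
            )
            out.append(stim)
    return out


# --- simulated observers -------------------------------------------------

@dataclass
class SyntheticObserverSpec:
    """Generative behavioral parameters (population means + participant SDs)."""

    beta_bias: float = 0.0
    beta_sens: float = 2.0
    beta_slope: float | None = None
    beta_cont: float | None = None
    rt_beta0: float = 380.0
    rt_bias: float = 0.0
    rt_slope: float | None = None
    rt_cont: float | None = None
    rt_noise_sd: float = 73.0
    deadline: float = 500.0
    participant_sd: dict[str, float] = field(default_factory=dict)

    _SD_DEFAULTS = {
        "beta_bias": 0.15,
        "beta_sens": 0.30,
        "beta_slope": 0.05,
        "beta_cont": 0.15,
        "rt_beta0": 15.0,
        "rt_bias": 4.0,
        "rt_slope": 1.5,
        "rt_cont": 4.0,
    }

    def __post_init__(self) -> None:
        if self.rt_noise_sd <= 0 or self.deadline <= 0:
            raise ValueError("rt_noise_sd and deadline must be positive")
        sds = dict(self._SD_DEFAULTS)
        sds.update(self.participant_sd)
        self.participant_sd = sds


def exp1_observer(**overrides) -> SyntheticObserverSpec:
    """Observer preset for the discriminability-staircase design.

    Calibrated so the population produces ~83% mean accuracy
    (beta_sens = 1.95 with beta_slope = 0.14 over the 5-level ladder),
    ~372 ms mean correct RT and ~5% omitted responses under the 500 ms
    deadline (rt_beta0 = 380, rt_noise_sd = 73), and a fitted (censored)
    RT slope near 3.92 (raw slope 4.85 before deadline censoring).
    """
    kw = dict(
        beta_bias=0.0, beta_sens=1.95, beta_slope=0.14,
        rt_beta0=380.0, rt_bias=0.0, rt_slope=4.85, rt_noise_sd=73.0,
    )
    kw.update(overrides)
    return SyntheticObserverSpec(**kw)


def exp2_observer(condition: str, **overrides) -> SyntheticObserverSpec:
    """Observer presets for the level-contrast design, per condition.

    Sensitivities are the condition's task sensitivities re-expressed as
    (beta_sens, beta_cont) through basic = beta_sens - 0.5*beta_cont and
    superordinate = beta_sens + 0.5*beta_cont; raw RT parameters are the
    censored-mean-matching solutions for the condition's per-task mean RTs.
    """
    presets = {
        # superordinate easier: sensitivities (sup 2.31, basic 1.44),
        # censored mean RTs (sup 356, basic 364)
        "superordinate_advantage": dict(
            beta_sens=1.875, beta_cont=0.87, rt_beta0=365.7, rt_cont=-9.8,
        ),
        # basic easier: sensitivities (sup 1.85, basic 2.28),
        # censored mean RTs (sup 376, basic 357)
        "basic_advantage": dict(
            beta_sens=2.065, beta_cont=-0.43, rt_beta0=373.6, rt_cont=23.0,
        ),
    }
    if condition not in presets:
        raise ValueError(f"unknown condition {condition!r}")
    kw = dict(beta_bias=0.0, rt_bias=0.0, rt_noise_sd=73.0, **presets[condition])
    kw.update(overrides)
    return SyntheticObserverSpec(**kw)


def exp1_trial_table(per_cell: int = 96) -> pd.DataFrame:
    """Trial structure for one participant: 2 classes x 5 levels x per_cell."""
    rows = []
    for cls in ("target", "distractor"):
        for label in sorted(SLOPE_LADDER):
            for k in range(per_cell):
                rows.append(
                    ("exp1", "exp1", "natural_vs_manmade", f"{cls[:3]}_{label}_{k:03d}",
                     cls, label)
                )
    return pd.DataFrame(
        rows,
        columns=["experiment", "condition", "task", "stimulus_id", "true_class",
                 "discriminability_label"],
    )


def exp2_trial_table(condition: str, per_task: int = 336) -> pd.DataFrame:
    """Trial structure for one participant: 2 tasks x per_task, half targets."""
    if per_task % 2:
        raise ValueError("per_task must be even (balanced targets/distractors)")
    rows = []
    for task in ("superordinate", "basic"):
        for i, cls in enumerate(["target"] * (per_task // 2) + ["distractor"] * (per_task // 2)):
            rows.append(("exp2", condition, task, f"{task[:3]}_{cls[:3]}_{i:03d}", cls, np.nan))
    return pd.DataFrame(
        rows,
        columns=["experiment", "condition", "task", "stimulus_id", "true_class",
                 "discriminability_label"],
    )


def _trial_codes(trials: pd.DataFrame, experiment: str):
    """Stimulus-determined regressors (no response needed)."""
    is_target = (trials["true_class"] == "target").to_numpy()
    x_sens = np.where(is_target, 0.5, -0.5)
    x_bias = x_sens.copy()
    if experiment == "exp1":
        ladder = trials["discriminability_label"].map(
            lambda v: SLOPE_LADDER[round(float(v), 1)]
        ).to_numpy(float)
        x_acc = np.where(is_target, -ladder, ladder)  # accuracy: reversed for targets
        x_rt = ladder
    else:
        is_sup = (trials["task"] == "superordinate").to_numpy()
        x_acc = np.where(is_sup == is_target, 0.25, -0.25)
        x_rt = np.where(is_sup, 0.5, -0.5)
    return is_target, x_sens, x_bias, x_acc, x_rt


def simulate_observer(
    trials: pd.DataFrame,
    observer: SyntheticObserverSpec,
    n_participants: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate trial records for ``n_participants`` observers.

    ``trials`` is a one-participant trial structure (see
    :func:`exp1_trial_table` / :func:`exp2_trial_table`); each participant
    gets an independent copy with participant-level Gaussian parameter draws.
    Responses follow the probit accuracy model; RTs the linear RT model; an
    RT beyond the deadline becomes response = "none" with no RT recorded.
    """
    experiment = trials["experiment"].iloc[0]
    third_acc = observer.beta_slope if experiment == "exp1" else observer.beta_cont
    third_rt = observer.rt_slope if experiment == "exp1" else observer.rt_cont
    if third_acc is None or third_rt is None:
        raise ValueError("observer is missing the slope/contrast parameter "
                         f"required for {experiment}")
    third_acc_name = "beta_slope" if experiment == "exp1" else "beta_cont"
    third_rt_name = "rt_slope" if experiment == "exp1" else "rt_cont"

    from scipy.special import ndtr

    is_target, x_sens, x_bias, x_acc, x_rt = _trial_codes(trials, experiment)
    sd = observer.participant_sd
    rng = np.random.default_rng(seed)
    frames = []
    for p in range(n_participants):
        bias = observer.beta_bias + sd["beta_bias"] * rng.standard_normal()
        sens = observer.beta_sens + sd["beta_sens"] * rng.standard_normal()
        third = third_acc + sd[third_acc_name] * rng.standard_normal()
        r0 = observer.rt_beta0 + sd["rt_beta0"] * rng.standard_normal()
        rb = observer.rt_bias + sd["rt_bias"] * rng.standard_normal()
        r3 = third_rt + sd[third_rt_name] * rng.standard_normal()

        p_target = ndtr(bias + sens * x_sens + third * x_acc)
        y = rng.random(len(trials)) < p_target
        rt = r0 + rb * x_bias + r3 * x_rt + observer.rt_noise_sd * rng.standard_normal(
            len(trials)
        )
        rt = np.maximum(rt, 1.0)
        omitted = rt > observer.deadline

        df = trials.copy()
        df.insert(0, "participant", f"p{p:02d}")
        df["response"] = np.where(omitted, "none", np.where(y, "target", "distractor"))
        df["rt_ms"] = np.where(omitted, np.nan, rt)
        df["correct"] = np.where(omitted, np.nan, y == is_target)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
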