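"""Design codings mapping trials to probit-model regressors.

Vocabulary: ``true_class`` and ``response`` are "target" / "distractor"
("none" for omitted responses).  In the natural vs. man-made task the target
class is man-made, so y = 1 encodes a man-made (target-button) response.

Accuracy models (y = probit^-1(beta_bias + beta_sens*x_sens + ...)):

* x_sens = +0.5 for target (man-made) trials, -0.5 for distractor (natural);
* discriminability-staircase design: x_slope runs (-2, -1, 0, 1, 2) for
  natural images at discriminability (1.0, 0.8, 0.6, 0.4, 0.2) and reversed
  for man-made, so positive beta_slope means sensitivity grows with
  discriminability;
* level-contrast design: x_cont = +0.25 for superordinate/target and
  basic/distractor trials, -0.25 for superordinate/distractor and
  basic/target trials (an interaction contrast).

RT models (correct trials only):

* x_bias = +0.5 target, -0.5 distractor trials;
* staircase: x_slope = (-2, -1, 0, 1, 2) at discriminability
  (1.0, 0.8, 0.6, 0.4, 0.2) for all images (no class reversal);
* contrast: x_cont = +0.5 for the superordinate task, -0.5 for basic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "DesignCoding",
    "code_exp1_accuracy",
    "code_exp1_rt",
    "code_exp2_accuracy",
    "code_exp2_rt",
    "code_trials",
    "SLOPE_LADDER",
]

#: x_slope value per discriminability label, natural-image (distractor) scheme
SLOPE_LADDER: dict[float, float] = {1.0: -2.0, 0.8: -1.0, 0.6: 0.0, 0.4: 1.0, 0.2: 2.0}

RESPONSES = ("target", "distractor", "none")


@dataclass
class TrialRecord:
    """One behavioral trial."""

    participant: str
    experiment: str  # exp1 | exp2
    condition: str
    task: str  # superordinate | basic (exp2); task name otherwise
    stimulus_id: str
    true_class: str  # target | distractor
    response: str  # target | distractor | none
    discriminability_label: float | None = None
    rt_ms: float | None = None
    correct: bool | None = None
    deadline_ms: float = 500.0

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        if self.response == "none":
            if self.rt_ms is not None:
                raise ValueError("omitted response cannot carry an RT")
        elif self.rt_ms is not None and not (0 < self.rt_ms <= self.deadline_ms):
            raise ValueError(f"rt_ms {self.rt_ms} outside (0, {self.deadline_ms}]")
        if self.response != "none":
            expected = self.response == self.true_class
            if self.correct is None:
                self.correct = expected
            elif self.correct != expected:
                raise ValueError("correct flag inconsistent with response vs true_class")


@dataclass
class DesignCoding:
    """Regressor values for one trial."""

    y: int
    x_sens: float
    x_slope: float | None = None
    x_cont: float | None = None
    x_bias: float | None = None


def _ladder(label: float) -> float:
    try:
        return SLOPE_LADDER[round(float(label), 1)]
    except (KeyError, TypeError, ValueError):
        raise ValueError(f"unknown discriminability label {label!r}") from None


def code_exp1_accuracy(trial: TrialRecord) -> DesignCoding:
    """Staircase accuracy coding; y = 1 for a man-made (target) response."""
    if trial.response == "none":
        raise ValueError("omitted trials are not coded")
    if trial.discriminability_label is None:
        raise ValueError("discriminability label required")
    is_target = trial.true_class == "target"
    ladder = _ladder(trial.discriminability_label)
    return DesignCoding(
        y=int(trial.response == "target"),
        x_sens=0.5 if is_target else -0.5,
        x_slope=-ladder if is_target else ladder,
    )


def code_exp1_rt(trial: TrialRecord) -> DesignCoding:
    """Staircase RT coding (correct trials); x_bias mirrors the class."""
    if trial.response == "none":
        raise ValueError("omitted trials are not coded")
    if trial.discriminability_label is None:
        raise ValueError("discriminability label required")
    return DesignCoding(
        y=int(trial.response == "target"),
        x_sens=0.5 if trial.true_class == "target" else -0.5,
        x_slope=_ladder(trial.discriminability_label),
        x_bias=0.5 if trial.true_class == "target" else -0.5,
    )


def code_exp2_accuracy(trial: TrialRecord) -> DesignCoding:
    """Level-contrast accuracy coding; y = 1 for a target-button press."""
    if trial.response == "none":
        raise ValueError("omitted trials are not coded")
    is_target = trial.true_class == "target"
    is_sup = trial.task == "superordinate"
    return DesignCoding(
        y=int(trial.response == "target"),
        x_sens=0.5 if is_target else -0.5,
        x_cont=0.25 if (is_sup == is_target) else -0.25,
    )


def code_exp2_rt(trial: TrialRecord) -> DesignCoding:
    """Level-contrast RT coding (correct trials only)."""
    if trial.response == "none":
        raise ValueError("omitted trials are not coded")
    return DesignCoding(
        y=int(trial.response == "target"),
        x_sens=0.5 if trial.true_class == "target" else -0.5,
        x_bias=0.5 if trial.true_class == "target" else -0.5,
        x_cont=0.5 if trial.task == "superordinate" else -0.5,
    )


def code_trials(trials: pd.DataFrame, experiment: str, model: str) -> pd.DataFrame:
    """Vectorized coding of a trial table.

    ``trials`` has TrialRecord-named columns.  Omitted (response = "none")
    trials are dropped; for RT models only correct responded trials are kept.
    Returns a frame with participant, y (or rt_ms) and the x_* regressors.
    """
    if experiment not in ("exp1", "exp2"):
        raise ValueError(f"unknown experiment {experiment!r}")
    if model not in ("accuracy", "rt"):
        raise ValueError(f"unknown model {model!r}")
    df = trials[trials["response"] != "none"].copy()
    if model == "rt":
        df = df[df["response"] == df["true_class"]]
        if df["rt_ms"].isna().any():
            raise ValueError("correct responded trials must carry an RT")

    is_target = (df["true_class"] == "target").to_numpy()
    out = pd.DataFrame(
        {
            "participant": df["participant"].to_numpy(),
            "y": (df["response"] == "target").astype(int).to_numpy(),
            "x_sens": np.where(is_target, 0.5, -0.5),
        },
        index=df.index,
    )
    if experiment == "exp1":
        ladder = df["discriminability_label"].map(
            lambda v: SLOPE_LADDER.get(round(float(v), 1))
        )
        if ladder.isna().any():
            bad = df.loc[ladder.isna(), "discriminability_label"].unique()
            raise ValueError(f"unknown discriminability labels {bad!r}")
        ladder = ladder.to_numpy(dtype=float)
        out["x_slope"] = ladder if model == "rt" else np.where(is_target, -ladder, ladder)
    else:
        is_sup = (df["task"] == "superordinate").to_numpy()
        if model == "accuracy":
            out["x_cont"] = np.where(is_sup == is_target, 0.25, -0.25)
        else:
            out["x_cont"] = np.where(is_sup, 0.5, -0.5)
    if model == "rt":
        out["x_bias"] = np.where(is_target, 0.5, -0.5)
        out["rt_ms"] = df["rt_ms"].to_numpy(dtype=float)
    return out
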