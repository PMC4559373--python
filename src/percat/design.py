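"""Experiment design from model discriminability.

Three design tools:

* bin stimuli by per-image discriminability and sample a fixed number per bin
  (discriminability-staircased stimulus sets);
* a set-level discriminability: the normalized distance between the decision
  value distributions of target and distractor sets (two-sample d-prime with
  pooled SD);
* a combinatorial search over basic-category combinations to construct a
  condition where superordinate categorization is predicted easier than
  basic, and a condition predicting the reverse.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .boundary import (
    DiscriminabilityRecord,
    TaskDefinition,
    task_accuracy,
    train_eval_task,
)

__all__ = [
    "BIN_LABELS",
    "DiscriminabilityBin",
    "SampledBin",
    "ConditionDesign",
    "ReversalSearchResult",
    "bin_label",
    "assign_bins",
    "bin_and_sample",
    "set_discriminability",
    "reversal_search",
]

#: equal-width bins over [0, 1], labeled by their upper edge
BIN_LABELS: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class DiscriminabilityBin:
    label: float
    lower: float
    upper: float
    member_ids: list[str]


@dataclass
class SampledBin:
    label: float
    ids: tuple[str, ...]
    realized_mean: float  # mean correct_rate of the sampled ids


@dataclass(frozen=True)
class ConditionDesign:
    condition: str  # superordinate_advantage | basic_advantage
    natural_set: tuple[str, ...]
    manmade_set: tuple[str, ...]
    superordinate_discriminability: float
    basic_discriminability: float

    @property
    def advantage(self) -> float:
        """Predicted superordinate-minus-basic discriminability."""
        return self.superordinate_discriminability - self.basic_discriminability


@dataclass
class ReversalSearchResult:
    superordinate_advantage: ConditionDesign
    basic_advantage: ConditionDesign
    table: pd.DataFrame  # every evaluated combination


def bin_label(correct_rate: float) -> float:
    """Bin label for a correct rate: (0, 0.2] -> 0.2, ..., (0.8, 1.0] -> 1.0.

    Rates of exactly 0 join the lowest bin.
    """
    if not (0.0 <= correct_rate <= 1.0):
        raise ValueError(f"correct_rate {correct_rate} outside [0, 1]")
    # 1e-9 guard: k/n ratios like 3/5 must not spill into the next bin
    idx = int(np.ceil(correct_rate * len(BIN_LABELS) - 1e-9)) - 1
    return BIN_LABELS[max(idx, 0)]


def assign_bins(
    records: Iterable[DiscriminabilityRecord],
    class_of: Mapping[str, str] | None = None,
) -> dict:
    """Group records into discriminability bins.

    Keys are bin labels, or (class, label) pairs when ``class_of`` maps image
    ids to a grouping class (e.g. superordinate category).
    """
    width = 1.0 / len(BIN_LABELS)
    bins: dict = {}
    for rec in records:
        label = bin_label(rec.correct_rate)
        key = label if class_of is None else (class_of[rec.image_id], label)
        if key not in bins:
            bins[key] = DiscriminabilityBin(
                label=label, lower=label - width, upper=label, member_ids=[]
            )
        bins[key].member_ids.append(rec.image_id)
    for b in bins.values():
        b.member_ids.sort()
    return bins


def bin_and_sample(
    records: Sequence[DiscriminabilityRecord],
    per_bin: int = 96,
    seed: int = 0,
    exclusion_list: Iterable[str] = (),
    class_of: Mapping[str, str] | None = None,
) -> dict:
    """Sample ``per_bin`` distinct ids uniformly without replacement per bin.

    ``exclusion_list`` models manual inspection: excluded ids are never
    sampled (the uniform draw is over the remaining eligible members, which
    is equivalent to deterministic resampling after exclusion).  Raises,
    naming the bin and shortfall, when a bin is under-populated.
    """
    excluded = set(exclusion_list)
    rate = {r.image_id: r.correct_rate for r in records}
    bins = assign_bins(records, class_of=class_of)
    rng = np.random.default_rng(seed)
    out: dict = {}
    for key in sorted(bins, key=str):
        eligible = [i for i in bins[key].member_ids if i not in excluded]
        if len(eligible) < per_bin:
            raise ValueError(
                f"bin {key} under-populated: {len(eligible)} eligible images "
                f"for per_bin={per_bin} (short {per_bin - len(eligible)})"
            )
        ids = tuple(rng.choice(eligible, size=per_bin, replace=False))
        out[key] = SampledBin(
            label=bins[key].label,
            ids=ids,
            realized_mean=float(np.mean([rate[i] for i in ids])),
        )
    return out


def set_discriminability(
    target_values: Sequence[float], distractor_values: Sequence[float]
) -> float:
    """Normalized distance between target and distractor decision values.

    Two-sample d-prime: |mean(target) - mean(distractor)| / pooled SD.
    Returns +inf when the pooled SD is zero with unequal means, and 0 when
    both samples are degenerate and equal.
    """
    t = np.asarray(target_values, dtype=float)
    d = np.asarray(distractor_values, dtype=float)
    if len(t) < 2 or len(d) < 2:
        raise ValueError("need >= 2 values per set")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(d))):
        raise ValueError("non-finite decision values")
    diff = abs(t.mean() - d.mean())
    pooled_var = ((len(t) - 1) * t.var(ddof=1) + (len(d) - 1) * d.var(ddof=1)) / (
        len(t) + len(d) - 2
    )
    if pooled_var == 0.0:
        return 0.0 if diff == 0.0 else float("inf")
    return float(diff / np.sqrt(pooled_var))


def reversal_search(
    descriptors: Mapping[str, np.ndarray],
    categories: Mapping[str, str],
    natural_pool: Sequence[str],
    manmade_pool: Sequence[str],
    basic_target: str,
    k: int = 3,
    *,
    n_splits: int = 5,
    train_fraction: float = 0.8,
    seed: int = 0,
    c_grid: Sequence[float] | None = None,
) -> ReversalSearchResult:
    """Search basic-category combinations for opposite-advantage conditions.

    Every C(|natural_pool|, k) x C(|manmade_pool|, k) combination defines a
    superordinate task (man-made combination = targets vs. natural
    combination = distractors); each natural combination also defines a basic
    task (``basic_target`` vs. the same natural distractor set).  Each task's
    discriminability is its cross-validated accuracy.  Returns the
    combination maximizing (superordinate - basic) discriminability and the
    one maximizing the reverse, with lexicographic tie-breaking.
    """
    natural_pool = sorted(natural_pool)
    manmade_pool = sorted(manmade_pool)
    if len(natural_pool) < k or len(manmade_pool) < k:
        raise ValueError(f"pools must hold >= k={k} categories")
    if basic_target in natural_pool:
        raise ValueError("basic_target must be distinct from the natural pool")
    kwargs = dict(
        n_splits=n_splits, train_fraction=train_fraction, categories=categories
    )
    if c_grid is not None:
        kwargs["c_grid"] = tuple(c_grid)

    ss = np.random.SeedSequence(seed)
    seed_basic, seed_sup = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))

    nat_combos = list(itertools.combinations(natural_pool, k))
    man_combos = list(itertools.combinations(manmade_pool, k))

    basic_acc: dict[tuple[str, ...], float] = {}
    for i, nat in enumerate(nat_combos):
        task = TaskDefinition(
            name=f"basic:{basic_target}|{'+'.join(nat)}",
            target_categories=frozenset([basic_target]),
            distractor_categories=frozenset(nat),
            level="basic",
        )
        splits = train_eval_task(descriptors, task=task, seed=seed_basic + i, **kwargs)
        basic_acc[nat] = task_accuracy(splits)

    rows = []
    for i, nat in enumerate(nat_combos):
        for j, man in enumerate(man_combos):
            task = TaskDefinition(
                name=f"sup:{'+'.join(man)}|{'+'.join(nat)}",
                target_categories=frozenset(man),
                distractor_categories=frozenset(nat),
                level="superordinate",
            )
            splits = train_eval_task(
                descriptors,
                task=task,
                seed=seed_sup + i * len(man_combos) + j,
                **kwargs,
            )
            sup = task_accuracy(splits)
            rows.append((nat, man, sup, basic_acc[nat], sup - basic_acc[nat]))
    table = pd.DataFrame(
        rows,
        columns=["natural_set", "manmade_set", "superordinate_acc", "basic_acc", "advantage"],
    )

    # argmax / argmin with lexicographic tie-break: rows are already in
    # lexicographic (natural_set, manmade_set) order, first extremum wins
    adv = table["advantage"].to_numpy()
    best = table.iloc[int(np.argmax(adv))]
    worst = table.iloc[int(np.argmin(adv))]

    def _design(row, condition: str) -> ConditionDesign:
        return ConditionDesign(
            condition=condition,
            natural_set=tuple(row["natural_set"]),
            manmade_set=tuple(row["manmade_set"]),
            superordinate_discriminability=float(row["superordinate_acc"]),
            basic_discriminability=float(row["basic_acc"]),
        )

    return ReversalSearchResult(
        superordinate_advantage=_design(best, "superordinate_advantage"),
        basic_advantage=_design(worst, "basic_advantage"),
        table=table,
    )
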