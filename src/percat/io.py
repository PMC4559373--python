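"""Readers and writers for the pipeline's on-disk formats.

Formats: image dataset manifests (CSV: id, path, basic_category,
superordinate_category), descriptor caches (.npy matrix + CSV row index),
trial tables (CSV, TrialRecord columns, tolerant of foreign column names via
a mapping), prediction logs and discriminability tables (CSV), and fit
reports (JSON + text).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .boundary import DiscriminabilityRecord
from .gist import GistDescriptor, ImageStimulus, preprocess

MANIFEST_COLUMNS = ["id", "path", "basic_category", "superordinate_category"]
TRIAL_COLUMNS = [
    "participant", "experiment", "condition", "task", "stimulus_id",
    "true_class", "discriminability_label", "response", "rt_ms", "correct",
]


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns {missing}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate manifest ids: {dupes[:5]}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df[MANIFEST_COLUMNS].to_csv(path, index=False)


def load_images(
    manifest: pd.DataFrame,
    root: str | Path = ".",
    target_mean: float = 128.0,
) -> list[ImageStimulus]:
    """Read and preprocess every image in a manifest (paths relative to root)."""
    import imageio.v3 as iio

    root = Path(root)
    out = []
    errors = []
    for row in manifest.itertuples():
        p = root / row.path
        try:
            raw = iio.imread(p)
        except Exception as exc:
            errors.append(f"{row.id}: unreadable image {p} ({exc})")
            continue
        out.append(
            preprocess(
                raw,
                target_mean,
                id=str(row.id),
                basic_category=str(row.basic_category),
                superordinate_category=str(row.superordinate_category),
            )
        )
    if errors:
        raise ValueError("manifest image errors:\n" + "\n".join(errors))
    return out


def save_descriptors(descriptors: Mapping[str, GistDescriptor], prefix: str | Path) -> None:
    """Cache descriptors as <prefix>.npy plus <prefix>.index.csv (id -> row)."""
    prefix = Path(prefix)
    ids = list(descriptors)
    mat = np.vstack([np.asarray(descriptors[i].values, float) for i in ids])
    np.save(prefix.with_suffix(".npy"), mat)
    pd.DataFrame({"id": ids, "row": range(len(ids))}).to_csv(
        prefix.with_suffix(".index.csv"), index=False
    )


def load_descriptors(prefix: str | Path) -> dict[str, GistDescriptor]:
    prefix = Path(prefix)
    mat = np.load(prefix.with_suffix(".npy"))
    index = pd.read_csv(prefix.with_suffix(".index.csv"))
    return {
        str(r.id): GistDescriptor(values=mat[int(r.row)])
        for r in index.itertuples()
    }


def read_trials(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a trial CSV, renaming foreign columns via ``column_map``.

    ``column_map`` maps source column names to the canonical TrialRecord
    names.  Missing optional columns (discriminability_label, rt_ms, correct)
    are filled with NaN; schema violations are itemized.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    problems = []
    required = ["participant", "experiment", "task", "stimulus_id", "true_class", "response"]
    for c in required:
        if c not in df.columns:
            problems.append(f"missing column {c!r}")
    if problems:
        raise ValueError(f"trial file {path}: " + "; ".join(problems))
    for c in TRIAL_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    bad_resp = ~df["response"].isin(["target", "distractor", "none"])
    if bad_resp.any():
        problems.append(f"unknown response values {df.loc[bad_resp, 'response'].unique()!r}")
    none_with_rt = (df["response"] == "none") & df["rt_ms"].notna()
    if none_with_rt.any():
        problems.append(f"{int(none_with_rt.sum())} omitted trial(s) carry an RT")
    if problems:
        raise ValueError(f"trial file {path}: " + "; ".join(problems))
    return df[TRIAL_COLUMNS]


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    trials[cols].to_csv(path, index=False)


def write_discriminability_table(
    records: Iterable[DiscriminabilityRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            (r.image_id, r.task, r.test_appearances, r.correct_rate, r.mean_decision_value)
            for r in records
        ],
        columns=["image_id", "task", "test_appearances", "correct_rate", "mean_decision_value"],
    ).to_csv(path, index=False)


def read_discriminability_table(path: str | Path) -> list[DiscriminabilityRecord]:
    df = pd.read_csv(path)
    return [
        DiscriminabilityRecord(
            image_id=str(r.image_id),
            task=str(r.task),
            test_appearances=int(r.test_appearances),
            correct_rate=float(r.correct_rate),
            mean_decision_value=float(r.mean_decision_value),
        )
        for r in df.itertuples()
    ]


def write_fit_report(fit, path_json: str | Path, path_txt: str | Path | None = None) -> None:
    """JSON (machine) and text-table (human) reports of a mixed-model fit."""
    payload = {
        "model": fit.model,
        "params": {k: float(v) for k, v in fit.params.items()},
        "se": {k: float(v) for k, v in fit.se.items()},
        "ci": {k: [float(a), float(b)] for k, (a, b) in fit.ci.items()},
        "p": {k: float(v) for k, v in fit.p.items()},
        "random_effect_sds": {k: float(v) for k, v in fit.random_effect_sds.items()},
        "n_mc": fit.n_mc,
        "seed": fit.seed,
        "n_obs": fit.n_obs,
        "n_participants": fit.n_participants,
        "loglik": None if np.isnan(fit.loglik) else float(fit.loglik),
        "converged": bool(fit.converged),
        "separation": bool(fit.separation),
    }
    Path(path_json).write_text(json.dumps(payload, indent=2) + "\n")
    if path_txt is not None:
        Path(path_txt).write_text(fit.summary() + "\n")
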