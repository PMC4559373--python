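"""Run configuration: YAML-backed defaults, validation, and config hashing.

Numeric defaults mirror the study's printed design values: 100 train/test
splits at 80/20, 5-fold inner cross-validation, 96 stimuli per
discriminability bin, combinations of 3 basic categories, 10,000 Monte-Carlo
inference samples, and a 500 ms response deadline.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class RunConfig:
    # paths
    manifest: str | None = None
    trials: str | None = None
    out_dir: str = "percat_out"
    # gist
    gist_scales: int = 4
    gist_orientations: int = 8
    gist_max_frequency: float = 1.0 / 8.0
    gist_bandwidth_factor: float = 0.56
    target_mean: float = 128.0
    boundary_padding: str = "symmetric"
    # boundary model
    n_splits: int = 100
    train_fraction: float = 0.8
    inner_folds: int = 5
    c_grid: list[float] = field(
        default_factory=lambda: [1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3]
    )
    # stimulus design
    per_bin: int = 96
    reversal_k: int = 3
    reversal_n_splits: int = 5
    # behavioral analysis
    glmm_variant: str = "slope"  # slope (staircase) | contrast (level)
    n_mc: int = 10_000
    deadline_ms: float = 500.0
    # reproducibility
    seed: int = 0

    def validate(self, *, need_manifest: bool = False, need_trials: bool = False) -> None:
        problems = []
        if need_manifest:
            if not self.manifest:
                problems.append("manifest path not set")
            elif not Path(self.manifest).exists():
                problems.append(f"manifest {self.manifest} does not exist")
        if need_trials:
            if not self.trials:
                problems.append("trials path not set")
            elif not Path(self.trials).exists():
                problems.append(f"trials file {self.trials} does not exist")
        if not (0 < self.train_fraction < 1):
            problems.append("train_fraction must be in (0, 1)")
        if self.n_splits < 1 or self.per_bin < 1 or self.n_mc < 1:
            problems.append("n_splits, per_bin and n_mc must be positive")
        if self.glmm_variant not in ("slope", "contrast"):
            problems.append(f"unknown glmm_variant {self.glmm_variant!r}")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Config from YAML (optional) with keyword overrides on top."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        unknown = set(loaded) - set(RunConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def config_hash(config: RunConfig) -> str:
    """Short stable digest of the full configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
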