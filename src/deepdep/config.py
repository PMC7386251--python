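"""Run configuration: one YAML file describing a full pipeline run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class RunConfig:
    """Paths, perturbation settings, cutoffs, and seeds for one run.

    Serializes to and from a single YAML file; unknown keys are rejected so
    typos fail loudly instead of being silently ignored.
    """

    network: Optional[str] = None
    reference_expression: Optional[str] = None
    expression: Optional[str] = None
    screen_scores: Optional[str] = None
    variants: Optional[str] = None
    manifest: Optional[str] = None
    output_dir: str = "."
    mode: str = "crispr"  # crispr | rnai
    network_rule: str = "correlation"  # correlation | conditional
    log2p1: bool = False
    cutoffs: dict = field(default_factory=lambda: {"CERES": -1.5, "BAGEL": 4.0, "zGARP": -4.0})
    n_trials: int = 1000
    n_folds: int = 5
    n_features: int = 1000
    patience: int = 200
    seed: int = 0
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if self.mode not in ("crispr", "rnai"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.network_rule not in ("correlation", "conditional"):
            raise ValueError(f"unknown network rule {self.network_rule!r}")

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
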