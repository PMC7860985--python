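"""YAML run configuration for the CLI workflows."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigurationError
from .gmm import COVARIANCE_TYPES

DEFAULT_CHANNELS = ["FSC-H", "SSC-H", "FL1-H"]


@dataclass
class RunConfig:
    """Validated parameters of a fingerprinting run.

    Defaults mirror the reference workflow: K=128 mixtures with full
    covariances on FSC-H/SSC-H/FL1-H, a 128x128 grid for the binning
    comparator, 1,000 Mantel permutations, and a 100-candidate, 5-fold
    randomized forest search.
    """

    channels: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    gate_file: str | None = None
    method: str = "gmm"
    K: int = 128
    covariance_type: str = "full"
    L: int = 128
    n_cells_min: int = 1000
    n_cells_rep: int | None = None
    qs: list[float] = field(default_factory=lambda: [0, 1, 2])
    seed: int = 0
    cofactor: float = 1.0
    mantel_permutations: int = 1000
    rf_candidates: int = 100
    rf_folds: int = 5
    rf_trees: int = 200
    sweep: dict | None = None
    benchmark: dict | None = None  # overrides for the in-silico benchmark scale

    def __post_init__(self):
        if self.method not in ("gmm", "grid"):
            raise ConfigurationError(f"method must be gmm or grid, got {self.method!r}")
        if self.K < 2:
            raise ConfigurationError("K must be >= 2")
        if self.L < 2:
            raise ConfigurationError("L must be >= 2")
        if self.covariance_type not in COVARIANCE_TYPES:
            raise ConfigurationError(
                f"covariance_type must be one of {COVARIANCE_TYPES}"
            )
        if len(self.channels) < 1:
            raise ConfigurationError("at least one channel required")
        if self.gate_file is not None and not os.path.exists(self.gate_file):
            raise ConfigurationError(f"gate file not found: {self.gate_file}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    def digest(self) -> str:
        """Stable hash of the configuration, stamped into run logs."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
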