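"""Run configuration: one object carries every stage parameter.

Every stage consumes its parameters through :class:`RunConfig`; a hash of the
canonical serialized config is embedded in every report so outputs are
traceable to the exact settings that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .pcr import DEFAULT_COVARIATES
from .synth import CohortConfig

CONFIG_SCHEMA_VERSION = 1

__all__ = ["RunConfig", "CONFIG_SCHEMA_VERSION"]


@dataclass
class RunConfig:
    # paths (unused when simulating)
    phenotypes_path: Optional[str] = None
    timeseries_path: Optional[str] = None
    features_path: Optional[str] = None
    atlas_path: Optional[str] = None
    output_dir: str = "gcaconn_output"

    # stage toggles
    simulate: bool = True
    simulate_mode: str = "edges"            # or "timeseries"
    run_permutations: bool = True
    run_cells: bool = True
    run_mediation: bool = True
    run_low_motion: bool = True

    # stage parameters
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    metric: str = "pearson"
    censor_threshold_mm: float = 0.5
    low_motion_fd_mm: float = 0.2
    min_site_n: int = 75
    covariates: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    k_grid: Optional[list] = None
    n_perm: int = 200
    n_perm_cells: int = 1000   # BH over 120 cells needs finer p resolution
    n_splits: int = 20
    n_sims: int = 1000
    schema_version: int = CONFIG_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig(**self.cohort)
        if self.schema_version != CONFIG_SCHEMA_VERSION:
            raise ValueError(
                f"config schema {self.schema_version} unsupported "
                f"(expected {CONFIG_SCHEMA_VERSION})"
            )
        # the cohort generator follows the run seed unless set explicitly
        if self.cohort.seed == 0 and self.seed != 0:
            self.cohort = dataclasses.replace(self.cohort, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
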