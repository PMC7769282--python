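"""Pipeline configuration: explicit seeds, thresholds, replicate counts.

The config round-trips losslessly through YAML/JSON. Replicate counts
default to test-scale values (500); production-scale values (2 x 10^4
permutations, 2,000 bootstrap replicates) are plain config entries.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError
from .evaluate import USE_CASE_TARGETS
from .synthcohort import CohortDesign


@dataclass
class PipelineConfig:
    seed: int | None = None
    output_dir: str = "pe_triage_output"
    input_csv: str | None = None  # case-control CSV replacing the synthetic stage
    n_total: int = 2364
    n_preterm_pe: int = 23
    n_term_pe: int = 74
    n_controls: int = 335
    n_null_metabolites: int = 36
    n_batches: int = 6
    dup_fraction: float = 0.15
    qc_cv_threshold: float = 25.0
    qc_missing_threshold: float = 0.20
    missingness_exceptions: dict[str, str] = field(default_factory=dict)
    one_metric_exceptions: dict[str, str] = field(default_factory=dict)
    B_boot: int = 500
    B_perm: int = 500
    B_eval: int = 500
    targets: dict[str, float] = field(default_factory=lambda: dict(USE_CASE_TARGETS))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed must be set explicitly")
        if not 0.0 <= self.dup_fraction <= 1.0:
            raise ConfigurationError("dup_fraction must be in [0, 1]")
        if self.qc_cv_threshold <= 0 or not 0.0 < self.qc_missing_threshold <= 1.0:
            raise ConfigurationError("invalid QC thresholds")
        if min(self.B_boot, self.B_perm, self.B_eval) < 1:
            raise ConfigurationError("replicate counts must be >= 1")
        for k, v in self.targets.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"use-case target {k} outside [0, 1]")

    @property
    def design(self) -> CohortDesign:
        return CohortDesign(self.n_total, self.n_preterm_pe, self.n_term_pe, self.n_controls)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
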