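"""Run configuration with documented defaults and YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .fitting import FitConfig


@dataclass
class RunConfig:
    """Options for a full pipeline run.

    seed
        master seed for the synthetic generator and fit multi-starts.
    n_chemicals / n_replicates
        synthetic experiment size (chemicals per batch, replicate plates).
    noise_sd
        lognormal sigma of multiplicative well noise.
    dropout_rate
        probability a well is flagged low-quality (dispense failure).
    activity_threshold
        continuous hit-call at or above which a series is positive.
    bmr_factor
        benchmark response = bmr_factor × bmad for BMD derivation.
    auc_grid_points
        log10-concentration grid size for trapezoidal AUC.
    """

    seed: int = 0
    n_chemicals: int = 6
    n_replicates: int = 4
    noise_sd: float = 0.1
    dropout_rate: float = 0.01
    activity_threshold: float = 0.9
    bmr_factor: float = 1.349
    auc_grid_points: int = 100
    n_deterministic_starts: int = 5
    n_random_starts: int = 5

    def fit_config(self) -> FitConfig:
        return FitConfig(
            seed=self.seed,
            n_deterministic_starts=self.n_deterministic_starts,
            n_random_starts=self.n_random_starts,
            bmr_factor=self.bmr_factor,
            activity_threshold=self.activity_threshold,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)
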