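"""Run configuration: one flat YAML file, validated before any computation.

Defaults encode the framework's standard settings (50 balanced epochs,
batch size 250, momentum 0.9, ranking cap 500, 22-day smoothing kernel,
0.01 phenology threshold, 0.15 loess span). Unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Strict):
    size: int = 64
    n_predictors: int = 3
    n_species: int = 30
    n_obs: int = 100_000
    n_sites: int = 300


class FilterSection(_Strict):
    max_uncertainty: float = 100.0
    min_year: int = 1971
    require_date: bool = True


class PartitionSection(_Strict):
    n_test: int = 5
    min_train: int = 20


class NetworkSection(_Strict):
    width: int = 380
    n_blocks: int = 4
    dropout: float = Field(0.2, ge=0.0, lt=1.0)
    preactivation: bool = False


class TrainingSection(_Strict):
    loss: str = "cel"
    ndcg_rank_cap: int = 500
    include_self_pair: bool = True
    phase1_epochs: int = 50
    phase2_max_epochs: int = 100
    early_stop_patience: int = 5
    lr_phase1: float = 1e-2
    lr_phase2: float = 5e-3
    momentum: float = Field(0.9, ge=0.0, lt=1.0)
    batch_size: int = 250
    plateau_factor: float = 0.5
    plateau_patience: int = 3
    min_lr: float = 1e-5


class SeasonSection(_Strict):
    year_length: float = 365.25
    phase: float = 0.0


class PhenologySection(_Strict):
    window: str = "mar_sep"
    kernel: int = 22
    threshold: float = 0.01
    aggregate_factor: int = 8


class DominanceSection(_Strict):
    window: str = "feb_nov"
    day_step: int = 7
    aggregate_factor: int = 8


class ProjectSection(_Strict):
    span: float = 0.15
    scenario: dict = Field(default_factory=dict)


class RunConfig(_Strict):
    """All knobs of a run; per-stage sections with field-level defaults."""

    seed: int = 0
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    filter: FilterSection = Field(default_factory=FilterSection)
    partition: PartitionSection = Field(default_factory=PartitionSection)
    network: NetworkSection = Field(default_factory=NetworkSection)
    training: TrainingSection = Field(default_factory=TrainingSection)
    season: SeasonSection = Field(default_factory=SeasonSection)
    phenology: PhenologySection = Field(default_factory=PhenologySection)
    dominance: DominanceSection = Field(default_factory=DominanceSection)
    project: ProjectSection = Field(default_factory=ProjectSection)
    cover_translation: dict | None = None


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; ``overrides`` are top-level keys."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    if overrides:
        for key, value in overrides.items():
            if "." in key:
                section, name = key.split(".", 1)
                data.setdefault(section, {})[name] = value
            else:
                data[key] = value
    return RunConfig.model_validate(data)
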