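"""Declarative run configuration (YAML) with strict schema validation.

Unknown keys are rejected so a typo cannot silently change an experiment;
the fully-resolved configuration is embedded in every run manifest.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .sequencing import SequencingConfig
from .training import TrainConfig

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StudyConfig(_Strict):
    n_participants: int = 1
    n_trials: int = 40
    seconds: float = 63.0
    fs: float = 128.0
    n_channels: int = 32
    noise_uv: float = 2.0
    mode: str = "noise"


class SequencingSection(_Strict):
    window_seconds: float = 2.0
    shift_seconds: float = 0.125
    sequence_length: int = 7

    def build(self) -> SequencingConfig:
        return SequencingConfig(self.window_seconds, self.shift_seconds, self.sequence_length)


class BrainRateSection(_Strict):
    mode: str = "sum_channels"
    variant: str = "mean_ratio"


class TopomapSection(_Strict):
    fill_value: float = 0.0


class ModelSection(_Strict):
    padding: str = "same"
    lstm_units: int = 128
    peephole: bool = False
    side_kernel: int = 3
    side_filters: int = 64


class TrainingSection(_Strict):
    learning_rate: float = 1e-3
    batch_size: int = 32
    patience: int = 6
    max_epochs: int = 60
    standardize_targets: bool = False
    standardize_inputs: bool = False

    def build(self, seed: int) -> TrainConfig:
        return TrainConfig(learning_rate=self.learning_rate, batch_size=self.batch_size,
                           patience=self.patience, max_epochs=self.max_epochs, seed=seed,
                           standardize_targets=self.standardize_targets,
                           standardize_inputs=self.standardize_inputs)


class ExperimentSection(_Strict):
    kind: str = "within"
    arch: str = "cnn_lstm"
    n_people: int = 1
    repetitions: int = 1
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)


class RunConfig(_Strict):
    """Top-level run configuration; every section has faithful defaults."""

    seed: int = 0
    output_dir: str = "runs"
    study: StudyConfig = Field(default_factory=StudyConfig)
    sequencing: SequencingSection = Field(default_factory=SequencingSection)
    brain_rate: BrainRateSection = Field(default_factory=BrainRateSection)
    topomap: TopomapSection = Field(default_factory=TopomapSection)
    model: ModelSection = Field(default_factory=ModelSection)
    training: TrainingSection = Field(default_factory=TrainingSection)
    experiment: ExperimentSection = Field(default_factory=ExperimentSection)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run configuration (defaults when path is None)."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)
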