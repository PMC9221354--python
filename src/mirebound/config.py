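"""Pipeline configuration: a validated, serializable run description."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = ["PipelineConfig", "load_config"]


class PipelineConfig(BaseModel):
    """Fully resolved configuration of one pipeline run.

    Validated at construction; every run writes the resolved config next to
    its outputs so results are reproducible from the artifact alone.
    """

    task: Literal["me_vs_mi", "left_vs_right", "followup"] = "followup"
    channels: list[str] = Field(
        default_factory=lambda: ["C3", "Cz", "C4", "FC1", "FC2", "CP1", "CP2"]
    )
    band: tuple[float, float] = (13.0, 40.0)
    epoch_window: tuple[float, float] = (-1.0, 4.0)
    reference_interval: tuple[float, float] = (-1.0, -0.1)
    feature_window: tuple[float, float] = (0.25, 2.75)
    search_window: tuple[float, float] = (0.0, 3.0)
    smooth_window: float = 0.25
    min_amplitude: float = 10.0
    min_magnitude: float = 12.0
    followup_channel: str = "Cz"
    cv_folds: int = 10
    optimize_svm: bool = False
    slr_variant: Literal["slr-lap", "slr-var", "l1-slr-lap", "l1-slr-comp", "none"] = (
        "none"
    )
    n_subjects: int = 10
    n_motions: int = 6
    n_trials: int = 40
    fs: float = 250.0
    seed: int = 0
    input_path: str | None = None  # sidecar/BrainVision input; None = synthetic
    output_dir: str = "mirebound_out"

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if self.band[0] >= self.band[1]:
            raise ValueError("band must be (low, high) with low < high")
        if self.fs <= 2 * self.band[1]:
            raise ValueError("fs must exceed twice the upper band edge")
        if self.epoch_window[0] >= 0:
            raise ValueError("epoch window must start before the stimulus")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        return self

    def resolved_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True, indent=1, default=list)


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load a YAML or JSON config file, applying keyword overrides."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    data.update(overrides)
    return PipelineConfig(**data)
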