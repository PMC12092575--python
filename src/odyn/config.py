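"""Validated run configuration and the reproducibility manifest.

The YAML configuration mirrors the pipeline's stages; every default is the
pipeline's reference setting (512 px patches with 256 px overlap at
0.5 mpp for scoring, IDaRS k=5/r=45 with batch 256 and dropout 0.2,
5-fold × 3-repeat patient-grouped CV, 96-month censor horizon), so a
minimal or empty config reproduces the reference protocol.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class SynthSection(BaseModel):
    n_patients: int = 20
    n_controls: int = 8
    slides_per_patient: int = 1
    canvas_size: int = Field(1536, ge=512)
    mask_mpp: float = Field(0.5, gt=0)
    transform_fraction: float = Field(0.5, ge=0, le=1)
    nuclear_effect: float = Field(1.0, ge=0)
    censor_rate: float = Field(0.1, ge=0, le=1)


class TessellationSection(BaseModel):
    patch_size: int = Field(512, ge=32)
    overlap: int = Field(256, ge=0)
    target_mpp: float = Field(0.5, gt=0)
    min_coverage: float = Field(0.5, ge=0, le=1)

    @model_validator(mode="after")
    def _overlap_lt_patch(self):
        if self.overlap >= self.patch_size:
            raise ValueError(
                f"overlap ({self.overlap}) must be < patch_size ({self.patch_size})"
            )
        return self


class TrainSection(BaseModel):
    k: int = Field(5, ge=0)
    r: int = Field(45, ge=0)
    batch_size: int = Field(256, ge=1)
    learning_rate: float = Field(1e-3, gt=0)
    epochs: int = Field(50, ge=1)
    sce_alpha: float = Field(1.0, ge=0)
    sce_beta: float = Field(1.0, ge=0)
    log_clamp: float = Field(-4.0, lt=0)
    dropout: float = Field(0.2, ge=0, lt=1)

    @model_validator(mode="after")
    def _at_least_one_draw(self):
        if self.k + self.r < 1:
            raise ValueError("k + r must be >= 1")
        return self


class CVSection(BaseModel):
    n_folds: int = Field(5, ge=2)
    n_repeats: int = Field(3, ge=1)
    val_fraction: float = Field(0.1, gt=0, lt=1)


class EvaluateSection(BaseModel):
    risk_cutoff: float = Field(0.5, ge=0, le=1)
    censor_horizon_months: float = Field(96.0, gt=0)


class RunConfig(BaseModel):
    """Top-level validated configuration for the whole pipeline."""

    seed: int = 0
    synth: SynthSection = SynthSection()
    tessellation: TessellationSection = TessellationSection()
    train: TrainSection = TrainSection()
    cv: CVSection = CVSection()
    evaluate: EvaluateSection = EvaluateSection()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Snapshot of everything needed to reproduce a run bit-for-bit."""

    def __init__(self, config: RunConfig, stage: str):
        from odyn import __version__

        self.data = {
            "stage": stage,
            "version": __version__,
            "config": config.model_dump(),
            "seeds": {"root": config.seed},
            "inputs": {},
            "created": datetime.now(timezone.utc).isoformat(),
        }

    def add_input(self, name: str, path: str | Path) -> None:
        self.data["inputs"][name] = {"path": str(path), "sha256": file_digest(path)}

    def add_seed(self, name: str, value: int) -> None:
        self.data["seeds"][name] = int(value)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1)
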