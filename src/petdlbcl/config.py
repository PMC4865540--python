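"""Pipeline configuration (schema-validated; unknown keys rejected)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .model import Cutoffs

__all__ = ["PipelineConfig", "load_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SegmentationOptions(_Strict):
    threshold: float = Field(2.5, gt=0, description="SUV threshold (inclusive)")
    mode: Literal["fixed", "pct41"] = "fixed"
    fraction: float = Field(0.41, gt=0, lt=1)
    min_voxels: int = Field(1, ge=1)


class ScoringOptions(_Strict):
    improvement_rule: Literal["delta_suvmax"] = "delta_suvmax"


class CutoffOptions(_Strict):
    mtv0: float = 400.0
    tlg0: float = 4500.0
    mtv2: float = 1.8
    tlg2: float = 5.6
    suvmax2: float = 3.0
    delta_suvmax: float = -66.0
    delta_mtv: float = -99.8
    delta_tlg: float = -99.9
    mtd_bulk: float = 10.0
    ipi_split: int = 2
    ds_split: int = 3

    def to_cutoffs(self) -> Cutoffs:
        return Cutoffs(**self.model_dump())


class SurvivalOptions(_Strict):
    tie_method: Literal["efron"] = "efron"
    landmark_years: float = Field(5.0, gt=0)


class SimulationOptions(_Strict):
    cohort_n: int = Field(147, ge=4)
    phantom_noise_sd: float = Field(0.05, ge=0)
    phantom_blur_fwhm: float = Field(6.0, ge=0)


class PipelineConfig(_Strict):
    segmentation: SegmentationOptions = SegmentationOptions()
    scoring: ScoringOptions = ScoringOptions()
    cutoffs: CutoffOptions = CutoffOptions()
    survival: SurvivalOptions = SurvivalOptions()
    simulation: SimulationOptions = SimulationOptions()
    grouping: Literal["mtv_ds", "mtv_dsuv", "tlg_ds", "ipi_ds"] = "mtv_ds"
    seed: int = 0


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML or JSON config file; ``None`` returns the defaults."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    payload = yaml.safe_load(path.read_text()) or {}
    return PipelineConfig.model_validate(payload)


def config_hash(config: PipelineConfig) -> str:
    """Stable hash of the canonical JSON form (recorded in all outputs)."""
    canonical = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
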