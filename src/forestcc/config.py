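"""Run configuration: a validated, losslessly serialisable parameter block.

Unknown keys are rejected by name, so a typo in a config file fails loudly
instead of silently running with a default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .accounting import CHINA_LAND_AREA_KM2


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Strict):
    rows: int = 60
    cols: int = 60
    pixel_size_m: float = 500.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    year_start: int = 2000
    year_end: int = 2013


class SceneConfig(_Strict):
    mix: dict[str, float] = Field(
        default_factory=lambda: {
            "stable_forest": 0.45,
            "stable_nonforest": 0.25,
            "abrupt_loss": 0.10,
            "gradual_gain": 0.15,
            "loss_then_recovery": 0.05,
        }
    )
    loss_magnitude: float = 0.8
    gain_magnitude: float = 0.7
    ramp_rate: float = 0.07
    nbr_level_forest: float = 0.60
    nbr_level_bare: float = 0.05
    nbr_sigma: float = 0.02
    lc_flip_prob: float = 0.05
    vcf_refine_factor: int = 2
    vcf_sigma_pct: float = 3.0
    gfc_refine_factor: int = 8
    province_rows: int = 2
    province_cols: int = 2


class DetectorConfig(_Strict):
    forest_threshold: float = 0.4
    change_threshold: float = 0.15
    max_segments: int = 4
    despike_threshold: float = 0.5
    mse_improvement_min: float = 0.01
    mask_filters_gain: bool = False


class WindowsConfig(_Strict):
    lc_t1: tuple[int, int] = (2001, 2003)
    lc_t2: tuple[int, int] = (2010, 2012)
    vcf_t1: tuple[int, int] = (2000, 2002)
    vcf_t2: tuple[int, int] = (2011, 2013)


class RunConfig(_Strict):
    grid: GridConfig = Field(default_factory=GridConfig)
    scene: SceneConfig = Field(default_factory=SceneConfig)
    detector: DetectorConfig = Field(default_factory=DetectorConfig)
    windows: WindowsConfig = Field(default_factory=WindowsConfig)
    land_area_km2: float = CHINA_LAND_AREA_KM2
    seed: int = 0
    output_dir: str = "out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
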