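"""Pipeline configuration: one JSON-serializable object covering every
stage, validated with pydantic. Every random operation derives from the
explicit ``seed``."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, Field, field_validator

from .analysis import AnalysisConfig
from .features import FeatureSettings
from .synthetic import CohortConfig, LesionEffect

__all__ = ["PipelineConfig"]


class PipelineConfig(BaseModel):
    """Settings for the simulate -> maps -> extract -> stats pipeline."""

    seed: int = 0
    # synthetic cohort
    counts: dict[str, int] = Field(
        default_factory=lambda: {
            "n_noPCa_PZ": 25, "n_noPCa_TZ": 8, "n_ciPCa_PZ": 4,
            "n_ciPCa_TZ": 4, "n_csPCa_PZ": 8, "n_csPCa_TZ": 3,
        }
    )
    image_shape: tuple[int, int, int] = (96, 96, 16)
    spacing: tuple[float, float, float] = (0.5, 0.5, 3.0)
    lesion_median_shift: float = 1.2
    lesion_contrast: float = 0.8
    # map engine
    cell_size: tuple[float, float, float] = (2.0, 2.0, 3.0)
    bin_width: float = 25.0
    bin_count: int | None = None
    gldm_alpha: int = 0
    overlap_threshold: float = 0.5
    # statistics
    alpha: float = 0.05
    ridge: float = 0.01
    bootstrap_n: int = 1000
    psad_cutoffs: tuple[float, float] = (0.15, 0.20)
    strata: tuple[str, ...] = ("all", "PZ", "TZ")

    @field_validator("spacing", "cell_size")
    @classmethod
    def _positive(cls, v):
        if any(x <= 0 for x in v):
            raise ValueError("must be strictly positive")
        return v

    @field_validator("psad_cutoffs")
    @classmethod
    def _cutoffs(cls, v):
        if tuple(v) != (0.15, 0.20):
            raise ValueError("PSAD cutoffs are fixed at 0.15 and 0.20 (ng/mL)/cm^3")
        return v

    # ------------------------------------------------------------------
    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            **self.counts,
            lesion_effect=LesionEffect(
                median_shift=self.lesion_median_shift, contrast=self.lesion_contrast
            ),
            image_shape=tuple(self.image_shape),
            spacing=tuple(self.spacing),
            seed=self.seed,
        )

    def feature_settings(self) -> FeatureSettings:
        return FeatureSettings(
            bin_width=self.bin_width, bin_count=self.bin_count, gldm_alpha=self.gldm_alpha
        )

    def analysis_config(self) -> AnalysisConfig:
        return AnalysisConfig(
            alpha=self.alpha,
            strata=tuple(self.strata),
            ridge=self.ridge,
            bootstrap_n=self.bootstrap_n,
            seed=self.seed,
        )

    # ------------------------------------------------------------------
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        ).hexdigest()[:12]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.model_dump(mode="json"), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    @classmethod
    def json_schema_text(cls) -> str:
        return json.dumps(cls.model_json_schema(), indent=2)
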