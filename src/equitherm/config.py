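"""Pipeline configuration: a strict, file-round-trippable model.

The YAML config has ``design``, ``effect``, ``color``, ``glcm``,
``texture`` and ``stats`` sections plus ``seed`` and ``out_dir``.
Unknown keys are rejected before any computation runs.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .color import NORMALIZATION_KINDS
from .synthetic import EffectModel, StudyDesign
from .texture import ALL_FAMILIES, GLCMConfig, TextureConfig


class ColorConfig(BaseModel):
    model_config = {"extra": "forbid"}

    bit_depth: int = Field(default=8, ge=2, le=8)
    glcm_bit_depth: int = Field(default=6, ge=2, le=8)
    normalized_variant: str = "minmax"

    @field_validator("normalized_variant")
    @classmethod
    def _known_kind(cls, v: str) -> str:
        if v not in NORMALIZATION_KINDS or v == "none":
            raise ValueError(
                f"normalized_variant must be one of "
                f"{[k for k in NORMALIZATION_KINDS if k != 'none']}"
            )
        return v


class GlcmSection(BaseModel):
    model_config = {"extra": "forbid"}

    distances: tuple[int, ...] = tuple(range(1, 10))
    log_base: str = "e"
    per_offset: bool = False


class TextureSection(BaseModel):
    model_config = {"extra": "forbid"}

    families: tuple[str, ...] = ALL_FAMILIES

    @field_validator("families")
    @classmethod
    def _known_families(cls, v):
        unknown = set(v) - set(ALL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown texture families {sorted(unknown)}")
        return tuple(v)


class StatsSection(BaseModel):
    model_config = {"extra": "forbid"}

    alpha: float = Field(default=0.05, gt=0, lt=1)
    alpha_nonzero: float = Field(default=0.05, gt=0, lt=1)
    scale_align: str = "match_moments"
    bh_correction: bool = False
    targets: tuple[str, ...] = ("WBC", "CPK", "AST")

    @field_validator("scale_align")
    @classmethod
    def _known_align(cls, v: str) -> str:
        if v not in ("match_moments", "raw"):
            raise ValueError("scale_align must be 'match_moments' or 'raw'")
        return v


class PipelineConfig(BaseModel):
    model_config = {"extra": "forbid"}

    design: StudyDesign = StudyDesign()
    effect: EffectModel = EffectModel()
    color: ColorConfig = ColorConfig()
    glcm: GlcmSection = GlcmSection()
    texture: TextureSection = TextureSection()
    stats: StatsSection = StatsSection()
    seed: int = 0
    out_dir: str = "results/run"

    def with_seed(self, seed: int | None) -> "PipelineConfig":
        if seed is None:
            return self
        data = self.model_dump()
        data["seed"] = seed
        data["design"]["seed"] = seed
        return PipelineConfig.model_validate(data)

    def texture_config(self) -> TextureConfig:
        return TextureConfig(
            families=self.texture.families,
            glcm=GLCMConfig(
                distances=self.glcm.distances,
                log_base=self.glcm.log_base,
                bit_depth=self.color.glcm_bit_depth,
            ),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        cfg = cls.model_validate(data)
        if "seed" in data and "design" in data and "seed" not in data["design"]:
            cfg = cfg.with_seed(data["seed"])
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text())
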