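"""Run configuration: one YAML file with stage-addressable parameter blocks.

Every stage of every pipeline variant can be re-parameterized by name, which
is how misbehaving registrations are tweaked in practice (optimizer choice,
step scale ``sp_a``, blurring schedule, pre-blur).  CLI flags override the
config file values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import PipelineConfig, default_pipeline_config
from .registration import RegistrationParams

__all__ = ["RunConfig", "params_to_dict", "params_from_dict",
           "pipeline_config_from_spec"]


def params_to_dict(p: RegistrationParams) -> dict:
    d = asdict(p)
    d["pyramid_schedule"] = list(p.pyramid_schedule)
    return d


def params_from_dict(d: dict) -> RegistrationParams:
    d = dict(d)
    if "pyramid_schedule" in d:
        d["pyramid_schedule"] = tuple(d["pyramid_schedule"])
    return RegistrationParams(**d)


def pipeline_config_from_spec(variant: str, overrides: dict | None = None,
                              speed: str = "fast", seed: int = 0) -> PipelineConfig:
    """Default stage plan for ``variant`` with per-stage override blocks.

    ``overrides`` maps stage names (e.g. ``affine_0``, ``rigid``,
    ``bspline_2``) to partial RegistrationParams field dicts.
    """
    cfg = default_pipeline_config(variant, speed=speed, seed=seed)
    for stage, block in (overrides or {}).items():
        if stage not in cfg.stage_params:
            raise KeyError(f"unknown stage {stage!r} for variant {variant!r}")
        cfg.stage_params[stage] = cfg.stage_params[stage].with_(**block)
    return cfg


@dataclass
class RunConfig:
    """End-to-end run description (paths, orientations, QC rule, seeds)."""

    input_dir: str = "."
    output_dir: str = "out"
    model_template: str = ""
    model_mask: str = ""
    age_group: str = ""
    target_orientation: str = "Left"
    orientation: dict = field(default_factory=dict)  # scan filename -> label
    speed: str = "fast"
    seed: int = 0
    qc_rule: str = "fraction_of_mean"
    qc_threshold: float = 0.10
    similarity_floor: float = 0.7
    pipelines: dict = field(default_factory=dict)  # variant -> stage overrides

    def __post_init__(self) -> None:
        if self.qc_threshold <= 0 or self.similarity_floor <= 0:
            raise ValueError("QC thresholds must be positive")

    # -- serialization -----------------------------------------------------
    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return RunConfig(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
        return path

    # -- derived objects ---------------------------------------------------
    def pipeline_config(self, variant: str) -> PipelineConfig:
        return pipeline_config_from_spec(
            variant, self.pipelines.get(variant), speed=self.speed,
            seed=self.seed)

    def validate_paths(self) -> None:
        for label, p in (("input_dir", self.input_dir),
                         ("model_template", self.model_template),
                         ("model_mask", self.model_mask)):
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{label}: no such path {p}")
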