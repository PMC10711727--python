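"""Pipeline configuration: one validated object covering every stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .first_order import FDR_FAMILIES
from .synth import GeneratorConfig

__all__ = ["PipelineConfig"]

RDM_METHODS = ("pearson", "spearman")
SECOND_ORDER_TESTS = ("parametric", "permutation")
ZERO_METHODS = ("wilcox", "pratt")
LOG_LEVELS = ("DEBUG", "INFO", "WARNING", "ERROR")


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, validated against closed enum sets.

    Paths may be None, in which case the corresponding inputs are simulated
    from the generator block. The seed feeds every random stage and is
    echoed in all output metadata.
    """

    patterns_path: str | None = None
    ratings_path: str | None = None
    design_path: str | None = None
    output_dir: str = "rsa_output"
    alpha: float = 0.05
    fdr_family: str = "per_model_phase"
    rdm_method: str = "pearson"
    zscore_voxels: bool = False
    wilcoxon_zero_method: str = "wilcox"
    second_order_test: str = "parametric"
    second_order_permutations: int = 10_000
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.fdr_family not in FDR_FAMILIES:
            raise ValueError(f"fdr_family must be one of {FDR_FAMILIES}")
        if self.rdm_method not in RDM_METHODS:
            raise ValueError(f"rdm_method must be one of {RDM_METHODS}")
        if self.second_order_test not in SECOND_ORDER_TESTS:
            raise ValueError(f"second_order_test must be one of {SECOND_ORDER_TESTS}")
        if self.wilcoxon_zero_method not in ZERO_METHODS:
            raise ValueError(f"wilcoxon_zero_method must be one of {ZERO_METHODS}")
        if self.log_level not in LOG_LEVELS:
            raise ValueError(f"log_level must be one of {LOG_LEVELS}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        # the seed is reused for the generator unless one was set explicitly
        if self.generator.seed == 0 and self.seed != 0:
            object.__setattr__(self, "generator",
                               GeneratorConfig(**{**self._generator_dict(), "seed": self.seed}))

    def _generator_dict(self) -> dict:
        g = self.generator
        return {
            "n_subjects": g.n_subjects,
            "rois": g.rois,
            "phases": g.phases,
            "n_voxels": g.n_voxels,
            "planted_weights": g.planted_weights,
            "subject_sd": g.subject_sd,
            "voxel_sd": g.voxel_sd,
            "rating_baseline": g.rating_baseline,
            "rating_weights": dict(g.rating_weights),
            "rating_sd": g.rating_sd,
            "rating_integer": g.rating_integer,
            "seed": g.seed,
        }

    def to_yaml(self) -> str:
        d = {
            "patterns_path": self.patterns_path,
            "ratings_path": self.ratings_path,
            "design_path": self.design_path,
            "output_dir": self.output_dir,
            "alpha": self.alpha,
            "fdr_family": self.fdr_family,
            "rdm_method": self.rdm_method,
            "zscore_voxels": self.zscore_voxels,
            "wilcoxon_zero_method": self.wilcoxon_zero_method,
            "second_order_test": self.second_order_test,
            "second_order_permutations": self.second_order_permutations,
            "generator": yaml.safe_load(self.generator.to_yaml()),
            "seed": self.seed,
            "log_level": self.log_level,
        }
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        gen = d.pop("generator", None)
        if gen is not None:
            d["generator"] = GeneratorConfig.from_yaml(yaml.safe_dump(gen))
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text())
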