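"""Run configuration: YAML schema, validation, logging setup.

A run is described by one YAML file (overridable by CLI flags) naming the
input paths, the learners, the stage-1/stage-2 controls, the evaluation
grid and the seed. Validation aggregates *all* problems into a single
error so a user fixes the file once, not field by field.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .learners import LEARNER_IDS
from .modules import ModuleGridConfig
from .stage1 import Stage1Config
from .stage2 import PipelineConfig

log = logging.getLogger("pathstack")


class ConfigError(ValueError):
    """Aggregated configuration problems (user error)."""


@dataclass
class RunConfig:
    omics: str = ""
    labels: str = ""
    gene_sets: str = ""
    annotation: str = ""
    ancestry: str = ""
    output_dir: str = "pathstack_out"
    root_term: str = "GO:ROOT"

    stage1_learner: str = "ridge"
    stage2_learner: str = "ridge"
    B: int = 5
    n_folds: int = 5
    cutoff: float = 0.3
    fallback_k: int = 10
    resampling: str = "cv"
    top_n: int | None = None  # None: select from the grid by CV
    stage2_cutoff: float = 0.8
    unmapped_mode: str = "all"

    min_genes: int = 20
    max_genes: int = 200
    min_features: int = 10

    eval_k: int = 5
    eval_r: int = 10
    beta: float = 6.0
    min_module_sizes: list = field(default_factory=lambda: [5, 10, 15])
    merge_cut_heights: list = field(default_factory=lambda: [0.1, 0.2, 0.3])
    module_alpha: float = 0.05
    min_fraction: float = 0.5

    seed: int = 0
    workers: int = 1

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self, *, need_inputs: bool = True) -> None:
        problems: list[str] = []
        if need_inputs:
            for name in ("omics", "labels", "gene_sets", "annotation"):
                p = getattr(self, name)
                if not p:
                    problems.append(f"missing required path: {name}")
                elif not Path(p).exists():
                    problems.append(f"{name} file not found: {p}")
            if self.ancestry and not Path(self.ancestry).exists():
                problems.append(f"ancestry file not found: {self.ancestry}")
        for name in ("stage1_learner", "stage2_learner"):
            if getattr(self, name) not in LEARNER_IDS:
                problems.append(f"{name} {getattr(self, name)!r} not in {sorted(LEARNER_IDS)}")
        if self.B < 1:
            problems.append("B must be >= 1")
        if not (0 <= self.cutoff < 1):
            problems.append("cutoff must be in [0, 1)")
        if self.fallback_k < 1:
            problems.append("fallback_k must be >= 1")
        if self.top_n is not None and self.top_n < 0:
            problems.append("top_n must be >= 0")
        if not (0 < self.stage2_cutoff <= 1):
            problems.append("stage2_cutoff must be in (0, 1]")
        if self.unmapped_mode not in ("strict", "all"):
            problems.append("unmapped_mode must be 'strict' or 'all'")
        if self.min_genes <= 0 or self.min_genes > self.max_genes:
            problems.append("require 0 < min_genes <= max_genes")
        if self.eval_k < 2 or self.eval_r < 1:
            problems.append("require eval_k >= 2 and eval_r >= 1")
        if not self.min_module_sizes or not self.merge_cut_heights:
            problems.append("module grids must be nonempty")
        if any(not (0 < h < 1) for h in self.merge_cut_heights):
            problems.append("merge_cut_heights must lie in (0, 1)")
        if problems:
            raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(problems))

    def stage1_config(self) -> Stage1Config:
        return Stage1Config(B=self.B, n_folds=self.n_folds, cutoff=self.cutoff,
                            fallback_k=self.fallback_k, seed=self.seed,
                            resampling=self.resampling)

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(stage1=self.stage1_config(), top_n=self.top_n,
                              stage2_cutoff=self.stage2_cutoff,
                              unmapped_mode=self.unmapped_mode)

    def module_grid(self) -> ModuleGridConfig:
        return ModuleGridConfig(beta=self.beta,
                                min_module_sizes=tuple(self.min_module_sizes),
                                merge_cut_heights=tuple(self.merge_cut_heights),
                                seed=self.seed)

    def echo(self) -> dict:
        return asdict(self)


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
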