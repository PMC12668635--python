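"""Pipeline configuration with validation and YAML/JSON loading."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .classification import ClassifierConfig
from .embedding import GATConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """All tunables of a pipeline run.

    File paths are optional so the pipeline can also be driven fully
    in memory (e.g. from the simulator); when given, they are checked at
    validation time.
    """

    expr_dir: str | None = None
    prior_path: str | None = None
    pathway_path: str | None = None
    out_dir: str | None = None
    states: list[str] = field(default_factory=list)
    normal_state: str | None = None  # DEG reference; None skips DEG filtering
    alpha: float = 0.3
    epsilon: float = 1e-2
    cmi_threshold: float = 0.03
    cmi_max_order: int = 1
    lfc_min: float = 1.0
    p_max: float = 0.05
    fallback_fraction: float = 0.15
    pagerank_damping: float = 0.85
    gat: GATConfig = field(default_factory=GATConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    append_pca_features: int = 0  # >0 appends that many all-gene PCs
    seed: int = 0

    def validate(self, require_paths: bool = False) -> None:
        if len(self.states) < 2:
            raise ValueError("state order must list at least 2 states")
        for name, val in (("alpha", self.alpha),
                          ("fallback_fraction", self.fallback_fraction)):
            if not (0 <= val <= 1):
                raise ValueError(f"{name}={val} out of [0, 1]")
        if not (0 < self.fallback_fraction < 1):
            raise ValueError("fallback_fraction must be in (0, 1)")
        if self.epsilon <= 0 or self.cmi_threshold <= 0:
            raise ValueError("epsilon and cmi_threshold must be positive")
        if not (0 < self.pagerank_damping < 1):
            raise ValueError("pagerank_damping must be in (0, 1)")
        if self.normal_state is not None and self.normal_state not in self.states:
            raise ValueError("normal_state must be one of the declared states")
        if require_paths:
            for label in ("expr_dir", "prior_path"):
                p = getattr(self, label)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{label} missing or does not exist: {p}")
            if self.pathway_path is not None and not Path(self.pathway_path).exists():
                raise FileNotFoundError(f"pathway_path does not exist: {self.pathway_path}")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> PipelineConfig:
    """Load a PipelineConfig from YAML or JSON."""
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    gat = GATConfig(**raw.pop("gat", {}))
    clf = ClassifierConfig(**{k: tuple(v) if k == "hidden" else v
                              for k, v in raw.pop("classifier", {}).items()})
    return PipelineConfig(gat=gat, classifier=clf, **raw)
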