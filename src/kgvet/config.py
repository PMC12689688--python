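"""Run configuration: defaults ← YAML config file ← CLI flags.

Every knob that changes a number in a report lives here, and the fully
resolved configuration is embedded verbatim in every report so results are
reproducible from the report file alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

__all__ = ["EmbeddingConfig", "ResourceConfig", "RunConfig"]


@dataclass(frozen=True)
class EmbeddingConfig:
    backend: str = "mock"        # mock | planted | transformer
    dimension: int = 32
    seed: int = 0
    model_name: str | None = None  # transformer only
    normalized: bool = False       # L2-normalize vectors before scoring


@dataclass(frozen=True)
class ResourceConfig:
    damping: float = 0.85
    tolerance: float = 1e-8
    max_iterations: int = 500
    max_hops: int = 3
    edge_scope: str = "union"      # union | hierarchy_only
    combiner: str = "mean"         # mean | min
    dangling: str = "as_printed"   # as_printed | redistribute


@dataclass(frozen=True)
class RunConfig:
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    resource: ResourceConfig = field(default_factory=ResourceConfig)
    #: per-component acceptance thresholds; a triple is accepted when every
    #: component score clears its threshold and the triple is not flagged.
    thresholds: dict = field(
        default_factory=lambda: {"semantic": 0.75, "type": 0.75, "resource": 0.75}
    )
    sd_ddof: int = 1               # 1 = sample SD (default), 0 = population SD
    per_concept_normalization: bool = False
    dedupe: bool = False
    combination_rule: str = "conjunctive"  # conjunctive | weighted_average

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        emb = EmbeddingConfig(**data.pop("embedding", {}) or {})
        res = ResourceConfig(**data.pop("resource", {}) or {})
        return cls(embedding=emb, resource=res, **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def override(self, **kwargs) -> "RunConfig":
        """Return a copy with top-level fields replaced (flag precedence)."""
        return replace(self, **kwargs)
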