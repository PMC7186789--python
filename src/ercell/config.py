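"""Pipeline configuration: the published thresholds, overridable per run."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path


@dataclass
class PipelineConfig:
    """Every numeric threshold of the pipeline, with its conventional default.

    min_detected: cells below this detected-gene count are removed (200).
    ratio_ceiling: genes with dN/dS above this are discarded (2).
    alpha: significance level for adjusted p-values (0.05).
    adjust_method: multiple-testing adjustment (BH).
    n_perm: permutation replicates for the subtype null (10000).
    young_branch_threshold: phylogenetic branch at/above which a gene is
        "young" (8, i.e. lineage-specific).
    fc_threshold: fold-change bound for upregulated genes, strict (2).
    depth_fit: "pooled" or "per_stage" depth correction in trajectories.
    seed: master RNG seed for every stochastic step.
    """

    min_detected: int = 200
    ratio_ceiling: float = 2.0
    alpha: float = 0.05
    adjust_method: str = "BH"
    n_perm: int = 10_000
    young_branch_threshold: int = 8
    fc_threshold: float = 2.0
    depth_fit: str = "pooled"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("min_detected", "ratio_ceiling", "n_perm",
                     "young_branch_threshold", "fc_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.depth_fit not in ("pooled", "per_stage"):
            raise ValueError("depth_fit must be 'pooled' or 'per_stage'")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Flat ``key = value`` text file; ``#`` starts a comment."""
        values: dict = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise ValueError(f"unknown config key: {key!r}")
            values[key] = casts[types[key]](val)
        values.update(overrides)
        return cls(**values)
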