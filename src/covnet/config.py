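"""Pipeline configuration (YAML-mirrorable flat key-value)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the end-to-end pipeline.

    Defaults follow the study conventions: edge significance and group-label
    permutation tests with 10,000 permutations, network thresholds at
    p < 0.05 and p < 0.01, a 10,000-partition consensus ensemble with
    alpha = 0.05, top-quartile hubs and FDR control at q < 0.05.
    """

    threshold_p_levels: tuple[float, ...] = (0.05, 0.01)
    n_null_permutations: int = 10_000
    n_comparison_permutations: int = 10_000
    n_mrcc_partitions: int = 10_000
    mrcc_alpha: float = 0.05
    hub_quantile: float = 0.25
    fdr_q: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "threshold_p_levels", tuple(float(l) for l in self.threshold_p_levels)
        )
        for name in ("mrcc_alpha", "hub_quantile", "fdr_q"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for level in self.threshold_p_levels:
            if not 0.0 < level <= 1.0:
                raise ValueError(f"threshold level {level} must be in (0, 1]")
        for name in ("n_null_permutations", "n_comparison_permutations",
                     "n_mrcc_partitions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
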