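"""Pipeline configuration: the thresholds and resampling controls of the
gene selection funnel plus the p-value conventions of the association battery.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .containers import ValidationError

__all__ = ["PipelineConfig", "load_config", "save_config", "config_hash"]


@dataclass
class PipelineConfig:
    """Controls for signature discovery and downstream testing.

    Attributes
    ----------
    sd_threshold
        Genes whose across-sample standard deviation strictly exceeds this
        enter the clustering (log-scale units).
    network_score_threshold
        Minimum interaction confidence score for an edge to count in the
        network filter.
    correlation_threshold
        Minimum pairwise Pearson r for two genes to be linked in the
        correlation filter.
    k_range
        Inclusive (lo, hi) range of candidate cluster counts for consensus
        clustering.
    fixed_k
        If set, pins the number of gene clusters instead of the delta-area
        criterion (the published signature fixed six clusters).
    n_resamples, resample_fraction
        Consensus clustering resampling controls: number of gene subsamples
        and the fraction of genes drawn (without replacement) per subsample.
    univariate_inclusion_p
        Covariates with any univariate p below this enter the multivariate
        model.
    significance_p
        Declared significance level for multivariate results.
    rng_seed
        Single master seed; all stage-level randomness derives from it.
    """

    sd_threshold: float = 0.8
    network_score_threshold: float = 0.7
    correlation_threshold: float = 0.5
    k_range: tuple[int, int] = (2, 8)
    fixed_k: int | None = None
    n_resamples: int = 250
    resample_fraction: float = 0.8
    univariate_inclusion_p: float = 0.10
    significance_p: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.k_range = (int(self.k_range[0]), int(self.k_range[1]))
        if not (0.0 <= self.network_score_threshold <= 1.0):
            raise ValidationError("network_score_threshold must lie in [0, 1]")
        if not (-1.0 <= self.correlation_threshold <= 1.0):
            raise ValidationError("correlation_threshold must lie in [-1, 1]")
        if self.k_range[0] < 2 or self.k_range[1] < self.k_range[0]:
            raise ValidationError("k_range must satisfy 2 <= lo <= hi")
        if self.n_resamples < 1:
            raise ValidationError("n_resamples must be positive")
        if not (0.0 < self.resample_fraction <= 1.0):
            raise ValidationError("resample_fraction must lie in (0, 1]")
        if self.fixed_k is not None and self.fixed_k < 1:
            raise ValidationError("fixed_k must be a positive integer")
        for name in ("univariate_inclusion_p", "significance_p"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ValidationError(f"{name} must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        d = dict(d)
        if "k_range" in d:
            d["k_range"] = tuple(d["k_range"])
        return cls(**d)

    def ks(self) -> list[int]:
        """Candidate cluster counts actually evaluated."""
        if self.fixed_k is not None:
            return [self.fixed_k]
        return list(range(self.k_range[0], self.k_range[1] + 1))


def load_config(path: str | Path) -> PipelineConfig:
    """Read a config from YAML or JSON (by extension; YAML parses both)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"config file {path} does not hold a mapping")
    return PipelineConfig.from_dict(data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg.to_dict(), indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: PipelineConfig) -> str:
    """Stable hash of the configuration, for run logs."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
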