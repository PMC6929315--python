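"""Pipeline configuration: every tunable threshold in one validated record.

Defaults are the analysis' published operating points (entropy >= 0.7,
TPM >= 0.05, identity/coverage > 0.85, responsive gate >= 2-fold at
p <= 0.006, multigroup gate q <= 0.05) plus the structural-classification
cutoffs that the category definitions require.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates the schema."""


@dataclass
class PipelineConfig:
    # de novo contig filter chain
    entropy_min: float = 0.7
    tpm_min: float = 0.05
    identity_min: float = 0.85
    coverage_min: float = 0.85
    # differential-expression gates
    fc_min: float = 2.0
    p_responsive: float = 0.006
    q_de: float = 0.05
    # repeat-overlap taxonomy
    standalone_cov_min: float = 0.80
    terminal_exon_cov_min: float = 0.50
    terminus_tolerance_bp: int = 10
    min_overlap_bp: int = 10
    # transcript comparison
    end_match_tolerance_bp: int = 100
    monoexonic_reciprocal_min: float = 0.80
    # intron retention
    nmd_rule_nt: int = 50
    retention_cov_min: float = 0.95
    # behavioural switches
    entropy_k: int = 5
    aln_filter_mode: str = "strict"  # "strict": keep iff id AND cov pass; "lenient": remove iff both fail
    welch: bool = False
    rng_seed: int = 0

    _FRACTIONS = (
        "entropy_min", "identity_min", "coverage_min", "p_responsive", "q_de",
        "standalone_cov_min", "terminal_exon_cov_min",
        "monoexonic_reciprocal_min", "retention_cov_min",
    )
    _NONNEG_INTS = (
        "terminus_tolerance_bp", "min_overlap_bp", "end_match_tolerance_bp",
        "nmd_rule_nt",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        bad: list[str] = []
        for name in self._FRACTIONS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                bad.append(f"{name}={v!r} (must be in [0,1])")
        for name in self._NONNEG_INTS:
            v = getattr(self, name)
            if v < 0:
                bad.append(f"{name}={v!r} (must be >= 0)")
        if self.fc_min < 1:
            bad.append(f"fc_min={self.fc_min!r} (must be >= 1)")
        if self.tpm_min < 0:
            bad.append(f"tpm_min={self.tpm_min!r} (must be >= 0)")
        if self.entropy_k < 1:
            bad.append(f"entropy_k={self.entropy_k!r} (must be >= 1)")
        if self.aln_filter_mode not in ("strict", "lenient"):
            bad.append(f"aln_filter_mode={self.aln_filter_mode!r}")
        if bad:
            raise ConfigError("invalid configuration: " + "; ".join(bad))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


DEFAULT_CONFIG = PipelineConfig()
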