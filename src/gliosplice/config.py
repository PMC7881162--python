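"""Pipeline configuration: the named thresholds used across all stages.

Defaults are the analysis constants of the study design: significance
p <= 0.05, at least 1 inclusion and 1 exclusion read and 10 total reads per
event, |dPSI| >= 0.10, 95% reciprocal overlap for cross-sample event
matching, 75% quantifiability and 20% group dPSI for the response
signature, 250 nM EC50 for the sensitivity call, and 100 bootstrap
resamples for enrichment standard errors.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict

import yaml


@dataclass
class PipelineConfig:
    seed: int = 0
    p_max: float = 0.05
    min_total_reads: int = 10
    min_inc_reads: int = 1
    min_exc_reads: int = 1
    min_abs_dpsi: float = 0.10
    min_reciprocal_overlap: float = 0.95
    min_fraction_quantified: float = 0.75
    min_signature_dpsi: float = 0.20
    ec50_sensitive_nM: float = 250.0
    bootstrap_B: int = 100
    paths: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("p_max", "min_abs_dpsi", "min_reciprocal_overlap",
                     "min_fraction_quantified", "min_signature_dpsi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0,1]")
        if self.min_total_reads < max(self.min_inc_reads, self.min_exc_reads):
            raise ValueError(
                "min_total_reads must be >= max(min_inc_reads, min_exc_reads)"
            )
        if self.bootstrap_B < 1:
            raise ValueError("bootstrap_B must be >= 1")

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable hash of the configuration, for run provenance logs."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a flat YAML or JSON configuration document."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
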