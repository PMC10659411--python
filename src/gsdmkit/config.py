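"""Flat YAML configuration with a strict schema.

All stage parameters live in one flat key-value namespace; unknown keys
are rejected so typos fail loudly.  Every pipeline run persists the
resolved configuration in its manifest.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import yaml

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Resolved stage parameters for a pipeline run."""

    seed: int = 0
    # curation
    identity_threshold: float = 0.95
    rbh_min_score: float = 50.0
    # alignment
    gap_open: float = 11.0
    gap_extend: float = 1.0
    guide_kmer: int = 3
    # profile HMM
    hmm_gap_threshold: float = 0.5
    hmm_pseudocount: float = 1.0
    bits_threshold: float = 20.0
    min_orf_aa: int = 50
    # motifs
    yvad_threshold: float = 15.0
    reference_id: str = ""
    beta11_end: int = 0
    alpha5_start: int = 0
    nterm_start: int = 0
    nterm_end: int = 0
    logo_small_sample_correction: bool = True
    # synthetic data
    simulate_contigs: bool = False

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - cls.field_names()
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold flat key-value pairs")
        return cls.from_dict(raw)

    def updated(self, **overrides) -> "PipelineConfig":
        """CLI flags override file values; unknown keys still rejected."""
        clean = {k: v for k, v in overrides.items() if v is not None}
        unknown = set(clean) - self.field_names()
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return dataclasses.replace(self, **clean)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
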