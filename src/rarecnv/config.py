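"""Run configuration: nested parameter groups with strict key checking."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .calling import CallingParams

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Raised for unknown keys or invalid configuration values."""


def _from_dict(cls, data: dict, context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown {context} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class PathsConfig:
    intensities: dict = field(default_factory=dict)  # array -> long TSV
    probe_map: str | None = None
    sample_sheet: str | None = None
    exons: str | None = None
    masks_bed: str | None = None
    chromosome_structure: str | None = None
    reference_svs: str | None = None
    anchor_genes: str | None = None


@dataclass
class QCConfig:
    min_call_rate: float = 0.99
    dlrs_k_sd: float = 3.5
    mask_buffer_bp: int = 1_000_000


@dataclass
class RegionConfig:
    min_carriers: int = 5
    merge_gap_probes: int = 5
    min_fraction: float = 0.9


@dataclass
class AssocConfig:
    min_carriers: int = 24
    include_pcs: bool = True


@dataclass
class BFDPPriors:
    prior_pi_regions: float = 0.001
    prior_pi_genes: float = 0.002
    prior_pi_known: float = 0.99
    k_bound: float = 3.0
    k_bound_known: float = 20.0
    known_genes: list = field(default_factory=lambda: ["BRCA1", "BRCA2", "ATM", "CHEK2"])


@dataclass
class DirectionConfig:
    n_perm: int = 50
    region_exclusions: list = field(default_factory=list)
    gene_exclusions: list = field(default_factory=list)


@dataclass
class RunConfig:
    """Full pipeline configuration.

    ``scenario`` (optional) holds :class:`~rarecnv.synthetic.ScenarioConfig`
    keyword arguments; when present the pipeline starts by simulating a
    cohort instead of reading intensity files.
    """

    output_dir: str = "rarecnv_out"
    seed: int = 0
    scenario: dict | None = None
    paths: PathsConfig = field(default_factory=PathsConfig)
    calling: CallingParams = field(default_factory=CallingParams)
    qc: QCConfig = field(default_factory=QCConfig)
    regions: RegionConfig = field(default_factory=RegionConfig)
    assoc: AssocConfig = field(default_factory=AssocConfig)
    bfdp: BFDPPriors = field(default_factory=BFDPPriors)
    direction: DirectionConfig = field(default_factory=DirectionConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        nested = {
            "paths": PathsConfig,
            "calling": CallingParams,
            "qc": QCConfig,
            "regions": RegionConfig,
            "assoc": AssocConfig,
            "bfdp": BFDPPriors,
            "direction": DirectionConfig,
        }
        kwargs = {}
        for key, sub_cls in nested.items():
            if key in data:
                sub = data.pop(key)
                if not isinstance(sub, dict):
                    raise ConfigError(f"{key} section must be a mapping")
                # tuples arrive from YAML as lists
                sub = {
                    k: tuple(v) if isinstance(v, list) and k.endswith(("_range", "band")) else v
                    for k, v in sub.items()
                }
                kwargs[key] = _from_dict(sub_cls, sub, key)
        allowed = {f.name for f in fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Parse a YAML run configuration, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    return RunConfig.from_dict(raw)
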