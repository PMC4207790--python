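"""Pipeline configuration: nested dataclasses, strict YAML/JSON loading.

Unknown keys fail fast with the offending key path; threshold domains are
validated on construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calling import CallerThresholds


@dataclass(frozen=True)
class SimulateConfig:
    n_chrom: int = 3
    chrom_lengths: list[int] | None = None
    genes_per_chrom: int = 6
    n_strains: int = 8
    mean_depth: float = 30.0
    error_rate: float = 0.005
    #: number of planted mutations per functional class, spread round-robin
    #: over the strains
    planted: dict[str, int] = field(
        default_factory=lambda: {
            "intergenic": 2,
            "synonymous": 1,
            "missense": 2,
            "nonsense": 1,
            "frameshift": 1,
            "inframe_indel": 1,
        }
    )
    #: (strain_index, chrom_name) pairs carrying a whole-chromosome duplication
    duplicated: list[list] = field(default_factory=list)


@dataclass(frozen=True)
class ExperimentConfig:
    n_lineages: int = 20
    cells_per_well_range: list[int] = field(default_factory=lambda: [400, 3000])
    p_adapt: float = 0.014
    mutation_model: str = "induced"
    mu_predivision: float = 0.0
    p_induced: float = 0.05


@dataclass(frozen=True)
class AneuploidyConfig:
    window_size: int = 5000
    n_windows: int = 200
    band: list[float] = field(default_factory=lambda: [1.75, 2.25])


@dataclass(frozen=True)
class StatsConfig:
    genome_length: int | None = None  # default: simulated nuclear genome length
    locus_len: int = 1200


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    verbosity: str = "info"
    write_count_tables: bool = False
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    thresholds: CallerThresholds = field(default_factory=CallerThresholds)
    aneuploidy: AneuploidyConfig = field(default_factory=AneuploidyConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)


_NESTED = {
    "simulate": SimulateConfig,
    "experiment": ExperimentConfig,
    "thresholds": CallerThresholds,
    "aneuploidy": AneuploidyConfig,
    "stats": StatsConfig,
}


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"config section {path or 'root'} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)} under '{path or 'root'}'"
        )
    kwargs = {}
    for key, value in data.items():
        sub = _NESTED.get(key)
        if sub is not None and cls is PipelineConfig:
            kwargs[key] = _build(sub, value, f"{path}{key}.")
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as e:
        raise ValueError(f"invalid config under '{path or 'root'}': {e}") from e


def config_from_dict(data: dict | None) -> PipelineConfig:
    return _build(PipelineConfig, data or {}, "")


def load_config(path) -> PipelineConfig:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return config_from_dict(data)
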