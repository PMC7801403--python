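"""Pipeline configuration: schema, defaults, YAML round trip, sub-seeds.

Absolute event rates are not identified by the biology alone; the defaults
here are calibrated so that (a) untreated burden grows roughly 10-fold per
week, (b) chemotherapy produces a burden nadir near treatment day 7 on the
day-0/5/7/14 sampling grid, and (c) mTORC1-high cells cycle faster than low
cells.  All of them live in this module, not in the simulator code.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field

import yaml

from .clonal_sim import ChemoSchedule, ExperimentDesign, MechanismSpec, RateSet
from .clonestats import StatsConfig
from .synth_assets import IntensityModel, ReadSpec

__all__ = [
    "AssetConfig",
    "PipelineConfig",
    "DEFAULT_RATES",
    "load_config",
    "config_template",
    "config_hash",
    "stage_seed",
]

# calibrated defaults (see module docstring); the base RateSet is the
# induction-side parameterisation from which mechanism templates are derived
DEFAULT_RATES = RateSet(
    birth_H=0.5, birth_L=0.3,
    death_H=0.05, death_L=0.05,
    trans_HL=0.2, trans_LH=0.2,
    kill_H=0.8, kill_L=1.1,
    nutrient_coupling=1.0,
    capacity_K=2e8,
)


@dataclass(frozen=True)
class AssetConfig:
    """Knobs for the synthetic raw-data generators."""

    depth_per_cell: float = 1.0
    depth_mode: str = "poisson"     # or 'exact'
    per_base_error_rate: float = 0.001
    min_quality: int = 20
    max_hamming: int = 2


@dataclass(frozen=True)
class PipelineConfig:
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    rates: RateSet = field(default_factory=lambda: DEFAULT_RATES)
    mechanism: MechanismSpec = field(default_factory=lambda: MechanismSpec("induction"))
    schedule: ChemoSchedule = field(default_factory=ChemoSchedule)
    assets: AssetConfig = field(default_factory=AssetConfig)
    intensity: IntensityModel = field(default_factory=IntensityModel)
    reads: ReadSpec = field(default_factory=ReadSpec)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    verbosity: int = 1


_BLOCKS = {
    "design": ExperimentDesign,
    "rates": RateSet,
    "mechanism": MechanismSpec,
    "schedule": ChemoSchedule,
    "assets": AssetConfig,
    "intensity": IntensityModel,
    "reads": ReadSpec,
    "stats": StatsConfig,
}


def _build(cls, data: dict, block: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in config block '{block}': {sorted(unknown)}")
    if cls is ExperimentDesign and "sampling_days" in data:
        data = {**data, "sampling_days": tuple(data["sampling_days"])}
    return cls(**data)


def load_config(source) -> PipelineConfig:
    """Build a validated PipelineConfig from a YAML path, text, or dict.

    Unknown keys anywhere in the document are rejected.
    """
    if isinstance(source, dict):
        doc = source
    else:
        text = source.read_text() if hasattr(source, "read_text") else str(source)
        doc = yaml.safe_load(text) or {}
    unknown = set(doc) - set(_BLOCKS) - {"seed", "verbosity"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    for block, cls in _BLOCKS.items():
        if block in doc:
            kwargs[block] = _build(cls, dict(doc[block] or {}), block)
    if "seed" in doc:
        kwargs["seed"] = int(doc["seed"])
    if "verbosity" in doc:
        kwargs["verbosity"] = int(doc["verbosity"])
    return PipelineConfig(**kwargs)


def config_to_dict(cfg: PipelineConfig) -> dict:
    out: dict = {}
    for block in _BLOCKS:
        d = dataclasses.asdict(getattr(cfg, block))
        if block == "design":
            d["sampling_days"] = list(d["sampling_days"])
        out[block] = d
    out["seed"] = cfg.seed
    out["verbosity"] = cfg.verbosity
    return out


def config_hash(cfg: PipelineConfig) -> str:
    """Stable hash of the fully serialised configuration."""
    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage sub-seed by stage-name hashing (< 2^31).

    Hashing the stage name (rather than using positional offsets) keeps each
    stage's random stream stable if stages are added or reordered.
    """
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


def config_template() -> str:
    """Fully-commented default configuration document."""
    cfg = PipelineConfig()
    lines = ["# clonfate pipeline configuration (defaults)", ""]
    comments = {
        "design": "barcoding experiment layout (cells exposed, MOI, sorts, sampling days)",
        "rates": "per-day event rates; the induction-side base parameterisation",
        "mechanism": "selection | induction | mixed (mixing_weight on induction)",
        "schedule": "chemotherapy window on the treatment clock",
        "assets": "synthetic read generation and extraction thresholds",
        "intensity": "log-normal reporter channel model",
        "reads": "barcode amplicon architecture and error model",
        "stats": "mechanism-classifier decision thresholds",
    }
    doc = config_to_dict(cfg)
    for block in _BLOCKS:
        lines.append(f"# {comments[block]}")
        lines.append(yaml.safe_dump({block: doc[block]}, sort_keys=False).rstrip())
        lines.append("")
    lines.append("seed: 0")
    lines.append("verbosity: 1")
    return "\n".join(lines) + "\n"
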