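"""Run configuration: simulation, chain, and grid parameters from YAML.

Every field has a documented default; unknown keys are rejected so typos
fail loudly rather than silently running the default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import yaml


class ConfigError(ValueError):
    """Raised for unreadable, unparsable, or unknown-key configurations."""


@dataclass
class SimulationConfig:
    n_founders: int = 200          # founder animals (even)
    n_generations: int = 4         # bred generations after the founders
    offspring_per_mating: int = 2
    n_chromosomes: int = 10
    markers_per_chromosome: int = 500   # sparse-panel markers per chromosome
    spacing_bp: int = 50_000            # sparse-panel marker spacing
    density_ratio: int = 1              # dense:sparse marker ratio (14 emulates 770K:50K)
    qtl_spacing: int = 250              # QTL = every m-th ordered sparse SNP
    maf_low: float = 0.01
    maf_high: float = 0.5
    ld_rho: float = 0.9                 # latent LD correlation at the reference distance
    reference_distance: float = 50_000.0
    cm_per_mb: float = 1.0


@dataclass
class ChainSettings:
    n_iterations: int = 4000
    burn_in: int = 500
    thinning: int = 1
    wg_n_iterations: int = 800   # whole-genome chains converge fast at h²=1
    wg_burn_in: int = 200


@dataclass
class GridConfig:
    preset: str = "desk"                 # desk | full
    panels: list = field(default_factory=lambda: ["sparse"])
    flank_sizes: list = field(default_factory=lambda: [1, 5, 10, 100])
    cv_groups: int = 6
    cv_restarts: int = 10


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    chain: ChainSettings = field(default_factory=ChainSettings)
    grid: GridConfig = field(default_factory=GridConfig)
    seed: int = 1
    outdir: str = "localqtl_out"


def _build(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        f = names[key]
        if dataclasses.is_dataclass(f.type) or f.name in ("simulation", "chain", "grid"):
            sub = {"simulation": SimulationConfig, "chain": ChainSettings, "grid": GridConfig}[key]
            kwargs[key] = _build(sub, value, f"{context}.{key}")
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: Union[str, Path, None]) -> RunConfig:
    """Load a RunConfig from YAML; ``None`` gives all defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as err:
        raise ConfigError(f"cannot parse {path}: {err}") from None
    return _build(RunConfig, data, str(path))


def dump_config(config: RunConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=False))
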