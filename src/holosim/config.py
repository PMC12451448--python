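"""Simulation configuration, validation, and experiment-grid construction.

Configuration files are flat YAML key-value documents; any omitted key
falls back to the main-simulation default below.  The full-scale
defaults (100 hosts, 200 taxa, 10^6 microbes per host, 10^8 in the
environment, 1500 host generations with a 200-generation burn-in) match
the reference full-scale study conditions; desk-scale experiments override the
population sizes explicitly.

Seed policy: a single master seed; per-run seeds are derived by stable
hashing of (master seed, purpose, scenario, replicate, X, T_M), so any
run of a grid can be reproduced in isolation and independently of
execution order.  Environmental series are keyed by (scenario,
replicate) only, so every (X, T_M) combination of a replicate sees the
identical series.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from itertools import product

import yaml

from .environment import DEFAULT_PARAMS, SCENARIO_KINDS

#: X and T_M grids and scenario list used for the full reference sweep
#: (14 x 9 x 6 x 20 replicates = 15120 runs).
GRID_X_VALUES = (0.0, 0.167, 0.333, 0.500, 0.667, 0.933, 0.990, 0.999, 1.0)
GRID_TM_VALUES = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 20, 50, 100, 200)
GRID_SCENARIOS = SCENARIO_KINDS

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "RunSpec",
    "load_config",
    "save_config",
    "derive_seed",
    "build_grid",
    "GRID_X_VALUES",
    "GRID_TM_VALUES",
    "GRID_SCENARIOS",
]


class ConfigError(ValueError):
    """Invalid configuration value or file."""


@dataclass
class SimulationConfig:
    """All model parameters plus scenario, replication and seed controls.

    Proportions: ``X`` vertical inheritance at birth, ``P`` within-host
    retention per microbial generation, ``Z``/``Y`` environmental-pool
    persistence and host shedding (fixed-pool contribution is
    ``1 - Z - Y``), ``G``/``I`` host-genetic weightings of phenotype and
    within-host environment.
    """

    N_H: int = 100          # hosts
    N_M: int = 200          # microbial taxa
    n_MH: int = 10**6       # microbes per host
    n_ME: int = 10**8       # microbes in the environment
    T_H: int = 1500         # host generations (burn-in included)
    T_M: int = 1            # microbial generations per host generation
    burn_in: int = 200
    X: float = 0.5
    P: float = 0.98
    Z: float = 0.8
    Y: float = 0.05
    G: float = 0.0
    I: float = 0.5
    s: float = 1.0
    trait_min: float = -2.5
    trait_max: float = 2.5
    phi_hg: float = 0.0
    scenario: str = "1A"
    scenario_params: dict = field(default_factory=dict)
    replicates: int = 20
    seed: int = 1
    # model-variant switches (defaults are the canonical behaviour)
    fitness_context: str = "destination"   # or "source"
    allocation_mode: str = "deterministic"  # or "binomial"
    selection_env: str = "final"           # or "start"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in ("N_H", "N_M", "n_MH", "n_ME", "T_H", "T_M", "burn_in", "replicates"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ConfigError(f"{name} must be an integer, got {v!r}")
        if self.N_H < 2:
            raise ConfigError(f"N_H must be >= 2, got {self.N_H}")
        if self.N_M < 1:
            raise ConfigError(f"N_M must be >= 1, got {self.N_M}")
        if self.n_MH < 1 or self.n_ME < 1:
            raise ConfigError("community sizes n_MH and n_ME must be >= 1")
        if self.T_M < 1:
            raise ConfigError(f"T_M must be >= 1, got {self.T_M}")
        if self.T_H < 1:
            raise ConfigError(f"T_H must be >= 1, got {self.T_H}")
        if not 0 <= self.burn_in <= self.T_H:
            raise ConfigError(f"burn_in must be in [0, T_H], got {self.burn_in}")
        if self.replicates < 1:
            raise ConfigError(f"replicates must be >= 1, got {self.replicates}")
        for name in ("X", "P", "Z", "Y", "G", "I"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.Z + self.Y > 1.0 + 1e-12:
            raise ConfigError(f"Z + Y must be <= 1, got Z={self.Z}, Y={self.Y}")
        if self.s <= 0:
            raise ConfigError(f"s must be > 0, got {self.s}")
        if not self.trait_min < self.trait_max:
            raise ConfigError(
                f"trait_min must be < trait_max, got [{self.trait_min}, {self.trait_max}]"
            )
        if self.scenario not in SCENARIO_KINDS:
            raise ConfigError(f"scenario must be one of {SCENARIO_KINDS}, got {self.scenario!r}")
        unknown = set(self.scenario_params) - set(DEFAULT_PARAMS)
        if unknown:
            raise ConfigError(f"unknown scenario_params keys: {sorted(unknown)}")
        if self.fitness_context not in ("destination", "source"):
            raise ConfigError(f"fitness_context must be 'destination' or 'source'")
        if self.allocation_mode not in ("deterministic", "binomial"):
            raise ConfigError("allocation_mode must be 'deterministic' or 'binomial'")
        if self.selection_env not in ("final", "start"):
            raise ConfigError("selection_env must be 'final' or 'start'")

    def replace(self, **kwargs) -> "SimulationConfig":
        """Return a validated copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELD_NAMES = {f.name for f in dataclasses.fields(SimulationConfig)}
_INT_FIELDS = {"N_H", "N_M", "n_MH", "n_ME", "T_H", "T_M", "burn_in", "replicates", "seed"}


def load_config(path) -> SimulationConfig:
    """Load a YAML config file; omitted keys take the documented defaults."""
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse config file {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must be a flat key-value document")
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in _INT_FIELDS & set(data):
        v = data[key]
        if isinstance(v, float) and v.is_integer():
            data[key] = int(v)
    return SimulationConfig(**data)


def save_config(config: SimulationConfig, path) -> None:
    """Write a config as a flat YAML document (round-trips exactly)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def derive_seed(master_seed: int, *parts) -> int:
    """Stable sub-seed from the master seed and a tuple of labels.

    Uses SHA-256 of the canonical repr, truncated to 31 bits, so derived
    seeds are reproducible across platforms and sessions.
    """
    key = repr((int(master_seed),) + tuple(parts)).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class RunSpec:
    """One fully resolved simulation run within a grid."""

    scenario: str
    replicate: int
    X: float
    T_M: int
    seed: int        # drives the simulation itself
    env_seed: int    # drives the environmental series (shared across X, T_M)
    config: SimulationConfig = field(compare=False)

    @property
    def label(self) -> str:
        return f"{self.scenario}_X{self.X:g}_TM{self.T_M}_rep{self.replicate}"


def build_grid(base: SimulationConfig, X_values=None, T_M_values=None,
               scenarios=None, replicates=None) -> list:
    """Cartesian product of (scenario, replicate, X, T_M) run specifications.

    Environmental-series seeds are keyed by (scenario, replicate) only,
    so all X/T_M combinations of a replicate reuse the identical series;
    simulation seeds additionally key on (X, T_M).
    """
    X_values = list(GRID_X_VALUES if X_values is None else X_values)
    T_M_values = list(GRID_TM_VALUES if T_M_values is None else T_M_values)
    scenarios = list(GRID_SCENARIOS if scenarios is None else scenarios)
    replicates = base.replicates if replicates is None else replicates
    if not X_values or not T_M_values or not scenarios or replicates < 1:
        raise ConfigError("grid lists must be non-empty and replicates >= 1")
    specs = []
    for scen, rep, x, tm in product(scenarios, range(replicates), X_values, T_M_values):
        cfg = base.replace(scenario=scen, X=x, T_M=tm, replicates=replicates)
        specs.append(RunSpec(
            scenario=scen,
            replicate=rep,
            X=x,
            T_M=tm,
            seed=derive_seed(base.seed, "run", scen, rep, float(x), int(tm)),
            env_seed=derive_seed(base.seed, "env", scen, rep),
            config=cfg,
        ))
    return specs
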