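"""Run configuration and logging setup for the pipeline entry points."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError
from .genome import DEFAULT_AUTOSOMES

log = logging.getLogger("metahic")


@dataclass
class RunConfig:
    """Flat key-value pipeline configuration with paper-matching defaults."""

    resolutions: tuple = (1_000, 5_000, 10_000, 25_000, 40_000, 100_000, 250_000, 500_000)
    species: str = "human"
    autosomes: tuple | None = None        # None -> species preset allow-list
    aggregation_recipe: str = "sum-balanced"  # or "sum-raw"
    coexpression_fraction: float = 0.01
    conservation_fraction: float = 0.10
    eqtl_resolution: int = 1_000
    min_distance: int = 0
    balance_tolerance: float = 1e-6
    balance_max_iter: int = 1000
    tad_window: int = 5
    tie_seed: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.autosomes is None:
            self.autosomes = tuple(DEFAULT_AUTOSOMES.get(self.species, ()))
        else:
            self.autosomes = tuple(self.autosomes)
        self.resolutions = tuple(int(r) for r in self.resolutions)
        if self.aggregation_recipe not in ("sum-balanced", "sum-raw"):
            raise ConfigError(
                f"unknown aggregation_recipe {self.aggregation_recipe!r}"
            )
        if not 0 < self.coexpression_fraction < 1:
            raise ConfigError("coexpression_fraction must be in (0,1)")
        if not 0 < self.conservation_fraction < 1:
            raise ConfigError("conservation_fraction must be in (0,1)")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError("config file must be a flat key-value mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration, recorded as provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


class JsonLineFormatter(logging.Formatter):
    def format(self, record):
        return json.dumps(
            {"level": record.levelname, "name": record.name, "msg": record.getMessage()}
        )


def setup_logging(level: str = "INFO", json_lines: bool = False) -> None:
    """Log to stderr; optional machine-readable JSON-lines records."""
    handler = logging.StreamHandler(sys.stderr)
    if json_lines:
        handler.setFormatter(JsonLineFormatter())
    else:
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("metahic")
    root.handlers[:] = [handler]
    root.setLevel(level)
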