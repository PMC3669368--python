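"""Run configuration: YAML loading, validation, and power-table I/O."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import pandas as pd
import yaml

from .errors import ParameterError
from .power import (POWER_TABLE_COLUMNS, SimulationSetting, build_causal_ld_grid,
                    build_noncausal_ld_grid, build_nold_grid)
from .settests import METHODS

__all__ = ["RunConfig", "load_config", "write_power_table", "read_power_table"]

GRID_NAMES = ("no_ld", "causal_ld", "causal_ld_tagonly", "noncausal_ld")


@dataclass
class RunConfig:
    """Validated configuration for a grid power run.

    Either ``grid`` names one of the study grids or ``settings`` lists
    explicit :class:`SimulationSetting` field mappings.
    """

    grid: str | None = None
    settings: tuple = ()
    methods: tuple = METHODS
    alpha: float = 0.05
    replicates: int = 500
    vegas_sims: int = 1000
    base_seed: int = 0
    workers: int = 1

    def __post_init__(self):
        if (self.grid is None) == (not self.settings):
            raise ParameterError("config must name a grid or list explicit settings")
        if self.grid is not None and self.grid not in GRID_NAMES:
            raise ParameterError(f"grid must be one of {GRID_NAMES}, got {self.grid!r}")
        self.settings = tuple(
            s if isinstance(s, dict) else dict(s) for s in self.settings
        )
        for s in self.settings:
            SimulationSetting(**s)  # validate eagerly
        self.methods = tuple(self.methods)
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise ParameterError(f"unknown methods: {unknown}")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must lie in (0, 1)")
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")
        if self.vegas_sims < 100:
            raise ParameterError("vegas_sims must be >= 100")
        if self.workers < 1:
            raise ParameterError("workers must be >= 1")

    def build_grid(self):
        if self.settings:
            return [
                SimulationSetting(**{**s, "replicates": s.get("replicates",
                                                              self.replicates),
                                     "alpha": s.get("alpha", self.alpha)})
                for s in self.settings
            ]
        if self.grid == "no_ld":
            return build_nold_grid(replicates=self.replicates, alpha=self.alpha)
        if self.grid == "causal_ld":
            return build_causal_ld_grid(replicates=self.replicates, alpha=self.alpha)
        if self.grid == "causal_ld_tagonly":
            return build_causal_ld_grid(include_tag_only=True,
                                        replicates=self.replicates, alpha=self.alpha)
        return build_noncausal_ld_grid(replicates=self.replicates, alpha=self.alpha)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        d["settings"] = [dict(s) for s in self.settings]
        return d

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParameterError(f"config file {path} must contain a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ParameterError(f"unknown config keys: {unknown}")
    return RunConfig(**raw)


def write_power_table(table: pd.DataFrame, path) -> None:
    """Lossless TSV dump (floats rendered with shortest round-trip repr)."""
    table.to_csv(path, sep="\t", index=False)


def read_power_table(path) -> pd.DataFrame:
    try:
        table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # surface pandas' line-numbered message
        raise ParameterError(f"malformed power table {path}: {exc}") from exc
    missing = [c for c in POWER_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ParameterError(f"power table {path} is missing columns {missing}")
    return table
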