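"""YAML configuration: one flat, versioned document describing a run.

Sections: ``environment`` (basic rates and reinforcement model, or an
``extended`` block), ``costs``, ``dp``, ``lp`` and ``experiment`` (delays,
agent counts, free-run length).  Every key is optional and falls back to the
package defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .costs import CostModel
from .environment import EnvParams, ExtEnvParams
from .policies import DPConfig, LPConfig

__all__ = ["RunConfig", "load_config", "default_config", "dump_config"]

SCHEMA_VERSION = "flyforget-config-v1"


@dataclass
class RunConfig:
    env: EnvParams = field(default_factory=EnvParams)
    ext_env: ExtEnvParams = field(default_factory=ExtEnvParams)
    costs: CostModel = field(default_factory=CostModel)
    dp: DPConfig = field(default_factory=DPConfig)
    lp: LPConfig = field(default_factory=LPConfig)
    delays: tuple = tuple(int(d) for d in np.unique(
        np.round(np.geomspace(1, 201, 21) - 1).astype(int)))
    n_agents: int = 2000
    free_run_T: int = 1000
    free_run_n: int = 40

    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA_VERSION,
            "environment": self.env.to_dict(),
            "extended_environment": self.ext_env.to_dict(),
            "costs": {"scale": self.costs.scale},
            "dp": {"horizon": self.dp.horizon, "gamma": self.dp.gamma},
            "lp": {"lattice_spacing": self.lp.lattice_spacing,
                   "n_cost_bins": self.lp.n_cost_bins},
            "experiment": {"delays": list(self.delays),
                           "n_agents": self.n_agents,
                           "free_run_T": self.free_run_T,
                           "free_run_n": self.free_run_n},
        }


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path: str | Path) -> RunConfig:
    """Read a run configuration; missing sections use package defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    cfg = RunConfig()
    try:
        if "environment" in raw:
            cfg.env = EnvParams.from_dict(raw["environment"])
        if "extended_environment" in raw:
            cfg.ext_env = ExtEnvParams.from_dict(raw["extended_environment"])
        if "costs" in raw:
            cfg.costs = CostModel(**{k: v for k, v in raw["costs"].items()
                                     if k != "schema"})
        if "dp" in raw:
            cfg.dp = DPConfig(**raw["dp"])
        if "lp" in raw:
            cfg.lp = LPConfig(**raw["lp"])
        exp = raw.get("experiment", {})
        cfg.delays = tuple(int(d) for d in exp.get("delays", cfg.delays))
        cfg.n_agents = int(exp.get("n_agents", cfg.n_agents))
        cfg.free_run_T = int(exp.get("free_run_T", cfg.free_run_T))
        cfg.free_run_n = int(exp.get("free_run_n", cfg.free_run_n))
    except (TypeError, ValueError, KeyError) as exc:
        raise ValueError(f"invalid configuration {path}: {exc}") from exc
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
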