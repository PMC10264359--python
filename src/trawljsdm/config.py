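"""Pipeline configuration: one YAML file drives every stage.

Example::

    seed: 1
    paths:
      community: out/community.csv
      traits: null            # null -> packaged fixture
      taxonomy: null          # CSV or Newick; Newick takes precedence
      tree: null
      grid: null              # null -> grid derived from the hauls
      output: out
    filter: {min_occ_frac: 0.02, min_total: 150}
    scenario: {n_hauls: 1500}
    mcmc: {n_chains: 2, n_iterations: 3000, n_burnin: 1000, thin: 10}
    prediction:
      baseline_year: null     # null -> first survey year
      swept_area: 0.047
      lognormal_correction: true
      resolution: 0.05
    log_level: INFO
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .gibbs import McmcConfig
from .synthetic import SimulationScenario

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    seed: int
    paths: dict = field(default_factory=dict)
    filter: dict = field(default_factory=lambda: {"min_occ_frac": 0.02, "min_total": 150})
    scenario: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=dict)
    prediction: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def output_dir(self) -> Path:
        out = Path(self.paths.get("output", "out"))
        out.mkdir(parents=True, exist_ok=True)
        return out

    def mcmc_config(self) -> McmcConfig:
        kw = dict(self.mcmc)
        if "rho_grid" in kw:
            kw["rho_grid"] = np.asarray(kw["rho_grid"], dtype=float)
        if "alpha_grid_km" in kw and kw["alpha_grid_km"] is not None:
            kw["alpha_grid_km"] = np.asarray(kw["alpha_grid_km"], dtype=float)
        kw.setdefault("seed", self.seed)
        return McmcConfig(**kw)

    def simulation_scenario(self) -> SimulationScenario:
        kw = dict(self.scenario)
        for key in ("gamma_pa", "gamma_abu", "V_pa", "V_abu"):
            if key in kw:
                kw[key] = np.asarray(kw[key], dtype=float)
        kw.setdefault("seed", self.seed)
        return SimulationScenario(**kw)

    def prediction_options(self) -> dict:
        opts = {
            "baseline_year": None,
            "swept_area": 0.047,
            "lognormal_correction": True,
            "resolution": 0.05,
        }
        opts.update(self.prediction)
        return opts

    def digest(self) -> str:
        payload = {
            "seed": self.seed,
            "paths": {k: str(v) for k, v in self.paths.items()},
            "filter": self.filter,
            "scenario": {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in self.scenario.items()},
            "mcmc": self.mcmc,
            "prediction": self.prediction,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError("the configuration must set a seed")
    known = {"seed", "paths", "filter", "scenario", "mcmc", "prediction", "log_level"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys {sorted(unknown)}")
    return PipelineConfig(**raw)
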