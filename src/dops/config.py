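"""Config-file parsing (YAML or JSON) into run settings.

A config file has optional sections ``swarm`` and ``dds`` plus top-level
fields; every field defaults to the reference study conditions.  Example::

    objective: rastrigin
    dimension: 10
    variant: dops
    total_budget: 4000
    seed: 17
    swarm:
      n_particles: 40
      n_subswarms: 5
      w_max: 0.9
      w_min: 0.4
      theta2: 1.5
      theta3: 1.5
      regroup_interval: 10
      stagnation_tolerance: 0.01
      stagnation_limit: 4
    dds:
      r: 0.2
      probability_formula: reference
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .controller import DOPSConfig
from .dds import PerturbationSettings
from .swarm import SwarmSettings

__all__ = ["load_config_file", "config_from_dict", "config_to_dict"]


def load_config_file(path: str | Path) -> dict:
    """Load a YAML or JSON config file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def config_from_dict(data: dict) -> DOPSConfig:
    """Build a :class:`DOPSConfig` from a (possibly partial) dict."""
    swarm = SwarmSettings(**data.get("swarm", {}))
    dds = PerturbationSettings(**data.get("dds", {}))
    keys = ("total_budget", "multiswitch", "switchback_ratio", "phase1_cap_fraction", "seed")
    top = {k: data[k] for k in keys if k in data}
    return DOPSConfig(swarm=swarm, dds=dds, **top)


def config_to_dict(config: DOPSConfig) -> dict:
    return {
        "total_budget": config.total_budget,
        "multiswitch": config.multiswitch,
        "switchback_ratio": config.switchback_ratio,
        "phase1_cap_fraction": config.phase1_cap_fraction,
        "seed": config.seed,
        "swarm": {
            "n_particles": config.swarm.n_particles,
            "n_subswarms": config.swarm.n_subswarms,
            "w_max": config.swarm.w_max,
            "w_min": config.swarm.w_min,
            "theta2": config.swarm.theta2,
            "theta3": config.swarm.theta3,
            "regroup_interval": config.swarm.regroup_interval,
            "stagnation_tolerance": config.swarm.stagnation_tolerance,
            "stagnation_limit": config.swarm.stagnation_limit,
        },
        "dds": {
            "r": config.dds.r,
            "probability_formula": config.dds.probability_formula,
        },
    }
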