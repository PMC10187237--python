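"""YAML configuration round-trip for simulation runs.

One document with sections ``lattice``, ``kinetics``, ``solution`` and
``simulation``; omitted keys fall back to the fitted defaults (the
parameter set that reproduces the GMPCPP growth measurements).
"""

from __future__ import annotations

from dataclasses import asdict
import yaml

from .engine import SimConfig
from .lattice import LatticeParams
from .rates import KineticParams, SolutionState

__all__ = ["load_config", "save_config", "config_to_dict", "config_from_dict"]


def config_to_dict(config: SimConfig) -> dict:
    return {
        "lattice": asdict(config.lattice),
        "kinetics": asdict(config.params),
        "solution": asdict(config.solution),
        "simulation": {
            "end": config.end,
            "duration": config.duration,
            "n_replicates": config.n_replicates,
            "record_interval": config.record_interval,
            "rng_seed": config.rng_seed,
            "seed_layers": config.seed_layers,
        },
    }


def config_from_dict(doc: dict) -> SimConfig:
    lattice = LatticeParams(**doc.get("lattice", {}))
    params = KineticParams(**doc.get("kinetics", {}))
    sol_doc = doc.get("solution", {"tubulin_total": 1.25})
    if "frac_gdp_tubulin" in sol_doc and "gdp_conc" not in sol_doc:
        solution = SolutionState.from_gdp_tubulin_fraction(
            sol_doc["tubulin_total"], sol_doc["frac_gdp_tubulin"], params.affinity_ratio
        )
    else:
        solution = SolutionState(**sol_doc)
    sim = doc.get("simulation", {})
    return SimConfig(params=params, solution=solution, lattice=lattice, **sim)


def save_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path, **overrides) -> SimConfig:
    """Load a YAML run configuration; keyword overrides win over the file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if overrides:
        doc = dict(doc)
        sim = dict(doc.get("simulation", {}))
        for key, value in overrides.items():
            if value is None:
                continue
            sim[key] = value
        doc["simulation"] = sim
    return config_from_dict(doc)
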