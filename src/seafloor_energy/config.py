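"""Run configuration: YAML sections, defaults, and reproducibility metadata.

A run is fully described by a mapping with sections ``constants``,
``chemistry``, ``transport``, ``bioturbation`` and ``scenario``; any field
omitted falls back to the package default.  The effective (merged) config
is hashed and echoed into every output so a run can be reproduced exactly
from its own artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .cementation import GRAIN_SIZE_CLASSES, SedimentChemState
from .constants import FluidConstants, MineralKinetics, default_aragonite_kinetics

logger = logging.getLogger(__name__)

_SECTIONS = ("constants", "chemistry", "transport", "bioturbation", "scenario", "grid")

DEFAULTS: dict[str, dict[str, Any]] = {
    "constants": {
        "rho_w": 1025.0,
        "nu": 1.0e-6,
        "g": 9.81,
        "kappa": 0.41,
        "sigma": 0.283,
        "k": 0.113,
        "n_exp": 2.26,
        "M_c": 0.1,
        "rho_c": 2850.0,
        "r_f": 5.0,
    },
    "chemistry": {
        "Omega": [3.0, 10.0],
        "D": ["mud", "silt", "fine_sand", "sand", "coarse_sand"],
        "phi0": 0.4,
        "L": 0.05,
        "sphere_factor": 1.0,
    },
    "transport": {
        "H": 1.0,
        "q": "capacity",
        "A1": 0.3,
        "St_low": 30.0,
        "St_high": 75.0,
        "tau_star_c_mode": "brownlie",
        "capacity_coefficient": 0.05,
        "duty_cycle": 1.0,
    },
    "bioturbation": {
        "n_taxa_per_group": 8,
        "G_c": 1.0,
        "phi": 0.4,
        "rho_s": 2850.0,
        "scenario_model": "excavation",
    },
    "scenario": {
        "bio_model": "excavation",
        "Omega_t1": 3.0,
        "Omega_t2": 3.0,
        "biomass_factor": 1.0,
        "bodysize_factor": 1.0,
    },
    "grid": {
        "D_min": 1e-5,
        "D_max": 1e-2,
        "n_D": 40,
        "u_star_min": 1e-3,
        "u_star_max": 0.5,
        "n_u_star": 40,
    },
}


@dataclass
class RunConfig:
    """Merged, validated run configuration plus seed and provenance."""

    sections: dict[str, dict[str, Any]] = field(default_factory=dict)
    seed: int = 0

    @property
    def constants(self) -> dict[str, Any]:
        return self.sections["constants"]

    def __getitem__(self, key: str) -> dict[str, Any]:
        return self.sections[key]

    def mineral_kinetics(self) -> MineralKinetics:
        c = self.constants
        return MineralKinetics(
            sigma=c["sigma"], k=c["k"], n_exp=c["n_exp"],
            M_c=c["M_c"], rho_c=c["rho_c"], r_f=c["r_f"],
        )

    def fluid_constants(self) -> FluidConstants:
        c = self.constants
        return FluidConstants(rho_w=c["rho_w"], nu=c["nu"], g=c["g"], kappa=c["kappa"])

    def chem_state(self, Omega: float, D) -> SedimentChemState:
        ch = self.sections["chemistry"]
        return SedimentChemState(phi0=ch["phi0"], Omega=Omega, D=D, L=ch["L"])

    def config_hash(self) -> str:
        payload = json.dumps(self.sections, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def metadata(self) -> dict[str, str]:
        return {
            "version": __version__,
            "seed": str(self.seed),
            "config_hash": self.config_hash(),
        }

    def echo(self) -> None:
        """Log every effective parameter at run start."""
        logger.info("seafloor-energy %s  seed=%d  config=%s", __version__, self.seed, self.config_hash())
        for section in _SECTIONS:
            for key, value in self.sections.get(section, {}).items():
                logger.info("  [%s] %s = %r", section, key, value)


def load_config(path: str | Path | None = None, seed: int = 0, overrides: Mapping | None = None) -> RunConfig:
    """Load a YAML config and merge it over the package defaults.

    Unknown sections or keys are rejected with the offending field path so
    that typos never silently fall back to defaults.
    """
    user: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config root must be a mapping, got {type(user).__name__}")
    merged = {section: dict(values) for section, values in DEFAULTS.items()}
    for source in (user, overrides or {}):
        for section, values in source.items():
            if section == "seed":
                seed = int(values)
                continue
            if section not in merged:
                raise ValueError(f"unknown config section {section!r}; known: {_SECTIONS}")
            if not isinstance(values, Mapping):
                raise ValueError(f"config section {section!r} must be a mapping")
            for key, value in values.items():
                if key not in merged[section]:
                    raise ValueError(f"unknown config field {section}.{key}")
                merged[section][key] = value
    cfg = RunConfig(sections=merged, seed=seed)
    # fail fast on invalid physics
    cfg.mineral_kinetics()
    cfg.fluid_constants()
    return cfg


def resolve_grain_sizes(spec) -> list[float]:
    """Named classes and/or numbers → diameters in metres."""
    out = []
    for item in spec:
        if isinstance(item, str):
            if item not in GRAIN_SIZE_CLASSES:
                raise ValueError(f"unknown grain-size class {item!r}")
            out.append(GRAIN_SIZE_CLASSES[item])
        else:
            out.append(float(item))
    return out
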