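"""High-level runs behind the CLI: flux tables, distribution summaries, grids.

These functions are thin orchestration over the flux modules — every number
they emit equals a direct call to the corresponding flux function — plus
reproducibility metadata (version, seed, config hash) embedded as ``#``
comment lines in each CSV.
"""

from __future__ import annotations

import io
import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .balance import RatioGrid, cement_favorable_fraction, ratio_map
from .bioturbation import (
    BurrowerPopulation,
    flux_distributions,
    population_fluxes,
    read_reworking_table,
    synthesize_reworking_table,
)
from .cementation import cementation_energy_flux, resolve_grain_size
from .config import RunConfig, resolve_grain_sizes
from .constants import EnergyFlux
from .transport import FlowConditions, derive_transport, sediment_energy_flux

logger = logging.getLogger(__name__)

BIOTURBATION_LEVELS = ("none", "q25", "median", "q75")


def write_csv(df: pd.DataFrame, path, config: RunConfig, extra: dict | None = None) -> None:
    """Write a CSV with ``# key: value`` metadata lines above the header."""
    meta = dict(config.metadata())
    meta.update(extra or {})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def run_chem(config: RunConfig) -> pd.DataFrame:
    """Chemical flux for every configured (Ω, grain size) combination."""
    ch = config["chemistry"]
    omegas = list(ch["Omega"])
    if not omegas:
        raise ValueError("chemistry.Omega list must be nonempty")
    sizes = ch["D"]
    if not sizes:
        raise ValueError("chemistry.D list must be nonempty")
    kin = config.mineral_kinetics()
    rows = []
    for Om in omegas:
        for D in sizes:
            state = config.chem_state(Om, D)
            flux = cementation_energy_flux(state, kin, sphere_factor=ch["sphere_factor"])
            rows.append(
                {
                    "Omega": Om,
                    "grain_class": D if isinstance(D, str) else "",
                    "D_m": state.D,
                    "E_chem_J_m2_yr": flux.value,
                }
            )
    return pd.DataFrame(rows)


def run_transport_grid(config: RunConfig) -> pd.DataFrame:
    """Transport flux over the configured (D, u*) grid, long format."""
    D_axis, u_axis = grid_axes(config)
    tr = config["transport"]
    fluid = config.fluid_constants()
    rows = []
    for D in D_axis:
        for u in u_axis:
            flow = FlowConditions(
                u_star=u, D=D, H=tr["H"], q=tr["q"], A1=tr["A1"],
                rho_s=config.constants["rho_c"], duty_cycle=tr["duty_cycle"],
            )
            derived = derive_transport(
                flow, fluid,
                tau_star_c_mode=tr["tau_star_c_mode"],
                St_low=tr["St_low"], St_high=tr["St_high"],
                capacity_coefficient=tr["capacity_coefficient"],
            )
            flux = sediment_energy_flux(flow, derived, fluid, rho_carbonate=flow.rho_s)
            rows.append({"D_m": D, "u_star_m_s": u, "E_sed_J_m2_yr": flux.value})
    return pd.DataFrame(rows)


def load_or_synthesize_populations(config: RunConfig, table_path=None) -> list[BurrowerPopulation]:
    bio = config["bioturbation"]
    if table_path is not None:
        return read_reworking_table(table_path)
    return synthesize_reworking_table(
        seed=config.seed,
        n_taxa_per_group=bio["n_taxa_per_group"],
        phi=bio["phi"],
        rho_s=bio["rho_s"],
    )


def run_figure2(config: RunConfig, table_path=None) -> dict:
    """Quiet-water flux comparison: bioturbation box data vs chemical bands.

    Returns the per-group flux quantiles for both mechanical models, the
    chemical flux for every configured (Ω, grain-size) band, and the log10
    span of all fluxes together (``span_decades``) plus that of the
    bioturbation fluxes alone.
    """
    fluid = config.fluid_constants()
    pops = load_or_synthesize_populations(config, table_path)
    dist_rows = []
    bio_values = []
    for model in ("excavation", "crack_propagation"):
        values = population_fluxes(pops, model, fluid)
        if len(values):
            bio_values.append(values)
        # mode filtering is intended here: each endmember summarises the
        # groups it can describe
        for dist in flux_distributions(pops, model, fluid, warn_empty=False):
            dist_rows.append(
                {
                    "group": dist.group, "model": dist.model, "n": dist.n,
                    "min": dist.min, "q25": dist.q25, "median": dist.median,
                    "q75": dist.q75, "max": dist.max,
                }
            )
    distributions = pd.DataFrame(dist_rows)
    chem = run_chem(config)
    bio_all = np.concatenate(bio_values) if bio_values else np.array([])
    all_positive = np.concatenate([bio_all, chem["E_chem_J_m2_yr"].to_numpy()])
    all_positive = all_positive[all_positive > 0]
    bio_positive = bio_all[bio_all > 0]
    span = float(np.log10(all_positive.max() / all_positive.min())) if len(all_positive) else 0.0
    bio_span = (
        float(np.log10(bio_positive.max() / bio_positive.min())) if len(bio_positive) else 0.0
    )
    return {
        "populations": pops,
        "distributions": distributions,
        "chemical_bands": chem,
        "span_decades": span,
        "bioturbation_span_decades": bio_span,
    }


def grid_axes(config: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    g = config["grid"]
    D_axis = np.logspace(math.log10(g["D_min"]), math.log10(g["D_max"]), int(g["n_D"]))
    u_axis = np.logspace(
        math.log10(g["u_star_min"]), math.log10(g["u_star_max"]), int(g["n_u_star"])
    )
    return D_axis, u_axis


def bioturbation_level_fluxes(config: RunConfig, table_path=None) -> dict[str, float]:
    """Constant bioturbation fluxes for the none/q25/median/q75 scenarios.

    Quartiles are taken over the pooled distribution of the configured
    scenario model (excavation by default — the lower endmember, so the
    resulting maps understate rather than overstate animal influence).
    """
    fluid = config.fluid_constants()
    pops = load_or_synthesize_populations(config, table_path)
    model = config["bioturbation"]["scenario_model"]
    values = population_fluxes(pops, model, fluid)
    if len(values) == 0:
        raise ValueError(f"no taxa support the {model} model")
    q25, med, q75 = np.percentile(values, [25, 50, 75])
    return {"none": 0.0, "q25": float(q25), "median": float(med), "q75": float(q75)}


def run_figure3(config: RunConfig, table_path=None, Omega: float | None = None) -> dict[str, RatioGrid]:
    """Ratio maps for the four bioturbation scenarios, sharing one grid.

    The cementation-favorable cell count is nonincreasing through
    none → q25 → median → q75 because the numerator only grows.
    """
    D_axis, u_axis = grid_axes(config)
    ch = config["chemistry"]
    omega = Omega if Omega is not None else max(ch["Omega"]) if isinstance(ch["Omega"], list) else ch["Omega"]
    if omega <= 1:
        raise ValueError("figure-3 grids need Omega > 1")
    chem_template = config.chem_state(omega, D_axis[0])
    tr = config["transport"]
    flow_template = FlowConditions(
        u_star=0.0, D=D_axis[0], H=tr["H"], q=tr["q"], A1=tr["A1"],
        rho_s=config.constants["rho_c"], duty_cycle=tr["duty_cycle"],
    )
    levels = bioturbation_level_fluxes(config, table_path)
    kin = config.mineral_kinetics()
    fluid = config.fluid_constants()
    grids: dict[str, RatioGrid] = {}
    for level in BIOTURBATION_LEVELS:
        grids[level] = ratio_map(
            D_axis, u_axis, chem_template,
            bio_flux=levels[level], kin=kin, fluid=fluid,
            flow_template=flow_template, bioturbation_level=level,
            tau_star_c_mode=tr["tau_star_c_mode"],
            St_low=tr["St_low"], St_high=tr["St_high"],
            capacity_coefficient=tr["capacity_coefficient"],
        )
    fractions = {lvl: cement_favorable_fraction(g) for lvl, g in grids.items()}
    logger.info("cementation-favorable fractions: %s", fractions)
    return grids


def ratio_grid_frame(grid: RatioGrid) -> pd.DataFrame:
    """Long-format DataFrame of a ratio grid (axes echoed per row)."""
    D, U = np.meshgrid(grid.D_axis, grid.u_star_axis, indexing="ij")
    return pd.DataFrame(
        {
            "D_m": D.ravel(),
            "u_star_m_s": U.ravel(),
            "E_sed_J_m2_yr": grid.E_sed.ravel(),
            "E_chem_J_m2_yr": np.repeat(grid.E_chem, len(grid.u_star_axis)),
            "ratio": grid.ratio.ravel(),
        }
    )
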