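"""Energy balance, regime maps and scenario algebra.

The sign of dG_int/dt = dE_sed/dt + dE_bio/dt − dE_chem/dt expresses
whether a seafloor patch trends toward mobility (positive: physical energy
dislodges nascent cements) or cohesion (negative: cementation wins).
Ratio maps over (grain size, shear velocity) grids locate the 1:1 line
between the two regimes; the quiet-water ratio F = E_bio/E_chem and its
change ΔF = F_t2/F_t1 quantify how perturbations to seawater chemistry,
biomass or body size move substrates toward or away from stability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .bioturbation import BurrowerPopulation, crack_flux, excavation_flux
from .cementation import SedimentChemState, cementation_energy_flux
from .constants import EnergyFlux, FluidConstants, MineralKinetics, default_aragonite_kinetics
from .transport import FlowConditions, derive_transport, sediment_energy_flux

__all__ = [
    "EnergyBudget",
    "RatioGrid",
    "ScenarioResult",
    "energy_balance",
    "ratio_map",
    "cement_favorable_fraction",
    "quietwater_F",
    "scenario_deltaF",
]


def _magnitude(flux: EnergyFlux | float) -> float:
    v = flux.value if isinstance(flux, EnergyFlux) else float(flux)
    if v < 0:
        raise ValueError(f"flux magnitudes must be nonnegative, got {v}")
    return v


@dataclass(frozen=True)
class EnergyBudget:
    """The three flux magnitudes and the signed balance dG_int/dt.

    Positive ``dGint_dt`` → physical energy wins, cohesion inhibited;
    negative → cementation favored.
    """

    E_sed: float
    E_bio: float
    E_chem: float
    dGint_dt: float


@dataclass(frozen=True)
class RatioGrid:
    """Physical-to-chemical energy ratios over a (D, u*) grid.

    ``ratio[i, j]`` = (E_sed(D_i, u*_j) + E_bio)/E_chem(D_i); rows follow
    the grain-size axis, columns the shear-velocity axis.
    """

    D_axis: np.ndarray
    u_star_axis: np.ndarray
    ratio: np.ndarray
    E_sed: np.ndarray
    E_chem: np.ndarray
    bio_flux: float
    bioturbation_level: str = "none"

    def __post_init__(self) -> None:
        if self.ratio.shape != (len(self.D_axis), len(self.u_star_axis)):
            raise ValueError("ratio matrix shape does not match axes")
        if np.any(self.ratio < 0):
            raise ValueError("ratios must be nonnegative")


@dataclass(frozen=True)
class ScenarioResult:
    """Quiet-water scenario outcome: F at two times and their ratio ΔF."""

    F_t1: float
    F_t2: float
    delta_F: float
    perturbations: dict


def energy_balance(
    E_sed: EnergyFlux | float,
    E_bio: EnergyFlux | float,
    E_chem: EnergyFlux | float,
) -> EnergyBudget:
    """Signed energy balance dG_int/dt = E_sed + E_bio − E_chem."""
    s, b, c = _magnitude(E_sed), _magnitude(E_bio), _magnitude(E_chem)
    return EnergyBudget(E_sed=s, E_bio=b, E_chem=c, dGint_dt=s + b - c)


def ratio_map(
    D_axis: Sequence[float],
    u_star_axis: Sequence[float],
    chem_template: SedimentChemState,
    bio_flux: EnergyFlux | float = 0.0,
    kin: MineralKinetics | None = None,
    fluid: FluidConstants | None = None,
    flow_template: FlowConditions | None = None,
    bioturbation_level: str = "custom",
    **transport_kwargs,
) -> RatioGrid:
    """Physical-to-chemical ratio over a grain-size × shear-velocity grid.

    Grain size enters both sides of the ratio: it sets the transport flux
    (threshold of motion, damping, capacity) in the numerator and the
    specific surface area — hence the chemical flux — in the denominator.
    A constant bioturbation flux is added to the numerator everywhere,
    which puts a floor under the ratio even where transport is zero.
    Ω = 1 would make every ratio infinite and is rejected.
    """
    kin = kin or default_aragonite_kinetics()
    fluid = fluid or FluidConstants()
    D_axis = np.asarray(D_axis, dtype=float)
    u_star_axis = np.asarray(u_star_axis, dtype=float)
    if np.any(np.diff(D_axis) <= 0) or np.any(np.diff(u_star_axis) <= 0):
        raise ValueError("grid axes must be strictly increasing")
    if chem_template.Omega <= 1:
        raise ValueError(
            "Omega must exceed 1 for a ratio map (Omega = 1 gives zero chemical "
            "flux and infinite ratios everywhere)"
        )
    bio = _magnitude(bio_flux)
    if flow_template is None:
        flow_template = FlowConditions(u_star=0.0, D=D_axis[0])

    E_chem = np.empty(len(D_axis))
    for i, D in enumerate(D_axis):
        state = replace_state(chem_template, D=D)
        E_chem[i] = cementation_energy_flux(state, kin).value
    E_sed = np.empty((len(D_axis), len(u_star_axis)))
    for i, D in enumerate(D_axis):
        for j, u in enumerate(u_star_axis):
            flow = replace(flow_template, u_star=float(u), D=float(D))
            derived = derive_transport(flow, fluid, **transport_kwargs)
            E_sed[i, j] = sediment_energy_flux(
                flow, derived, fluid, rho_carbonate=flow.rho_s
            ).value
    ratio = (E_sed + bio) / E_chem[:, None]
    return RatioGrid(
        D_axis=D_axis,
        u_star_axis=u_star_axis,
        ratio=ratio,
        E_sed=E_sed,
        E_chem=E_chem,
        bio_flux=bio,
        bioturbation_level=bioturbation_level,
    )


def replace_state(template: SedimentChemState, **kwargs) -> SedimentChemState:
    """A copy of a chemical state with some fields replaced."""
    base = dict(
        phi0=template.phi0, Omega=template.Omega, D=template.D, L=template.L,
        V_t=template.V_t, V_c=template.V_c, V_c0=template.V_c0,
        A0=template.A0, phi=template.phi,
    )
    base.update(kwargs)
    return SedimentChemState(**base)


def cement_favorable_fraction(grid: RatioGrid, threshold: float = 1.0) -> float:
    """Fraction of grid cells with ratio below the 1:1 line (cohesion wins)."""
    return float(np.mean(grid.ratio < threshold))


def quietwater_F(E_bio: EnergyFlux | float, E_chem: EnergyFlux | float) -> float:
    """Quiet-water physical-to-chemical ratio F = E_bio/E_chem."""
    b, c = _magnitude(E_bio), _magnitude(E_chem)
    if c <= 0:
        raise ValueError("chemical flux must be > 0 to form the ratio F")
    return b / c


def scenario_deltaF(
    population: BurrowerPopulation,
    chem_state: SedimentChemState,
    kin: MineralKinetics | None = None,
    fluid: FluidConstants | None = None,
    bio_model: str = "excavation",
    Omega: tuple[float, float] | None = None,
    biomass_factor: float = 1.0,
    bodysize_factor: float = 1.0,
    couple_R_to_bodysize: bool = False,
    couple_depth_to_bodysize: bool = False,
) -> ScenarioResult:
    """ΔF = F_t2/F_t1 for named single- or multi-channel perturbations.

    Channels (each a multiplier applied between time 1 and time 2):

    * ``Omega=(Ω₁, Ω₂)`` — porewater chemistry; scales the chemical flux by
      ((Ω₂−1)/(Ω₁−1))^n through the rate law, so F scales by the inverse.
    * ``biomass_factor`` — multiplies the reworking rate R; F responds
      linearly (both bioturbation models are linear in R).
    * ``bodysize_factor`` — multiplies the burrow radius b.  The crack
      model scales as 1/b; the excavation model is insensitive to b unless
      depth (``couple_depth_to_bodysize``) or R
      (``couple_R_to_bodysize``) is coupled to body size.

    Fluxes are recomputed through the flux formulas at both times, so the
    channels compose multiplicatively (the model is separable).
    """
    kin = kin or default_aragonite_kinetics()
    fluid = fluid or FluidConstants()
    if bio_model not in ("excavation", "crack_propagation"):
        raise ValueError("bio_model must be 'excavation' or 'crack_propagation'")
    if biomass_factor <= 0 or bodysize_factor <= 0:
        raise ValueError("perturbation factors must be > 0")
    Omega1 = chem_state.Omega if Omega is None else Omega[0]
    Omega2 = chem_state.Omega if Omega is None else Omega[1]
    if Omega1 <= 1 or Omega2 <= 1:
        raise ValueError("Omega must exceed 1 at both times")

    def bio_flux_at(R: float, b: float, d: float) -> float:
        p = replace(population, R=R, b=b, d=d)
        if bio_model == "excavation":
            return excavation_flux(p, fluid).value
        return crack_flux(p).value

    def chem_flux_at(Om: float) -> float:
        return cementation_energy_flux(replace_state(chem_state, Omega=Om), kin).value

    R2 = population.R * biomass_factor
    b2 = population.b * bodysize_factor
    d2 = population.d
    if couple_R_to_bodysize:
        R2 *= bodysize_factor
    if couple_depth_to_bodysize:
        d2 *= bodysize_factor

    F1 = quietwater_F(bio_flux_at(population.R, population.b, population.d), chem_flux_at(Omega1))
    F2 = quietwater_F(bio_flux_at(R2, b2, d2), chem_flux_at(Omega2))
    perturbations = {
        "Omega": (Omega1, Omega2),
        "biomass_factor": biomass_factor,
        "bodysize_factor": bodysize_factor,
        "bio_model": bio_model,
        "couple_R_to_bodysize": couple_R_to_bodysize,
        "couple_depth_to_bodysize": couple_depth_to_bodysize,
    }
    return ScenarioResult(F_t1=F1, F_t2=F2, delta_F=F2 / F1, perturbations=perturbations)
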