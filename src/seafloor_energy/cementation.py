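"""Chemical energy flux from carbonate cementation.

Cementation binds loose grains into cohesive substrates.  Thermodynamically
it is a loss of interfacial free energy: precipitating cement fills pore
space and reduces the mineral–fluid surface area A, so G_int = σA falls.
The rate of that loss — per unit area of seafloor and per year — is the
"chemical" flux that sediment transport and bioturbation must outpace to
keep the bed mobile.

The chain is: a geometric specific surface area set by grain diameter, a
power-law precipitation rate in the saturation state Ω, a surface-area /
porosity closure, and a vertical observation window L (taken as the depth
of active bioturbation) that converts a volumetric energy-change rate into
an area-normalised one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .constants import EnergyFlux, MineralKinetics, default_aragonite_kinetics

__all__ = [
    "GRAIN_SIZE_CLASSES",
    "SedimentChemState",
    "specific_surface_area",
    "precipitation_volume_rate",
    "surface_area_from_porosity",
    "surface_area_rate",
    "cementation_energy_flux",
]

#: Named grain-size classes [m] accepted wherever a diameter is configured.
GRAIN_SIZE_CLASSES = {
    "mud": 4e-6,
    "silt": 20e-6,
    "fine_sand": 125e-6,
    "sand": 250e-6,
    "coarse_sand": 500e-6,
}


def resolve_grain_size(D) -> float:
    """Map a named grain-size class or a numeric diameter to metres."""
    if isinstance(D, str):
        try:
            return GRAIN_SIZE_CLASSES[D]
        except KeyError:
            raise ValueError(
                f"unknown grain-size class {D!r}; known: {sorted(GRAIN_SIZE_CLASSES)}"
            ) from None
    D = float(D)
    if D <= 0 or not math.isfinite(D):
        raise ValueError(f"grain diameter must be finite and > 0, got {D}")
    return D


@dataclass
class SedimentChemState:
    """Porewater/sediment state from which the chemical flux is computed.

    Required: initial porosity ``phi0`` (0–1), saturation state ``Omega``
    (≥ 1 for the precipitation branch), grain diameter ``D`` [m] (or a named
    class), and the vertical observation length ``L`` [m].

    The optional volume/surface fields (``V_t``, ``V_c``, ``V_c0``, ``A0``,
    ``phi``) describe a partially cemented state and are only needed by the
    time-evolution operator :func:`surface_area_rate`.
    """

    phi0: float
    Omega: float
    D: float
    L: float = 0.05
    # evolution fields (optional)
    V_t: Optional[float] = None
    V_c: Optional[float] = None
    V_c0: Optional[float] = None
    A0: Optional[float] = None
    phi: Optional[float] = None

    def __post_init__(self) -> None:
        self.D = resolve_grain_size(self.D)
        if not (0 < self.phi0 < 1):
            raise ValueError(f"initial porosity must lie in (0, 1), got {self.phi0}")
        if self.Omega < 0 or not math.isfinite(self.Omega):
            raise ValueError(f"saturation state must be finite and >= 0, got {self.Omega}")
        if self.L <= 0:
            raise ValueError(f"observation length L must be > 0, got {self.L}")


def specific_surface_area(
    D, kin: MineralKinetics | None = None, sphere_factor: float = 1.0
) -> float:
    """Geometric specific surface area A_sp = r_f·sphere_factor/(ρ_c·D) [m² kg⁻¹].

    The surface-to-volume ratio of a grain scales inversely with its
    diameter; the roughness factor r_f accounts for microscale texture.
    ``sphere_factor`` exposes the alternative convention that carries the
    sphere's 6/D surface-to-volume ratio explicitly (default 1, i.e. the
    bare inverse-diameter model).
    """
    kin = kin or default_aragonite_kinetics()
    D = resolve_grain_size(D)
    if sphere_factor <= 0:
        raise ValueError("sphere_factor must be > 0")
    return kin.r_f * sphere_factor / (kin.rho_c * D)


def precipitation_volume_rate(A: float, Omega: float, kin: MineralKinetics | None = None) -> float:
    """Volumetric precipitation rate dV_c/dt = k(Ω−1)^n (M_c/ρ_c) A [m³ yr⁻¹].

    Only the precipitation branch (Ω ≥ 1) is modelled; undersaturated
    porewaters raise a domain error rather than returning a dissolution
    rate.
    """
    kin = kin or default_aragonite_kinetics()
    if A < 0:
        raise ValueError(f"surface area must be >= 0, got {A}")
    if Omega < 1:
        raise ValueError(
            f"saturation state {Omega} < 1: dissolution is outside the model domain"
        )
    return kin.k * (Omega - 1.0) ** kin.n_exp * (kin.M_c / kin.rho_c) * A


def surface_area_from_porosity(A0: float, phi: float, phi0: float) -> float:
    """Surface area of a cementing bed, A = A0 (φ/φ0)^(2/3).

    Valid while cementation closes pore space, i.e. 0 < φ ≤ φ0.
    """
    if not (0 < phi0 < 1):
        raise ValueError(f"initial porosity must lie in (0, 1), got {phi0}")
    if not (0 < phi <= phi0):
        raise ValueError(
            f"porosity {phi} must lie in (0, {phi0}]: cementation only reduces porosity"
        )
    if A0 < 0:
        raise ValueError("initial surface area must be >= 0")
    return A0 * (phi / phi0) ** (2.0 / 3.0)


def surface_area_rate(state: SedimentChemState, kin: MineralKinetics | None = None) -> float:
    """Rate of surface-area loss dA/dt [m² yr⁻¹] for a partially cemented bed.

    dA/dt = −(2/3)·(A0²/(φ0·V_t))·[(V_t−V_c)/(V_t−V_c0)]^(1/3)·(M_c/ρ_c)·k(Ω−1)^n

    The bracketed attenuation term is 1 at the onset of cementation
    (V_c = V_c0, maximal |dA/dt|) and falls to 0 as the pores fill
    (V_c → V_t).  The result is ≤ 0: precipitation destroys surface area.
    """
    kin = kin or default_aragonite_kinetics()
    for name in ("V_t", "V_c", "V_c0", "A0"):
        if getattr(state, name) is None:
            raise ValueError(f"surface_area_rate requires state.{name}")
    V_t, V_c, V_c0, A0 = state.V_t, state.V_c, state.V_c0, state.A0
    if not (V_c0 <= V_c < V_t):
        raise ValueError(
            f"carbonate volume must satisfy V_c0 <= V_c < V_t, got "
            f"V_c0={V_c0}, V_c={V_c}, V_t={V_t}"
        )
    if state.Omega < 1:
        raise ValueError("dissolution (Omega < 1) is outside the model domain")
    bracket = ((V_t - V_c) / (V_t - V_c0)) ** (1.0 / 3.0)
    rate = kin.k * (state.Omega - 1.0) ** kin.n_exp * (kin.M_c / kin.rho_c)
    return -(2.0 / 3.0) * (A0**2 / (state.phi0 * V_t)) * bracket * rate


def cementation_energy_flux(
    state: SedimentChemState,
    kin: MineralKinetics | None = None,
    sphere_factor: float = 1.0,
) -> EnergyFlux:
    """Chemical energy flux magnitude [J m⁻² yr⁻¹] at the onset of cementation.

    |dE_chem/dt| = (2/3)·σ·(A_sp(1−φ0))²/φ0 · ρ_c·M_c·k(Ω−1)^n · L

    This is the maximum-rate case (V_c = V_c0, attenuation bracket = 1);
    later stages of cementation are slower and can be followed with
    :func:`surface_area_rate`.  Returned as a magnitude with
    ``source="chemical"`` — the sign is applied in the energy balance.
    """
    kin = kin or default_aragonite_kinetics()
    if state.Omega < 1:
        raise ValueError(
            f"saturation state {state.Omega} < 1: dissolution is outside the model domain"
        )
    A_sp = specific_surface_area(state.D, kin, sphere_factor=sphere_factor)
    magnitude = (
        (2.0 / 3.0)
        * kin.sigma
        * (A_sp * (1.0 - state.phi0)) ** 2
        / state.phi0
        * kin.rho_c
        * kin.M_c
        * kin.k
        * (state.Omega - 1.0) ** kin.n_exp
        * state.L
    )
    return EnergyFlux(value=magnitude, source="chemical")
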