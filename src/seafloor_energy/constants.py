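"""Physical constants, mineral-kinetic parameter sets, and unit conventions.

Every energy flux in this package is expressed per unit area of seafloor per
unit *year* (J m⁻² yr⁻¹), matching the yearly precipitation rate constant of
the aragonite kinetics.  Hydraulic submodels naturally work in seconds; they
convert at the flux boundary through :func:`to_per_year` so that the three
competing fluxes (chemical, transport, bioturbation) are commensurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "SECONDS_PER_YEAR",
    "MineralKinetics",
    "FluidConstants",
    "EnergyFlux",
    "default_aragonite_kinetics",
    "to_per_year",
    "to_per_second",
]

#: Conversion between per-second and per-year rates [s yr⁻¹].
SECONDS_PER_YEAR = 3.156e7

#: The three recognised flux sources.
FLUX_SOURCES = ("chemical", "transport", "bioturbation")


@dataclass(frozen=True)
class MineralKinetics:
    """Kinetic and thermodynamic constants of a carbonate phase.

    Parameters
    ----------
    sigma : float
        Specific interfacial free energy of the mineral–fluid contact
        [J m⁻²].
    k : float
        Precipitation rate constant of the power-law rate law
        ``rate = k (Ω − 1)^n`` [mol m⁻² yr⁻¹].
    n_exp : float
        Rate-law exponent [-]; ≥ 1 for the supersaturation-driven branch.
    M_c : float
        Molar mass of the carbonate phase [kg mol⁻¹].
    rho_c : float
        Density of the carbonate phase [kg m⁻³].
    r_f : float
        Surface roughness factor [-]; multiplies the smooth-grain specific
        surface area (≥ 1).
    """

    sigma: float
    k: float
    n_exp: float
    M_c: float
    rho_c: float
    r_f: float

    def __post_init__(self) -> None:
        for name in ("sigma", "k", "n_exp", "M_c", "rho_c", "r_f"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"MineralKinetics.{name} must be finite and > 0, got {v}")
        if self.n_exp < 1:
            raise ValueError(f"rate-law exponent n_exp must be >= 1, got {self.n_exp}")
        if self.r_f < 1:
            raise ValueError(f"roughness factor r_f must be >= 1, got {self.r_f}")

    def replace(self, **kwargs) -> "MineralKinetics":
        return replace(self, **kwargs)


def default_aragonite_kinetics() -> MineralKinetics:
    """Aragonite parameter set: σ = 0.283 J m⁻², k = 0.113 mol m⁻² yr⁻¹,
    n = 2.26, M = 0.1 kg mol⁻¹, ρ = 2850 kg m⁻³ and a roughness factor of 5
    (appropriate for both shallow- and deep-water carbonate sediments)."""
    return MineralKinetics(sigma=0.283, k=0.113, n_exp=2.26, M_c=0.1, rho_c=2850.0, r_f=5.0)


@dataclass(frozen=True)
class FluidConstants:
    """Seawater and gravity constants used by the hydraulic submodels.

    ``rho_w`` [kg m⁻³], kinematic viscosity ``nu`` [m² s⁻¹], gravitational
    acceleration ``g`` [m s⁻²], von Kármán constant ``kappa`` [-], and the
    seconds-per-year conversion.
    """

    rho_w: float = 1025.0
    nu: float = 1.0e-6
    g: float = 9.81
    kappa: float = 0.41
    seconds_per_year: float = SECONDS_PER_YEAR

    def __post_init__(self) -> None:
        for name in ("rho_w", "nu", "g", "kappa", "seconds_per_year"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"FluidConstants.{name} must be finite and > 0, got {v}")
        if not (0.3 < self.kappa < 0.5):
            raise ValueError(f"von Karman constant should lie in (0.3, 0.5), got {self.kappa}")

    def replace(self, **kwargs) -> "FluidConstants":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class EnergyFlux:
    """An area-normalised energy flux [J m⁻² yr⁻¹] tagged with its source.

    Values are stored as nonnegative magnitudes; the chemical flux acquires
    its negative sign only inside the energy balance, where cementation
    *consumes* mineral surface area while the physical fluxes create it.
    """

    value: float
    source: str

    def __post_init__(self) -> None:
        if self.source not in FLUX_SOURCES:
            raise ValueError(f"unknown flux source {self.source!r}; expected one of {FLUX_SOURCES}")
        if not math.isfinite(self.value) or self.value < 0:
            raise ValueError(f"flux magnitude must be finite and >= 0, got {self.value}")


def to_per_year(
    flux_per_second: float,
    source: str = "transport",
    seconds_per_year: float = SECONDS_PER_YEAR,
) -> EnergyFlux:
    """Convert a J m⁻² s⁻¹ flux into an :class:`EnergyFlux` in J m⁻² yr⁻¹."""
    if not math.isfinite(flux_per_second):
        raise ValueError(f"flux must be finite, got {flux_per_second}")
    return EnergyFlux(value=flux_per_second * seconds_per_year, source=source)


def to_per_second(
    flux_per_year: float, seconds_per_year: float = SECONDS_PER_YEAR
) -> float:
    """Inverse of :func:`to_per_year`: J m⁻² yr⁻¹ → J m⁻² s⁻¹."""
    if not math.isfinite(flux_per_year):
        raise ValueError(f"flux must be finite, got {flux_per_year}")
    return flux_per_year / seconds_per_year
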