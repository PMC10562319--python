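"""Gas species, mass fluxes, CO2-equivalent conversion and uncertainty algebra.

All flux accounting in the package runs through this module. The canonical
internal mass unit is Gg of gas per year; Tg and Mg appear only at I/O.
Sign convention: emission to the atmosphere is positive, sequestration
(uptake from the atmosphere) is negative.

Uncertainties are carried as non-negative half-widths ("sd") and combined in
quadrature (root sum of squares), which treats components as independent.
Where an externally derived uncertainty exists for a net flux (e.g. a
Monte-Carlo interval for a forest net balance), it can be supplied as an
override and is carried through unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GasSpecies",
    "GasFlux",
    "Co2eqFlux",
    "SPECIES",
    "CO2",
    "CH4",
    "N2O",
    "get_species",
    "element_to_gas",
    "to_co2eq",
    "net_flux",
    "combine_uncertainty",
]

# AR5 100-year global warming potentials.
GWP100 = {"CO2": 1.0, "CH4": 28.0, "N2O": 265.0}

# Integer molar masses (g/mol), standard inventory practice.
MOLAR_MASS_GAS = {"CO2": 44.0, "CH4": 16.0, "N2O": 44.0}
MOLAR_MASS_ELEMENT = {"C": 12.0, "N": 14.0}

# Unit scale factors relative to the canonical Gg yr^-1.
_UNIT_TO_GG = {"Gg": 1.0, "Tg": 1000.0, "Mg": 1e-3}


@dataclass(frozen=True)
class GasSpecies:
    """A greenhouse-gas species with its warming potential and stoichiometry.

    ``element`` is the inventory element the gas carries (C for CO2/CH4,
    N for N2O) and ``element_atoms`` how many atoms of it one molecule
    contains (2 for N2O).
    """

    name: str
    gwp100: float
    molar_mass: float
    element: str
    element_atoms: int = 1

    @property
    def element_molar_mass(self) -> float:
        return MOLAR_MASS_ELEMENT[self.element]

    def gas_per_element(self) -> float:
        """Mass of gas produced per unit mass of its element.

        CO2: 44/12, CH4: 16/12, N2O: 44/(2*14) = 44/28.
        """
        return self.molar_mass / (self.element_atoms * self.element_molar_mass)


CO2 = GasSpecies("CO2", GWP100["CO2"], MOLAR_MASS_GAS["CO2"], "C", 1)
CH4 = GasSpecies("CH4", GWP100["CH4"], MOLAR_MASS_GAS["CH4"], "C", 1)
N2O = GasSpecies("N2O", GWP100["N2O"], MOLAR_MASS_GAS["N2O"], "N", 2)

SPECIES = {s.name: s for s in (CO2, CH4, N2O)}


def get_species(name: str) -> GasSpecies:
    try:
        return SPECIES[name]
    except KeyError:
        raise KeyError(f"unknown gas species {name!r}; expected one of {sorted(SPECIES)}")


def _to_gg(value: float, unit: str) -> float:
    try:
        return value * _UNIT_TO_GG[unit]
    except KeyError:
        raise ValueError(f"unknown mass unit {unit!r}; expected one of {sorted(_UNIT_TO_GG)}")


@dataclass(frozen=True)
class GasFlux:
    """A mass flux of one gas, in Gg gas yr^-1, with uncertainty half-width."""

    species: GasSpecies
    value: float  # Gg yr^-1, emission positive
    sd: float = 0.0  # Gg yr^-1, >= 0

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")

    @classmethod
    def from_unit(cls, species: GasSpecies, value: float, sd: float = 0.0, unit: str = "Gg") -> "GasFlux":
        return cls(species, _to_gg(value, unit), _to_gg(sd, unit))

    def in_unit(self, unit: str) -> tuple[float, float]:
        f = _UNIT_TO_GG[unit]
        return self.value / f, self.sd / f

    def scaled(self, a: float) -> "GasFlux":
        return GasFlux(self.species, a * self.value, abs(a) * self.sd)

    def __add__(self, other: "GasFlux") -> "GasFlux":
        if other == 0:
            return self
        if self.species is not other.species and self.species != other.species:
            raise ValueError(
                f"cannot add fluxes of {self.species.name} and {other.species.name}"
            )
        return GasFlux(
            self.species,
            self.value + other.value,
            math.hypot(self.sd, other.sd),
        )

    __radd__ = __add__


@dataclass(frozen=True)
class Co2eqFlux:
    """A CO2-equivalent flux in Gg CO2eq yr^-1 (emission positive)."""

    value: float
    sd: float = 0.0

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")

    @property
    def value_tg(self) -> float:
        return self.value / 1000.0

    @property
    def sd_tg(self) -> float:
        return self.sd / 1000.0

    @classmethod
    def from_tg(cls, value: float, sd: float = 0.0) -> "Co2eqFlux":
        return cls(value * 1000.0, sd * 1000.0)

    def scaled(self, a: float) -> "Co2eqFlux":
        return Co2eqFlux(a * self.value, abs(a) * self.sd)

    def with_sd(self, sd: float) -> "Co2eqFlux":
        """Replace the uncertainty with an externally supplied half-width."""
        return Co2eqFlux(self.value, sd)

    def __add__(self, other):
        if other == 0:
            return self
        return Co2eqFlux(self.value + other.value, math.hypot(self.sd, other.sd))

    __radd__ = __add__

    def __neg__(self):
        return Co2eqFlux(-self.value, self.sd)


def element_to_gas(element_mass: float, species: GasSpecies, sd: float = 0.0,
                   element: str | None = None) -> GasFlux:
    """Convert an elemental mass flux (Gg C or N yr^-1) to a gas flux.

    The mass is scaled by the molar-mass ratio of the gas to its element
    (C->CO2 x44/12, C->CH4 x16/12, N->N2O x44/28); the uncertainty scales by
    the same factor. If ``element`` is given it must match the species'
    element.
    """
    if element is not None and element != species.element:
        raise ValueError(
            f"element {element!r} does not match species {species.name} "
            f"(carries {species.element!r})"
        )
    r = species.gas_per_element()
    return GasFlux(species, element_mass * r, abs(sd) * r)


def to_co2eq(flux: GasFlux) -> Co2eqFlux:
    """Express a gas flux as CO2-equivalents using GWP100. Sign preserved."""
    g = flux.species.gwp100
    return Co2eqFlux(flux.value * g, flux.sd * g)


def combine_uncertainty(components: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Sum component (value, sd) pairs; combined sd is the root sum of squares.

    Raises on any negative sd.
    """
    total = 0.0
    ss = 0.0
    for value, sd in components:
        if sd < 0:
            raise ValueError(f"negative sd {sd} in uncertainty combination")
        total += value
        ss += sd * sd
    return total, math.sqrt(ss)


def net_flux(emission: Co2eqFlux, sequestration: Co2eqFlux,
             sd_override: float | None = None) -> Co2eqFlux:
    """Net emission = emission minus the sequestration magnitude.

    ``sequestration`` may be supplied as a negative flux (internal
    convention) or as a positive magnitude; either way its absolute value is
    subtracted. The combined sd is quadrature of the two components unless
    ``sd_override`` supplies an externally derived half-width (used where a
    net uncertainty comes from Monte-Carlo analysis rather than quadrature).
    """
    value = emission.value - abs(sequestration.value)
    sd = math.hypot(emission.sd, sequestration.sd)
    if sd_override is not None:
        if sd_override < 0:
            raise ValueError("sd_override must be >= 0")
        sd = sd_override
    return Co2eqFlux(value, sd)
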