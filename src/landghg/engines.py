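"""Per-subcategory flux engines and proxy-based spatial allocation.

Every engine is a linear map from areas (or activity totals) to gas fluxes:
flux = area x coefficient, sd = area x coefficient sd. Areas are treated as
exact — the uncertainty carried forward is the emission-coefficient
uncertainty only (a config switch on :class:`CoefficientTable` lookups can
add area sds for sensitivity studies, off by default).

Coefficient tables are pure data: engines never hard-code a coefficient.
Rows may be expressed on an elemental basis (mass of C or N per km2 per yr)
and are converted to gas mass through the molar-mass ratio before use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gases import (CH4, CO2, N2O, Co2eqFlux, GasFlux, combine_uncertainty,
                    element_to_gas, get_species, to_co2eq)

__all__ = [
    "CoefficientTable",
    "coefficient_flux",
    "lake_emissions",
    "river_area",
    "river_emissions",
    "mire_fluxes",
    "derive_mire_co2_coefficient",
    "drained_peat_soil_fluxes",
    "harvest_emissions",
    "peat_production_emissions",
    "allocate_by_proxy",
]

NARROW_RIVER_WIDTH_KM = 0.0035  # 3.5 m average width for rivers mapped as lines

# Coefficient unit -> factor to canonical Gg gas km^-2 yr^-1.
_COEF_UNIT_TO_GG_KM2 = {
    "Gg/km2": 1.0,
    "Mg/km2": 1e-3,
    "t/km2": 1e-3,
    "g/m2": 1e-3,  # 1 g m^-2 yr^-1 == 1 Mg km^-2 yr^-1
}


@dataclass
class CoefficientTable:
    """Area-based emission coefficients per (subcategory, gas, term, zone).

    Columns: category, subcategory, gas, term, zone, value, sd, unit, basis.
    ``term`` distinguishes multiple flux pathways of one subcategory (lake
    CO2 evasion vs CH4 diffusion vs ebullition; mire soil flux vs ecosystem
    net); plain single-pathway rows use term "flux". ``zone`` is southern /
    northern / national; a zonal lookup falls back to the national row.
    ``basis`` is "gas" or an element symbol (C, N) for rows stated as
    elemental mass, converted on lookup.
    """

    table: pd.DataFrame

    REQUIRED = ("category", "subcategory", "gas", "term", "zone", "value", "sd", "unit", "basis")

    def __post_init__(self):
        df = self.table.copy()
        for col, default in (("term", "flux"), ("zone", "national"),
                             ("sd", 0.0), ("unit", "Gg/km2"), ("basis", "gas")):
            if col not in df.columns:
                df[col] = default
        missing = set(self.REQUIRED) - set(df.columns)
        if missing:
            raise ValueError(f"coefficient table missing columns {sorted(missing)}")
        if (df["sd"] < 0).any():
            raise ValueError("coefficient sds must be >= 0")
        dup = df.duplicated(subset=["subcategory", "gas", "term", "zone"])
        if dup.any():
            raise ValueError(
                f"duplicate coefficient rows: {df.loc[dup, ['subcategory', 'gas', 'term', 'zone']].to_dict('records')}")
        self.table = df
        self._index = {
            (r.subcategory, r.gas, r.term, r.zone): r for r in df.itertuples()
        }

    def lookup(self, subcategory: str, gas: str, term: str = "flux",
               zone: str = "national") -> tuple[float, float]:
        """Coefficient (value, sd) in Gg gas km^-2 yr^-1, zone-falling-back.

        Elemental-basis rows are converted to gas mass here.
        """
        row = self._index.get((subcategory, gas, term, zone))
        if row is None and zone != "national":
            row = self._index.get((subcategory, gas, term, "national"))
        if row is None:
            raise KeyError(
                f"no coefficient for subcategory={subcategory!r} gas={gas!r} "
                f"term={term!r} zone={zone!r} (no national fallback)")
        f = _COEF_UNIT_TO_GG_KM2[row.unit]
        value, sd = row.value * f, row.sd * f
        if row.basis != "gas":
            species = get_species(gas)
            gf = element_to_gas(value, species, sd, element=row.basis)
            value, sd = gf.value, gf.sd
        return value, sd

    def has(self, subcategory: str, gas: str, term: str = "flux",
            zone: str = "national") -> bool:
        return ((subcategory, gas, term, zone) in self._index
                or (subcategory, gas, term, "national") in self._index)


def coefficient_flux(area_km2: float, subcategory: str, gas: str,
                     table: CoefficientTable, zone: str = "national",
                     term: str = "flux") -> GasFlux:
    """Flux = area x coefficient; sd = area x coefficient sd."""
    if area_km2 < 0:
        raise ValueError(f"area must be >= 0, got {area_km2}")
    c, csd = table.lookup(subcategory, gas, term, zone)
    return GasFlux(get_species(gas), area_km2 * c, area_km2 * csd)


# ---------------------------------------------------------------- waterbodies

MACROPHYTE_SPECIES = ("phragmites", "equisetum")


def lake_emissions(lakes: pd.DataFrame, table: CoefficientTable,
                   macrophyte_mode: str = "substitute") -> dict[str, GasFlux]:
    """Per-gas lake emissions summed over a lake registry.

    Per lake: CO2 = area x evasion coefficient of its size class; CH4 =
    open-water area x (diffusion + ebullition coefficients) plus, for each
    emergent macrophyte species group, covered area x the species
    coefficient. In ``substitute`` mode (default) the macrophyte-covered
    area is removed from the open-water area, so vegetation stands emit via
    the species coefficient instead of the open-water pathways; ``additive``
    applies macrophyte fluxes on top of full-area open-water fluxes.
    Registry columns: area_km2, size_class, optional cover_<species>.
    Lake-level sds (area x coefficient sd) are combined in quadrature.
    """
    if macrophyte_mode not in ("substitute", "additive"):
        raise ValueError(f"unknown macrophyte_mode {macrophyte_mode!r}")
    if lakes["size_class"].isna().any():
        bad = lakes.index[lakes["size_class"].isna()].tolist()
        raise ValueError(f"unclassified lakes in registry: rows {bad}")

    co2_terms: list[tuple[float, float]] = []
    ch4_terms: list[tuple[float, float]] = []
    for lake in lakes.itertuples():
        sub = f"lake_class_{int(lake.size_class)}"
        area = float(lake.area_km2)
        cover = {sp: float(getattr(lake, f"cover_{sp}", 0.0) or 0.0)
                 for sp in MACROPHYTE_SPECIES}
        total_cover = sum(cover.values())
        if total_cover > 1.0 + 1e-9:
            raise ValueError(f"macrophyte cover fractions sum to {total_cover} > 1")
        open_area = area * (1.0 - total_cover) if macrophyte_mode == "substitute" else area

        c, s = table.lookup(sub, "CO2", "co2_evasion")
        co2_terms.append((area * c, area * s))
        for term in ("ch4_diffusion", "ch4_ebullition"):
            c, s = table.lookup(sub, "CH4", term)
            ch4_terms.append((open_area * c, open_area * s))
        for sp, frac in cover.items():
            if frac > 0:
                c, s = table.lookup("lake_macrophyte", "CH4", f"macrophyte_{sp}")
                ch4_terms.append((area * frac * c, area * frac * s))

    co2_v, co2_s = combine_uncertainty(co2_terms) if co2_terms else (0.0, 0.0)
    ch4_v, ch4_s = combine_uncertainty(ch4_terms) if ch4_terms else (0.0, 0.0)
    return {"CO2": GasFlux(CO2, co2_v, co2_s), "CH4": GasFlux(CH4, ch4_v, ch4_s)}


def river_area(rivers: pd.DataFrame) -> float:
    """Total river surface km2: polygon areas plus 3.5 m x length for lines.

    Registry columns: kind ('polygon'|'line'), area_km2 (polygons),
    length_km (lines). Wide rivers are mapped as polygons; rivers narrower
    than 5 m are mapped as lines and assumed 3.5 m wide on average.
    """
    total = 0.0
    for r in rivers.itertuples():
        if r.kind == "polygon":
            total += float(r.area_km2)
        elif r.kind == "line":
            total += float(r.length_km) * NARROW_RIVER_WIDTH_KM
        else:
            raise ValueError(f"river record kind must be 'polygon' or 'line', got {r.kind!r}")
    return total


def river_emissions(river_area_km2: float, table: CoefficientTable) -> GasFlux:
    """River CO2 evasion from total river surface area."""
    return coefficient_flux(river_area_km2, "river", "CO2", table)


# -------------------------------------------------------------------- mires

def mire_fluxes(class_areas: Mapping[str, float], table: CoefficientTable
                ) -> dict[str, GasFlux]:
    """Undrained-mire soil emissions and ecosystem CO2 balance by mire class.

    ``class_areas`` maps mire_class_1..4 to km2. Soil CH4 and N2O emissions
    use term "flux"; the net ecosystem CO2 exchange (negative = carbon
    accumulation) uses term "ecosystem_net". CH4 uptake (sequestration) is
    not netted against the emissions — the emission side reports gross CH4
    release. Class sds combine in quadrature.
    """
    out: dict[str, GasFlux] = {}
    for gas, term, key in (("CH4", "flux", "CH4"), ("N2O", "flux", "N2O"),
                           ("CO2", "ecosystem_net", "CO2_ecosystem")):
        comps = []
        for sub, area in class_areas.items():
            f = coefficient_flux(area, sub, gas, table, term=term)
            comps.append((f.value, f.sd))
        v, s = combine_uncertainty(comps)
        out[key] = GasFlux(get_species(gas), v, s)
    return out


def derive_mire_co2_coefficient(long_term_c_accumulation: float,
                                ch4_c_flux: float, leaching_c: float
                                ) -> tuple[float, float]:
    """Net ecosystem CO2 coefficient from a long-term peat carbon balance.

    Inputs are non-negative magnitudes in g C m^-2 yr^-1: the long-term
    apparent rate of carbon accumulation in the peat column, the CH4-C flux
    out, and a constant net leaching export of C. Closing the mass balance,
    the net ecosystem CO2-C exchange (atmosphere sign convention, uptake
    negative) must supply everything that accumulates or leaves by other
    routes:

        CO2_C = -(accumulation + CH4_C + leaching)

    so that accumulation = -CO2_C - CH4_C - leaching. Returns the
    coefficient as (Gg CO2 km^-2 yr^-1, g CO2-C m^-2 yr^-1 signed).
    """
    for name, v in (("accumulation", long_term_c_accumulation),
                    ("ch4_c_flux", ch4_c_flux), ("leaching_c", leaching_c)):
        if v < 0:
            raise ValueError(f"{name} must be a non-negative magnitude, got {v}")
    co2_c = -(long_term_c_accumulation + ch4_c_flux + leaching_c)
    # 1 g C m^-2 yr^-1 == 1e-3 Gg C km^-2 yr^-1
    coef_gg_km2 = element_to_gas(co2_c * 1e-3, CO2).value
    return coef_gg_km2, co2_c


def drained_peat_soil_fluxes(area_km2: float, table: CoefficientTable,
                             zone: str = "national") -> dict[str, GasFlux]:
    """Soil CH4, CO2 and N2O fluxes from forestry-drained peatland area."""
    return {gas: coefficient_flux(area_km2, "drained_peatland", gas, table, zone=zone)
            for gas in ("CH4", "CO2", "N2O")}


# -------------------------------------------------------------------- forest

def harvest_emissions(harvest: pd.DataFrame) -> pd.DataFrame:
    """Harvested-carbon emissions per (assortment x soil class), as CO2eq.

    All harvested carbon is counted as an immediate CO2 emission (no wood
    product storage): C mass x 44/12, GWP 1. Input columns: assortment
    (timber|energywood), soil (mineral_soil|drained_peatland), carbon_gg
    (Gg C yr^-1, >= 0), sd_gg (same unit). Output adds co2eq_gg / co2eq_sd_gg
    and a total row per assortment plus a grand total.
    """
    if (harvest["carbon_gg"] < 0).any():
        raise ValueError("harvested carbon must be >= 0")
    rows = []
    for r in harvest.itertuples():
        gf = element_to_gas(float(r.carbon_gg), CO2, float(getattr(r, "sd_gg", 0.0)))
        eq = to_co2eq(gf)
        rows.append((r.assortment, r.soil, eq.value, eq.sd))
    df = pd.DataFrame(rows, columns=["assortment", "soil", "co2eq_gg", "co2eq_sd_gg"])
    totals = []
    for assortment, grp in df.groupby("assortment", sort=False):
        v, s = combine_uncertainty(list(zip(grp["co2eq_gg"], grp["co2eq_sd_gg"])))
        totals.append((assortment, "total", v, s))
    v, s = combine_uncertainty(list(zip(df["co2eq_gg"], df["co2eq_sd_gg"])))
    totals.append(("total", "total", v, s))
    return pd.concat([df, pd.DataFrame(totals, columns=df.columns)], ignore_index=True)


# ------------------------------------------------------------------ wetlands

def peat_production_emissions(area_km2: float, table: CoefficientTable
                              ) -> dict[str, GasFlux]:
    """National peat-extraction emissions from site area and inventory factors."""
    return {gas: coefficient_flux(area_km2, "peat_production", gas, table)
            for gas in ("CH4", "CO2", "N2O")}


# -------------------------------------------------------- proxy allocation

def allocate_by_proxy(totals: pd.DataFrame, proxy: np.ndarray,
                      municipality_grid: np.ndarray) -> np.ndarray:
    """Distribute municipal totals onto grid cells proportionally to a proxy.

    ``totals`` columns: municipality (id matching ``municipality_grid``),
    value (>= 0), optional biogenic flag (allocated as zero — biogenic CO2
    is excluded to avoid double counting). Each municipality's total is
    spread over its cells with weights proxy / sum(proxy); a municipality
    whose proxy is all zero falls back to a uniform spread. Allocation
    conserves each municipal total exactly; a municipality with no cells is
    rejected.
    """
    proxy = np.asarray(proxy, dtype=float)
    if (proxy < 0).any():
        raise ValueError("proxy weights must be non-negative")
    if proxy.shape != municipality_grid.shape:
        raise ValueError("proxy and municipality grids must share a shape")
    out = np.zeros_like(proxy)
    for r in totals.itertuples():
        if bool(getattr(r, "biogenic", False)):
            continue
        total = float(r.value)
        if total < 0:
            raise ValueError(f"negative sector total for municipality {r.municipality}")
        mask = municipality_grid == r.municipality
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"municipality {r.municipality} has no cells in the grid")
        w = np.where(mask, proxy, 0.0)
        ws = w.sum()
        if ws == 0:
            out[mask] += total / n
        else:
            out += total * w / ws
    return out
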