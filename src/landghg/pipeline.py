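"""Full gridded pipeline: engines + allocation + regional/national roll-up.

Takes a landscape bundle (synthetic or loaded from files), runs every flux
engine on it, spatially allocates the sector totals, and aggregates to
region summaries and a national rollup. Component flux rows are signed
CO2-equivalents in Tg yr^-1 (sinks negative), keyed by region, category and
component, so they can be checked one-for-one against a generator's ground
truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aggregate import national_rollup, regional_aggregate
from .engines import (allocate_by_proxy, coefficient_flux, harvest_emissions,
                      lake_emissions, peat_production_emissions, river_area,
                      river_emissions)
from .gases import GWP100, to_co2eq
from .landcover import CATEGORY_CODE, SUBCATEGORY_CODE

__all__ = ["run_pipeline"]


def _zonal_sum(grid: np.ndarray, region: np.ndarray) -> dict[int, float]:
    out = {}
    for r in np.unique(region[region > 0]):
        out[int(r)] = float(grid[region == r].sum())
    return out


def _allocate_with_category_fallback(totals: pd.DataFrame, proxy: np.ndarray,
                                     municipality: np.ndarray,
                                     category_mask: np.ndarray) -> np.ndarray:
    """Allocate within each municipality's cells of the target category.

    A municipality with no cells of the category falls back to its full
    extent, so no total is lost.
    """
    masked = np.where(category_mask, municipality, 0)
    present = set(np.unique(masked[masked > 0]))
    inside = totals[totals["municipality"].isin(present)]
    outside = totals[~totals["municipality"].isin(present)]
    grid = np.zeros_like(proxy)
    if len(inside):
        grid += allocate_by_proxy(inside, proxy, masked)
    if len(outside):
        grid += allocate_by_proxy(outside, proxy, municipality)
    return grid


def run_pipeline(landscape, macrophyte_mode: str = "substitute") -> dict:
    """Run every engine on a landscape and aggregate.

    Returns ``component_fluxes`` (region, category, component, gas,
    co2eq_tg — signed), ``regions`` (per-region summaries) and ``rollup``
    (national per-category emission/sink/net table).
    """
    coefs = landscape.coefficients
    grid = landscape.grid
    region = grid.region
    areas = landscape.areas(by_region=True)
    rows: list[dict] = []

    def emit(region_id, category, component, gas, co2eq_gg):
        rows.append({"region": int(region_id), "category": category,
                     "component": component, "gas": gas,
                     "co2eq_tg": co2eq_gg / 1000.0})

    # --- sector totals allocated by proxy, then summed back by region
    sector = landscape.sector_totals
    for (cat, sec, gas), grp in sector.groupby(["category", "sector", "gas"]):
        # biogenic-CO2 rows are skipped inside allocate_by_proxy
        totals = grp.rename(columns={"value_gg": "value"})[
            ["municipality", "value", "biogenic"]]
        cat_mask = grid.category == CATEGORY_CODE[cat]
        alloc = _allocate_with_category_fallback(
            totals, landscape.proxy, landscape.municipality, cat_mask)
        for r, v in _zonal_sum(alloc, region).items():
            if v:
                emit(r, cat, sec, gas, v * GWP100[gas])

    # --- coefficient engines on per-region subcategory areas
    for row in areas.itertuples():
        cat, sub, reg, area = row.category, row.subcategory, int(row.region), row.area_km2
        zone = landscape.zone(reg)
        if cat == "arable" and sub in ("organic_annual", "organic_perennial",
                                       "mineral_all_crops"):
            eq = to_co2eq(coefficient_flux(area, sub, "CO2", coefs, zone=zone))
            emit(reg, cat, sub, "CO2", eq.value)
        elif cat == "forest" and sub == "drained_peatland":
            for gas in ("CH4", "CO2", "N2O"):
                eq = to_co2eq(coefficient_flux(area, sub, gas, coefs, zone=zone))
                emit(reg, cat, f"drained_peat_soil_{gas}", gas, eq.value)
        elif cat == "wetland" and sub.startswith("mire_class"):
            for gas, term, name in (("CH4", "flux", f"{sub}_CH4"),
                                    ("N2O", "flux", f"{sub}_N2O"),
                                    ("CO2", "ecosystem_net", f"{sub}_CO2net")):
                eq = to_co2eq(coefficient_flux(area, sub, gas, coefs, term=term))
                emit(reg, cat, name, gas, eq.value)

    # --- peat production: national totals allocated over peat-site cells
    peat_areas = areas[(areas.category == "wetland")
                       & (areas.subcategory == "peat_production")]
    total_peat = float(peat_areas["area_km2"].sum())
    if total_peat > 0:
        national = peat_production_emissions(total_peat, coefs)
        peat_mask = grid.subcategory == SUBCATEGORY_CODE[("wetland", "peat_production")]
        for gas, flux in national.items():
            totals = pd.DataFrame({"municipality": [1], "value": [flux.value]})
            alloc = allocate_by_proxy(totals, peat_mask.astype(float),
                                      np.ones_like(region, dtype=int))
            for r, v in _zonal_sum(alloc, region).items():
                if v:
                    emit(r, "wetland", f"peat_production_{gas}", gas, v * GWP100[gas])

    # --- waterbodies per region from the feature registries
    for reg, grp in landscape.lakes.groupby("region"):
        per_gas = lake_emissions(grp, coefs, macrophyte_mode=macrophyte_mode)
        emit(reg, "waterbody", "lake_co2", "CO2", to_co2eq(per_gas["CO2"]).value)
        emit(reg, "waterbody", "lake_ch4", "CH4", to_co2eq(per_gas["CH4"]).value)
    for reg, grp in landscape.rivers.groupby("region"):
        eq = to_co2eq(river_emissions(river_area(grp), coefs))
        emit(reg, "waterbody", "river_co2", "CO2", eq.value)

    # --- forest harvest and NEE inputs
    for reg, grp in landscape.forest_inputs.groupby("region"):
        harvest = grp[grp.component.str.startswith("harvest")]
        if len(harvest):
            parts = harvest.component.str.split("_", n=2, expand=True)
            hdf = pd.DataFrame({"assortment": parts[1], "soil": parts[2],
                                "carbon_gg": harvest["value_gg"].values,
                                "sd_gg": 0.0})
            out = harvest_emissions(hdf)
            comp = out[out.soil != "total"]
            for r2 in comp.itertuples():
                emit(reg, "forest", f"harvest_{r2.assortment}_{r2.soil}", "CO2",
                     r2.co2eq_gg)
        for r2 in grp[grp.component.str.startswith("nee")].itertuples():
            emit(reg, "forest", r2.component, "CO2", r2.value_gg)

    component_fluxes = pd.DataFrame(rows)

    regions = regional_aggregate(component_fluxes, landscape.region_areas(),
                                 landscape.populations)

    cat_rows = []
    for (cat,), grp in component_fluxes.groupby(["category"]):
        for kind, sel in (("emission", grp[grp.co2eq_tg > 0]),
                          ("sink", grp[grp.co2eq_tg < 0])):
            if len(sel) == 0 and kind == "sink":
                continue
            row = {"category": cat, "kind": kind, "sd_tg": 0.0}
            for gcol, gas in (("ch4_tg", "CH4"), ("co2_tg", "CO2"), ("n2o_tg", "N2O")):
                row[gcol] = float(sel.loc[sel.gas == gas, "co2eq_tg"].sum())
            row["total_tg"] = row["ch4_tg"] + row["co2_tg"] + row["n2o_tg"]
            cat_rows.append(row)
    rollup = national_rollup(pd.DataFrame(cat_rows))

    return {"component_fluxes": component_fluxes, "regions": regions,
            "rollup": rollup}
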