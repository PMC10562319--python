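"""Packaged national summary tables and the desk-scale reproduction mode.

The package ships CSV transcriptions of the published national accounting
tables for mainland Finland (18 administrative regions, reference period
2017-2025): land-cover areas, per-gas CO2eq fluxes with uncertainty
half-widths and intensities, and regional emission/sink/net summaries.
``published_tables_report`` recomputes every derived quantity in those tables
from the primary printed numbers — per-gas sums, quadrature uncertainty
roll-ups, net emissions, intensities, per-capita values and shares — which
is the fast, data-free verification surface of the package.

Implied national emission coefficients (flux divided by area) are exposed
as a :class:`~landghg.engines.CoefficientTable` so the flux engines can be
exercised against the printed totals.
"""

from __future__ import annotations

import importlib.resources as resources
import math
from typing import Mapping

import numpy as np
import pandas as pd

from .aggregate import build_flux_ledger, intensity, ledger_balance, national_rollup, per_capita
from .engines import CoefficientTable
from .gases import GWP100, combine_uncertainty
from .landcover import MireClassificationRule

__all__ = [
    "NATIONAL_POPULATION",
    "ACCOUNTED_AREA_KM2",
    "TOTAL_REGION_AREA_KM2",
    "load_area_table",
    "load_flux_table",
    "load_region_table",
    "load_mire_rules",
    "intensity_areas",
    "derived_coefficient_table",
    "category_totals",
    "published_tables_report",
]

#: Total population of the 18 regions, 31 Dec 2020.
NATIONAL_POPULATION = 5_503_664
#: Accounted land-cover area (km2) — the sum of the five category areas.
ACCOUNTED_AREA_KM2 = 306_954
#: Total land + inland-water area of the 18 regions (km2).
TOTAL_REGION_AREA_KM2 = 336_887


def _read(name: str) -> pd.DataFrame:
    with resources.files("landghg.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_area_table() -> pd.DataFrame:
    """Land-cover areas (km2) by category and subcategory, with total rows."""
    return _read("table1_areas.csv")


def load_flux_table() -> pd.DataFrame:
    """National per-gas CO2eq fluxes (Tg yr^-1), sds and intensities."""
    return _read("table2_fluxes.csv")


def load_region_table() -> pd.DataFrame:
    """Regional emission/sink/net summaries (Tg CO2eq yr^-1); code 0 = total."""
    return _read("table3_regions.csv")


def load_mire_rules() -> MireClassificationRule:
    """Mire attribute -> class rule table.

    The concrete attribute-to-class mapping shipped here is a synthetic
    stand-in constructed by this package (the schema — productivity x
    fertility x site main class onto classes 1-4 — is the accounting
    scheme's; the original mapping table is not redistributed). Swap in a
    different CSV for production use.
    """
    return MireClassificationRule(_read("mire_classes_synthetic.csv"))


def _area_of(t1: pd.DataFrame, category: str, subcategory: str) -> float:
    sel = t1[(t1.category == category) & (t1.subcategory == subcategory)]
    return float(sel["area_km2"].iloc[0])


def intensity_areas(t1: pd.DataFrame | None = None,
                    t2: pd.DataFrame | None = None) -> pd.Series:
    """Denominator area (km2) for each flux-table row's intensity.

    Artificial-surface sources are all divided by the whole artificial
    area; forest harvest components by the area of their soil class; forest
    subtotals, sinks and net by the total forest area; the wetland net by
    the undrained-mire area; national rows by the accounted land-cover
    area. Rows with no printed area (the wetland sink row prints a zero
    intensity) get NaN and are skipped by intensity checks.
    """
    t1 = load_area_table() if t1 is None else t1
    t2 = load_flux_table() if t2 is None else t2
    a = lambda c, s: _area_of(t1, c, s)
    per_row = []
    for r in t2.itertuples():
        cat, src, kind = r.category, r.source, r.kind
        if cat == "artificial":
            area = a("artificial", "all")
        elif cat == "arable":
            area = {"livestock_production": a("arable", "livestock_production"),
                    "field_cultivation": a("arable", "field_cultivation"),
                    "organic_annual": a("arable", "organic_annual"),
                    "organic_perennial": a("arable", "organic_perennial"),
                    "mineral_all_crops": a("arable", "mineral_all_crops"),
                    "total": a("arable", "all")}[src]
        elif cat == "forest":
            if src in ("timber_mineral", "energywood_mineral"):
                area = a("forest", "mineral_soil")
            elif src in ("timber_drained_peat", "energywood_drained_peat",
                         "drained_peat_soil"):
                area = a("forest", "drained_peatland")
            else:
                area = a("forest", "all")
        elif cat == "waterbody":
            area = {"rivers": a("waterbody", "river"),
                    "lakes": a("waterbody", "lakes"),
                    "total": a("waterbody", "all")}[src]
        elif cat == "wetland":
            if kind == "sink":
                area = math.nan
            else:
                area = {"peat_production": a("wetland", "peat_production"),
                        "undrained_mires_soil": a("wetland", "undrained_mires"),
                        "net": a("wetland", "undrained_mires"),
                        "total": a("wetland", "all")}[src]
        else:  # national
            area = a("total", "all")
        per_row.append(area)
    return pd.Series(per_row, index=t2.index, name="area_km2")


def derived_coefficient_table() -> CoefficientTable:
    """National emission coefficients implied by the printed fluxes and areas.

    Coefficient = gas mass flux / area, with gas mass recovered from the
    CO2eq columns by dividing out the GWP. Single-gas rows carry the
    printed uncertainty half-width scaled the same way; multi-gas row sds
    cannot be attributed to one gas and are left at zero.
    """
    t1, t2 = load_area_table(), load_flux_table()
    a = lambda c, s: _area_of(t1, c, s)

    def row_of(category: str, source: str, kind: str = "emission"):
        sel = t2[(t2.category == category) & (t2.source == source) & (t2.kind == kind)]
        return sel.iloc[0]

    rows = []

    def add(category, subcategory, gas, term, area, co2eq_tg, sd_tg=0.0):
        gwp = GWP100[gas]
        rows.append({
            "category": category, "subcategory": subcategory, "gas": gas,
            "term": term, "zone": "national",
            "value": co2eq_tg * 1000.0 / gwp / area,
            "sd": sd_tg * 1000.0 / gwp / area,
            "unit": "Gg/km2", "basis": "gas",
        })

    for sub in ("organic_annual", "organic_perennial", "mineral_all_crops"):
        r = row_of("arable", sub)
        add("arable", sub, "CO2", "flux", a("arable", sub), r.co2_tg, r.sd_tg)
    r = row_of("waterbody", "rivers")
    add("waterbody", "river", "CO2", "flux", a("waterbody", "river"), r.co2_tg, r.sd_tg)
    r = row_of("wetland", "peat_production")
    area = a("wetland", "peat_production")
    add("wetland", "peat_production", "CH4", "flux", area, r.ch4_tg)
    add("wetland", "peat_production", "CO2", "flux", area, r.co2_tg)
    add("wetland", "peat_production", "N2O", "flux", area, r.n2o_tg)
    r = row_of("forest", "drained_peat_soil")
    area = a("forest", "drained_peatland")
    add("forest", "drained_peatland", "CH4", "flux", area, r.ch4_tg)
    add("forest", "drained_peatland", "CO2", "flux", area, r.co2_tg)
    add("forest", "drained_peatland", "N2O", "flux", area, r.n2o_tg)
    r = row_of("wetland", "undrained_mires_soil")
    area = a("wetland", "undrained_mires")
    add("wetland", "undrained_mires", "CH4", "flux", area, r.ch4_tg)
    add("wetland", "undrained_mires", "N2O", "flux", area, r.n2o_tg)
    r = row_of("wetland", "mires_ecosystems", "sink")
    add("wetland", "undrained_mires", "CO2", "ecosystem_net", area, r.co2_tg, r.sd_tg)
    return CoefficientTable(pd.DataFrame(rows))


def category_totals(t2: pd.DataFrame | None = None,
                    recompute_totals: bool = False) -> pd.DataFrame:
    """Per-category emission and sink totals in rollup shape.

    With ``recompute_totals`` the total CO2eq column is rebuilt from the
    per-gas columns instead of taking the printed value (they agree within
    printing precision).
    """
    t2 = load_flux_table() if t2 is None else t2
    sel = t2[t2.level == "category_total"].copy()
    if recompute_totals:
        sel["total_tg"] = sel[["ch4_tg", "co2_tg", "n2o_tg"]].sum(axis=1)
    return sel[["category", "kind", "ch4_tg", "co2_tg", "n2o_tg", "total_tg", "sd_tg"]]


def published_tables_report() -> dict:
    """Recompute every derived quantity of the national tables from scratch.

    Returns a dict with the recomputed flux table (per-gas sums,
    intensities), the national rollup and its quadrature uncertainties, the
    regional table with recomputed net/intensity/per-capita columns, the
    flux ledger, and headline scalars (total/net emission, shares,
    per-capita).
    """
    t1, t2, t3 = load_area_table(), load_flux_table(), load_region_table()

    flux = t2.copy()
    flux["gas_sum_tg"] = flux[["ch4_tg", "co2_tg", "n2o_tg"]].sum(axis=1)
    areas = intensity_areas(t1, t2)
    flux["intensity_recomputed"] = [
        intensity(v, a) if a == a else math.nan
        for v, a in zip(flux["total_tg"], areas)
    ]

    cats = category_totals(t2)
    rollup = national_rollup(cats)
    total_emission = rollup[rollup.category == "total_emission"].iloc[0]
    total_sink = rollup[rollup.category == "total_sink"].iloc[0]
    net = rollup[rollup.category == "net"].iloc[0]

    regions = t3[t3.code != 0].copy()
    total_row = t3[t3.code == 0].iloc[0]
    regions["net_recomputed"] = regions["emission_tg"] + regions["sink_tg"]
    regions["intensity_recomputed"] = [
        intensity(n, a) for n, a in zip(regions["net_tg"], regions["area_km2"])
    ]
    regions["implied_population"] = regions["net_tg"] * 1e6 / regions["per_capita_mg"]

    ledger = build_flux_ledger(cats)

    emission_tg = float(total_emission["total_tg"])
    sink_tg = float(total_sink["total_tg"])  # negative
    net_tg = emission_tg + sink_tg
    net_tg_regional = float(regions["net_recomputed"].sum())
    scalars = {
        "total_emission_tg": emission_tg,
        "total_emission_sd_tg": float(total_emission["sd_tg"]),
        "total_sink_tg": sink_tg,
        "net_emission_tg": net_tg,
        "net_emission_sd_tg": float(net["sd_tg"]),
        "net_emission_tg_regional": net_tg_regional,
        "artificial_share_pct": 100.0 * float(
            cats.query("category == 'artificial' and kind == 'emission'")["total_tg"].iloc[0]
        ) / emission_tg,
        "sequestration_offset_pct": 100.0 * (-sink_tg) / emission_tg,
        "per_capita_mg": per_capita(net_tg_regional, NATIONAL_POPULATION),
        "intensity_accounted_area": intensity(net_tg, ACCOUNTED_AREA_KM2),
        "intensity_region_area": intensity(net_tg_regional, TOTAL_REGION_AREA_KM2),
        "ledger_balance_tg": ledger_balance(ledger),
        "region_total_net_printed": float(total_row["net_tg"]),
    }
    return {"flux": flux, "rollup": rollup, "regions": regions,
            "ledger": ledger, "scalars": scalars,
            "area_table": t1}
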