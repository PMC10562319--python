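"""Roll-up of fluxes to categories, regions and the national level.

Sinks are carried as negative CO2-equivalent numbers throughout; net
emission is therefore a plain sum. Emission intensity is net emission
(Tg CO2eq yr^-1) divided by area (km2), reported in Gg CO2eq km^-2 yr^-1;
per-capita net emission is Tg converted to Mg divided by population.
Negative intensities and per-capita values are legal (regions whose sink
exceeds their emissions) and are never clamped.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gases import Co2eqFlux, combine_uncertainty

__all__ = [
    "intensity",
    "per_capita",
    "regional_aggregate",
    "national_rollup",
    "build_flux_ledger",
    "ledger_balance",
]

GAS_COLUMNS = ("ch4_tg", "co2_tg", "n2o_tg")
CATEGORIES5 = ("artificial", "arable", "forest", "waterbody", "wetland")


def intensity(net_tg: float, area_km2: float) -> float:
    """Emission intensity in Gg CO2eq km^-2 yr^-1 = 1000 x net_Tg / area.

    Undefined for non-positive area; reported as NaN (missing), since a
    zero-area denominator has no meaningful intensity.
    """
    if area_km2 <= 0:
        return math.nan
    return 1000.0 * net_tg / area_km2


def per_capita(net_tg: float, population: float) -> float:
    """Per-capita net emission in Mg CO2eq yr^-1 person^-1."""
    if population <= 0:
        return math.nan
    return net_tg * 1e6 / population


def regional_aggregate(flux_rows: pd.DataFrame,
                       region_areas: Mapping[int, float],
                       populations: Mapping[int, float] | None = None
                       ) -> pd.DataFrame:
    """Aggregate signed CO2eq flux contributions to region summaries.

    ``flux_rows`` columns: region, co2eq_tg (signed, sinks negative);
    any extra grouping columns are ignored. Every contribution must carry a
    region present in ``region_areas`` (rejected otherwise). Returns one row
    per region with emission (sum of positives), sink (sum of negatives),
    net, intensity and, when populations are given, per-capita net. Summing
    the regional columns reproduces the national totals exactly.
    """
    unknown = set(flux_rows["region"]) - set(region_areas)
    if unknown:
        raise ValueError(f"flux contributions with unmapped regions: {sorted(unknown)}")
    rows = []
    for region in sorted(region_areas):
        sub = flux_rows.loc[flux_rows["region"] == region, "co2eq_tg"]
        emission = float(sub[sub > 0].sum())
        sink = float(sub[sub < 0].sum())
        net = emission + sink
        area = float(region_areas[region])
        pop = float(populations[region]) if populations and region in populations else math.nan
        rows.append({
            "region": region,
            "area_km2": area,
            "emission_tg": emission,
            "sink_tg": sink,
            "net_tg": net,
            "intensity_gg_km2": intensity(net, area),
            "population": pop,
            "per_capita_mg": per_capita(net, pop) if pop == pop else math.nan,
        })
    return pd.DataFrame(rows)


def national_rollup(category_totals: pd.DataFrame,
                    net_sd_override_tg: float | None = None) -> pd.DataFrame:
    """Build the national emission/sink/net summary from category totals.

    ``category_totals`` has one row per (category, kind) with kind in
    {emission, sink}, per-gas columns ch4_tg / co2_tg / n2o_tg (sink rows
    negative) and an uncertainty half-width sd_tg. All five land-cover
    categories must be present on the emission side. Appends rows
    ``total_emission``, ``total_sink`` and ``net`` with per-gas sums,
    total = sum of gases, and quadrature sds (the net sd may be overridden
    by an externally derived value).
    """
    df = category_totals.copy()
    have = set(df.loc[df["kind"] == "emission", "category"])
    missing = set(CATEGORIES5) - have
    if missing:
        raise ValueError(f"missing emission totals for categories: {sorted(missing)}")
    if "total_tg" not in df.columns:
        df["total_tg"] = df[list(GAS_COLUMNS)].sum(axis=1)

    out = [df]
    sums = {}
    for kind, label in (("emission", "total_emission"), ("sink", "total_sink")):
        part = df[df["kind"] == kind]
        row = {"category": label, "kind": kind}
        for g in GAS_COLUMNS:
            row[g] = float(part[g].sum())
        row["total_tg"], row["sd_tg"] = combine_uncertainty(
            list(zip(part["total_tg"], part["sd_tg"])))
        sums[label] = row
        out.append(pd.DataFrame([row]))

    net = {"category": "net", "kind": "net"}
    for g in GAS_COLUMNS:
        net[g] = sums["total_emission"][g] + sums["total_sink"].get(g, 0.0)
    net["total_tg"], net["sd_tg"] = combine_uncertainty([
        (sums["total_emission"]["total_tg"], sums["total_emission"]["sd_tg"]),
        (sums["total_sink"]["total_tg"], sums["total_sink"]["sd_tg"]),
    ])
    if net_sd_override_tg is not None:
        net["sd_tg"] = net_sd_override_tg
    out.append(pd.DataFrame([net]))
    return pd.concat(out, ignore_index=True)


def build_flux_ledger(category_totals: pd.DataFrame) -> pd.DataFrame:
    """Directed flux ledger for the national balance (Sankey-ready).

    One entry per (category, gas) with a nonzero flux: emissions flow
    source -> atmosphere, sequestration flows atmosphere -> sink label.
    Entry values are positive magnitudes in Tg CO2eq yr^-1; the atmosphere
    balance (inflows minus outflows) equals the national net emission.
    """
    entries = []
    gas_names = {"ch4_tg": "CH4", "co2_tg": "CO2", "n2o_tg": "N2O"}
    for r in category_totals.itertuples():
        for col, gas in gas_names.items():
            v = float(getattr(r, col))
            if v > 0:
                entries.append((r.category, "atmosphere", gas, v))
            elif v < 0:
                entries.append(("atmosphere", f"{r.category}_sink", gas, -v))
    return pd.DataFrame(entries, columns=["source", "target", "gas", "value_tg"])


def ledger_balance(ledger: pd.DataFrame) -> float:
    """Atmosphere balance of a flux ledger = inflows - outflows (Tg)."""
    if ledger.empty:
        return 0.0
    inflow = ledger.loc[ledger["target"] == "atmosphere", "value_tg"].sum()
    outflow = ledger.loc[ledger["source"] == "atmosphere", "value_tg"].sum()
    return float(inflow - outflow)
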