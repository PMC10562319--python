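"""Flux engines: coefficient lookups, waterbodies, mires, harvest, allocation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from landghg.engines import (CoefficientTable, allocate_by_proxy,
                             coefficient_flux, derive_mire_co2_coefficient,
                             drained_peat_soil_fluxes, harvest_emissions,
                             lake_emissions, mire_fluxes,
                             peat_production_emissions, river_area,
                             river_emissions)
from landghg.gases import to_co2eq
from landghg.national_tables import derived_coefficient_table
from landghg.synthetic import default_true_coefficients


@pytest.fixture(scope="module")
def coefs():
    return default_true_coefficients()


@pytest.fixture(scope="module")
def published_coefs():
    return derived_coefficient_table()


# ------------------------------------------------------- coefficient table

def test_lookup_zone_fallback_and_missing_key(coefs):
    south = coefs.lookup("mineral_all_crops", "CO2", zone="southern")
    north = coefs.lookup("mineral_all_crops", "CO2", zone="northern")
    assert south != north
    # subcategory with only a national row serves any zone
    nat = coefs.lookup("organic_annual", "CO2", zone="northern")
    assert nat == coefs.lookup("organic_annual", "CO2")
    with pytest.raises(KeyError, match="no coefficient"):
        coefs.lookup("organic_annual", "N2O")


def test_elemental_basis_rows_converted_on_lookup():
    t = CoefficientTable(pd.DataFrame([
        {"category": "x", "subcategory": "s", "gas": "CO2", "value": 12.0,
         "sd": 1.2, "basis": "C"},
    ]))
    v, sd = t.lookup("s", "CO2")
    assert v == pytest.approx(44.0) and sd == pytest.approx(4.4)


def test_table_rejects_duplicates_and_negative_sd():
    base = {"category": "x", "subcategory": "s", "gas": "CO2", "value": 1.0}
    with pytest.raises(ValueError, match="duplicate"):
        CoefficientTable(pd.DataFrame([base, dict(base)]))
    with pytest.raises(ValueError, match="sds must be >= 0"):
        CoefficientTable(pd.DataFrame([dict(base, sd=-1.0)]))


def test_coefficient_flux_is_area_times_coefficient(coefs):
    c, csd = coefs.lookup("organic_annual", "CO2")
    f = coefficient_flux(100.0, "organic_annual", "CO2", coefs)
    assert f.value == pytest.approx(100.0 * c)
    assert f.sd == pytest.approx(100.0 * csd)
    zero = coefficient_flux(0.0, "organic_annual", "CO2", coefs)
    assert zero.value == 0.0 and zero.sd == 0.0
    with pytest.raises(ValueError):
        coefficient_flux(-1.0, "organic_annual", "CO2", coefs)


@given(st.floats(0, 1e5), st.floats(1, 10))
def test_engine_linearity_in_area(area, factor):
    coefs = default_true_coefficients()
    f1 = coefficient_flux(area, "organic_perennial", "CO2", coefs)
    f2 = coefficient_flux(area * factor, "organic_perennial", "CO2", coefs)
    assert f2.value == pytest.approx(f1.value * factor, rel=1e-9)
    assert f2.sd == pytest.approx(f1.sd * factor, rel=1e-9)


def test_derived_organic_annual_reproduces_printed_flux(published_coefs):
    # 958 km2 of organic annual cropland -> 2.78 TgCO2 yr^-1, intensity 2.90
    f = to_co2eq(coefficient_flux(958.0, "organic_annual", "CO2", published_coefs))
    assert f.value_tg == pytest.approx(2.78, abs=1e-9)
    assert 1000 * f.value_tg / 958.0 == pytest.approx(2.90, abs=0.01)


# ------------------------------------------------------------- waterbodies

def test_river_area_rules():
    rivers = pd.DataFrame([
        {"kind": "line", "length_km": 1.0, "area_km2": np.nan},
        {"kind": "polygon", "area_km2": 2.5, "length_km": np.nan},
    ])
    assert river_area(rivers) == pytest.approx(0.0035 + 2.5)
    with pytest.raises(ValueError, match="polygon.*line|line.*polygon"):
        river_area(pd.DataFrame([{"kind": "arc", "area_km2": 1, "length_km": 1}]))


def test_river_emissions_linear_and_printed_total(published_coefs):
    f = to_co2eq(river_emissions(1388.0, published_coefs))
    assert f.value_tg == pytest.approx(7.33, abs=1e-9)
    assert 1000 * f.value_tg / 1388.0 == pytest.approx(5.28, abs=0.01)
    assert to_co2eq(river_emissions(2 * 1388.0, published_coefs)).value_tg == \
        pytest.approx(2 * 7.33, abs=1e-9)
    assert river_emissions(0.0, published_coefs).value == 0.0


def _lake_oracle(lakes, coefs, mode="substitute"):
    """Brute-force per-lake summation, independent of the engine."""
    co2 = ch4 = 0.0
    for lk in lakes.itertuples():
        sub = f"lake_class_{int(lk.size_class)}"
        cov_p = getattr(lk, "cover_phragmites", 0.0)
        cov_e = getattr(lk, "cover_equisetum", 0.0)
        open_a = lk.area_km2 * (1 - cov_p - cov_e) if mode == "substitute" else lk.area_km2
        co2 += lk.area_km2 * coefs.lookup(sub, "CO2", "co2_evasion")[0]
        ch4 += open_a * (coefs.lookup(sub, "CH4", "ch4_diffusion")[0]
                         + coefs.lookup(sub, "CH4", "ch4_ebullition")[0])
        ch4 += lk.area_km2 * cov_p * coefs.lookup("lake_macrophyte", "CH4",
                                                  "macrophyte_phragmites")[0]
        ch4 += lk.area_km2 * cov_e * coefs.lookup("lake_macrophyte", "CH4",
                                                  "macrophyte_equisetum")[0]
    return co2, ch4


def test_lake_emissions_match_per_lake_oracle(small_landscape, coefs):
    lakes = small_landscape.lakes
    for mode in ("substitute", "additive"):
        got = lake_emissions(lakes, coefs, macrophyte_mode=mode)
        co2, ch4 = _lake_oracle(lakes, coefs, mode)
        assert got["CO2"].value == pytest.approx(co2, rel=1e-12)
        assert got["CH4"].value == pytest.approx(ch4, rel=1e-12)
    # additive mode never emits less CH4 than substitution
    add = lake_emissions(lakes, coefs, macrophyte_mode="additive")
    sub = lake_emissions(lakes, coefs, macrophyte_mode="substitute")
    assert add["CH4"].value >= sub["CH4"].value


def test_single_lake_no_macrophytes_exact(coefs):
    lakes = pd.DataFrame([{"area_km2": 4.0, "size_class": 3,
                           "cover_phragmites": 0.0, "cover_equisetum": 0.0}])
    got = lake_emissions(lakes, coefs)
    d = coefs.lookup("lake_class_3", "CH4", "ch4_diffusion")[0]
    e = coefs.lookup("lake_class_3", "CH4", "ch4_ebullition")[0]
    assert got["CH4"].value == pytest.approx(4.0 * (d + e))


def test_unclassified_lake_rejected(coefs):
    lakes = pd.DataFrame([{"area_km2": 1.0, "size_class": np.nan}])
    with pytest.raises(ValueError, match="unclassified"):
        lake_emissions(lakes, coefs)


# ------------------------------------------------------------------- mires

def test_mire_fluxes_sum_classes_and_reject_missing(coefs):
    areas = {f"mire_class_{i}": 100.0 * i for i in range(1, 5)}
    out = mire_fluxes(areas, coefs)
    want_ch4 = sum(a * coefs.lookup(s, "CH4")[0] for s, a in areas.items())
    want_co2 = sum(a * coefs.lookup(s, "CO2", "ecosystem_net")[0] for s, a in areas.items())
    assert out["CH4"].value == pytest.approx(want_ch4)
    assert out["CO2_ecosystem"].value == pytest.approx(want_co2)
    assert out["CO2_ecosystem"].value < 0  # undrained mires accumulate carbon
    zero = mire_fluxes({s: 0.0 for s in areas}, coefs)
    assert all(f.value == 0 for f in zero.values())
    with pytest.raises(KeyError):
        mire_fluxes({"mire_class_9": 1.0}, coefs)


def test_mire_co2_coefficient_mass_balance_closes():
    # accumulation = -CO2_C - CH4_C - leach_C under the configured convention
    acc, ch4_c, leach = 20.0, 5.0, 7.0
    coef_gg_km2, co2_c = derive_mire_co2_coefficient(acc, ch4_c, leach)
    assert acc == pytest.approx(-co2_c - ch4_c - leach)
    assert coef_gg_km2 == pytest.approx(co2_c * 1e-3 * 44 / 12)
    # sole-term and zero cases
    assert derive_mire_co2_coefficient(0, 0, 0) == (0.0, -0.0)
    _, only_acc = derive_mire_co2_coefficient(acc, 0, 0)
    assert only_acc == -acc
    with pytest.raises(ValueError):
        derive_mire_co2_coefficient(-1, 0, 0)


def test_drained_peat_fluxes_printed_total(published_coefs):
    out = drained_peat_soil_fluxes(36725.0, published_coefs)
    total_tg = sum(to_co2eq(f).value_tg for f in out.values())
    assert total_tg == pytest.approx(1.79, abs=0.01)


# ------------------------------------------------------------------ forest

def test_harvest_emissions_molar_conversion_and_totals():
    harvest = pd.DataFrame([
        {"assortment": "timber", "soil": "mineral_soil", "carbon_gg": 12000.0, "sd_gg": 0.0},
        {"assortment": "timber", "soil": "drained_peatland", "carbon_gg": 3000.0, "sd_gg": 0.0},
        {"assortment": "energywood", "soil": "mineral_soil", "carbon_gg": 600.0, "sd_gg": 0.0},
        {"assortment": "energywood", "soil": "drained_peatland", "carbon_gg": 0.0, "sd_gg": 0.0},
    ])
    out = harvest_emissions(harvest)
    # 12 Tg C -> 44 TgCO2 -> 44 TgCO2eq
    row = out[(out.assortment == "timber") & (out.soil == "mineral_soil")]
    assert row["co2eq_gg"].iloc[0] == pytest.approx(44000.0)
    grand = out[(out.assortment == "total")]["co2eq_gg"].iloc[0]
    assert grand == pytest.approx((12000 + 3000 + 600) * 44 / 12)
    with pytest.raises(ValueError, match=">= 0"):
        harvest_emissions(pd.DataFrame([{"assortment": "timber", "soil": "mineral_soil",
                                         "carbon_gg": -1.0, "sd_gg": 0.0}]))


# ---------------------------------------------------------------- wetlands

def test_peat_production_printed_total_and_intensity(published_coefs):
    out = peat_production_emissions(1026.0, published_coefs)
    total_tg = sum(to_co2eq(f).value_tg for f in out.values())
    assert total_tg == pytest.approx(1.95, abs=0.01)
    assert 1000 * total_tg / 1026.0 == pytest.approx(1.90, abs=0.01)


# -------------------------------------------------------------- allocation

def test_allocate_uniform_and_conservation():
    mun = np.array([[1, 1, 2], [1, 1, 2]])
    proxy = np.ones_like(mun, dtype=float)
    totals = pd.DataFrame({"municipality": [1, 2], "value": [8.0, 3.0]})
    out = allocate_by_proxy(totals, proxy, mun)
    np.testing.assert_allclose(out[mun == 1], 2.0)  # 8 over 4 cells
    np.testing.assert_allclose(out[mun == 2], 1.5)
    assert out.sum() == pytest.approx(11.0)


def test_allocate_crafted_weights_match_hand_computation():
    mun = np.array([[1, 1], [2, 2]])
    proxy = np.array([[1.0, 3.0], [0.0, 5.0]])
    totals = pd.DataFrame({"municipality": [1, 2], "value": [4.0, 10.0]})
    out = allocate_by_proxy(totals, proxy, mun)
    np.testing.assert_allclose(out, [[1.0, 3.0], [0.0, 10.0]])


def test_allocate_zero_proxy_fallback_biogenic_and_errors():
    mun = np.array([[1, 1]])
    proxy = np.zeros((1, 2))
    totals = pd.DataFrame({"municipality": [1], "value": [6.0]})
    np.testing.assert_allclose(allocate_by_proxy(totals, proxy, mun), 3.0)
    # biogenic rows allocate zero
    bio = pd.DataFrame({"municipality": [1], "value": [6.0], "biogenic": [True]})
    assert allocate_by_proxy(bio, proxy, mun).sum() == 0.0
    with pytest.raises(ValueError, match="no cells"):
        allocate_by_proxy(pd.DataFrame({"municipality": [9], "value": [1.0]}),
                          proxy, mun)
    with pytest.raises(ValueError, match="non-negative"):
        allocate_by_proxy(totals, -proxy - 1, mun)


@given(st.integers(0, 2**31 - 1))
def test_allocate_conserves_any_random_instance(seed):
    rng = np.random.default_rng(seed)
    mun = rng.integers(1, 4, size=(5, 5))
    mun.ravel()[:3] = [1, 2, 3]  # every municipality has at least one cell
    proxy = rng.uniform(0, 1, size=(5, 5))
    totals = pd.DataFrame({"municipality": [1, 2, 3],
                           "value": rng.uniform(0, 100, 3)})
    out = allocate_by_proxy(totals, proxy, mun)
    assert out.sum() == pytest.approx(totals["value"].sum(), rel=1e-12)
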