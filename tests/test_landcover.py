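"""Classification, resampling and area accounting on the land-cover grid."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from shapely.geometry import box

from landghg.landcover import (CATEGORY_CODE, SUBCATEGORY_CODE, LandscapeGrid,
                               MireClassificationRule,
                               area_table_from_subcategory_areas,
                               classify_cropland, classify_lake_size,
                               resample_fractions, zone_of_region)
from landghg.national_tables import load_area_table, load_mire_rules


# ------------------------------------------------------------ lake classes

@pytest.mark.parametrize("area,expected", [
    (0.01, 1), (0.05, 1), (0.5, 2), (5.0, 3),
    (50.0, 4), (500.0, 5),
    (0.1, 2), (1.0, 3), (10.0, 4), (100.0, 5),  # half-open boundaries
])
def test_lake_size_classes(area, expected):
    assert classify_lake_size(area) == expected


def test_tiny_lake_excluded_not_raised():
    assert classify_lake_size(0.005) is None
    with pytest.raises(ValueError):
        classify_lake_size(0.0)


@given(st.floats(0.01, 1e4), st.floats(0.01, 1e4))
def test_lake_class_monotone_in_area(a, b):
    small, large = min(a, b), max(a, b)
    assert classify_lake_size(small) <= classify_lake_size(large)


# --------------------------------------------------------------- cropland

@pytest.mark.parametrize("soil,crop,expected", [
    ("Fibric Histosol", "annual", "organic_annual"),
    ("Terric Histosol", "perennial", "organic_perennial"),
    ("Gleyic Podzol", "perennial", "organic_perennial"),
    ("Umbric Gleysol", "annual", "organic_annual"),
    ("Haplic Podzol", "annual", "mineral_all_crops"),
])
def test_cropland_soil_crop_classification(soil, crop, expected):
    assert classify_cropland(soil, crop) == expected


def test_unknown_soil_strict_vs_lenient():
    with pytest.raises(ValueError, match="unknown soil-map unit"):
        classify_cropland("Mystery Soil", "annual",
                          known_units=frozenset({"Haplic Podzol"}), strict=True)
    assert classify_cropland("Mystery Soil", "annual",
                             known_units=frozenset({"Haplic Podzol"}),
                             strict=False) == "mineral_all_crops"
    with pytest.raises(ValueError):
        classify_cropland("Haplic Podzol", "biennial")


# -------------------------------------------------------------------- zones

def test_zone_split_southern_northern():
    assert zone_of_region(1) == "southern"
    assert zone_of_region(16) == "southern"
    for r in (17, 18, 19):
        assert zone_of_region(r) == "northern"
    with pytest.raises(ValueError):
        zone_of_region(20)
    # synthetic landscapes configure their own split
    assert zone_of_region(4, northern=(4,), valid=range(1, 5)) == "northern"


# -------------------------------------------------------------------- mires

def test_mire_rule_table_lookup_and_partition():
    rule = load_mire_rules()
    # every configured attribute row maps to its own class
    for r in rule.table.itertuples():
        assert rule.classify_one(r.productivity, r.fertility, r.main_class) == r.mire_class
    # a full attribute frame partitions with no loss
    attrs = rule.table[["productivity", "fertility", "main_class"]]
    classes, unclassified = rule.classify(attrs)
    assert unclassified == 0
    assert set(classes.astype(int)) <= {1, 2, 3, 4}


def test_mire_rule_gap_reported_not_raised():
    rule = MireClassificationRule(pd.DataFrame({
        "productivity": ["productive"], "fertility": ["rich"],
        "main_class": ["spruce_mire"], "mire_class": [1]}))
    attrs = pd.DataFrame({"productivity": ["productive", "unproductive"],
                          "fertility": ["rich", "poor"],
                          "main_class": ["spruce_mire", "open_bog"]})
    classes, unclassified = rule.classify(attrs)
    assert unclassified == 1 and classes.iloc[0] == 1 and np.isnan(classes.iloc[1])


def test_mire_rule_rejects_duplicates_and_missing_columns():
    dup = pd.DataFrame({"productivity": ["p", "p"], "fertility": ["r", "r"],
                        "main_class": ["m", "m"], "mire_class": [1, 2]})
    with pytest.raises(ValueError, match="duplicate"):
        MireClassificationRule(dup)
    with pytest.raises(ValueError, match="missing columns"):
        MireClassificationRule(pd.DataFrame({"productivity": []}))


# --------------------------------------------------------------- resampling

def _brute_force_fractions(mask, fine_size, coarse_size):
    """Shapely polygon-overlap oracle for area-weighted resampling."""
    nr, nc = mask.shape
    mr = round(nr * fine_size / coarse_size)
    mc = round(nc * fine_size / coarse_size)
    out = np.zeros((mr, mc))
    fine_cells = [
        (box(j * fine_size, i * fine_size, (j + 1) * fine_size, (i + 1) * fine_size))
        for i in range(nr) for j in range(nc) if mask[i, j]
    ]
    for i in range(mr):
        for j in range(mc):
            cell = box(j * coarse_size, i * coarse_size,
                       (j + 1) * coarse_size, (i + 1) * coarse_size)
            out[i, j] = sum(cell.intersection(f).area for f in fine_cells) / coarse_size**2
    return out


def test_resample_identity_and_empty():
    ones = np.ones((25, 25))
    f = resample_fractions(ones, fine_size=16.0, coarse_size=100.0)
    assert f.shape == (4, 4)
    np.testing.assert_allclose(f, 1.0, atol=1e-12)
    np.testing.assert_allclose(
        resample_fractions(np.zeros((25, 25)), 16.0, 100.0), 0.0)


def test_resample_matches_geometric_oracle_non_integer_ratio():
    rng = np.random.default_rng(7)
    mask = rng.uniform(size=(10, 10)) < 0.5
    # 10 fine cells of 16 m = 160 m = 4 coarse cells of 40 m (ratio 2.5)
    got = resample_fractions(mask.astype(float), fine_size=16.0, coarse_size=40.0)
    want = _brute_force_fractions(mask, 16.0, 40.0)
    np.testing.assert_allclose(got, want, atol=1e-9)
    # area conservation against the oracle and the input
    assert got.sum() * 40.0**2 == pytest.approx(mask.sum() * 16.0**2, rel=1e-12)


def test_resample_rejects_misaligned_extent():
    with pytest.raises(ValueError, match="do not align"):
        resample_fractions(np.ones((10, 10)), fine_size=16.0, coarse_size=250.0)


# --------------------------------------------------------- area accounting

def test_grid_requires_regions_and_partitions_area(small_landscape):
    grid = small_landscape.grid
    areas = grid.subcategory_areas()
    # subcategory areas partition category areas (full-cell assignment)
    per_cat = areas.groupby("category")["area_km2"].sum()
    counts = {
        cat: float((grid.category == CATEGORY_CODE[cat]).sum()) * grid.cell_area_km2
        for cat in per_cat.index
    }
    for cat, total in per_cat.items():
        assert total == pytest.approx(counts[cat], rel=1e-12)
    # accounted area never exceeds the full landscape
    assert areas["area_km2"].sum() <= grid.category.size * grid.cell_area_km2 + 1e-9


def test_grid_rejects_missing_region():
    cat = np.full((2, 2), CATEGORY_CODE["forest"], dtype=np.int16)
    sub = np.full((2, 2), SUBCATEGORY_CODE[("forest", "mineral_soil")], dtype=np.int16)
    with pytest.raises(ValueError, match="lack a region"):
        LandscapeGrid(category=cat, subcategory=sub, region=np.zeros((2, 2), dtype=np.int16))


def test_area_table_fractions_and_published_totals():
    t1 = load_area_table()
    # leaves plus the artificial category, which has no subcategory breakdown
    leaves = t1[(t1.level == "component")
                | ((t1.category == "artificial") & (t1.level == "category_total"))]
    table = area_table_from_subcategory_areas(
        {(r.category, r.subcategory): r.area_km2 for r in leaves.itertuples()})
    # fractions of each category sum to 100
    for _, grp in table.groupby("category"):
        assert grp["fraction_of_category_pct"].sum() == pytest.approx(100.0)
    assert table["fraction_of_total_pct"].sum() == pytest.approx(100.0)
    # printed arable shares: livestock 9 %, organic annual 4 %, perennial 5 %,
    # mineral 81 % of the category
    arable = table[table.category == "arable"].set_index("subcategory")
    assert round(arable.loc["livestock_production", "fraction_of_category_pct"]) == 9
    assert round(arable.loc["organic_annual", "fraction_of_category_pct"]) == 4
    assert round(arable.loc["organic_perennial", "fraction_of_category_pct"]) == 5
    assert round(arable.loc["mineral_all_crops", "fraction_of_category_pct"]) == 81
    # leaf areas reproduce the printed grand total to printing precision
    assert table["area_km2"].sum() == pytest.approx(306954, abs=5)
    # printed category totals match leaf sums (small printing inconsistencies
    # in the published arable/waterbody totals stay within 120 km2)
    printed = t1[t1.level == "category_total"].set_index("category")["area_km2"]
    leaf_sums = table.groupby("category")["area_km2"].sum()
    for cat in ("forest", "wetland"):
        assert leaf_sums[cat] == pytest.approx(printed[cat])
    for cat in ("arable", "waterbody"):
        assert abs(leaf_sums[cat] - printed[cat]) <= 120


def test_empty_landscape_all_zero_table():
    table = area_table_from_subcategory_areas({("forest", "mineral_soil"): 0.0})
    assert (table["area_km2"] == 0).all()
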