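"""Synthetic boreal landscapes with known ground-truth fluxes.

The generator builds a complete, seed-deterministic input bundle for the
accounting pipeline — category/subcategory/region rasters, lake and river
registries, municipal sector totals, forest harvest/NEE inputs, a "true"
coefficient table and per-region populations — and computes the resulting
fluxes by direct per-cell / per-feature multiplication. That stored ground
truth is the oracle against which the pipeline is verified end to end.

Spatial structure is deliberately simple: regions are contiguous Voronoi
blocks, categories are a smoothed Gaussian random field thresholded by rank
to hit the target area fractions (defaults: the published national category
shares — artificial 3 %, arable 7 %, forest 69 %, waterbody 11 %,
wetland 10 %), and subcategories are per-cell draws from mixture weights.
No engine depends on spatial autocorrelation, so this suffices to exercise
every code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .engines import NARROW_RIVER_WIDTH_KM, CoefficientTable
from .gases import GWP100, SPECIES
from .landcover import (CATEGORY_CODE, SUBCATEGORY_CODE, LandscapeGrid,
                        classify_lake_size, zone_of_region)

__all__ = ["SyntheticConfig", "SyntheticLandscape", "default_true_coefficients",
           "generate_landscape", "calibrate_to_areas"]

#: Published national category shares of total land-cover area.
DEFAULT_CATEGORY_FRACTIONS = {
    "artificial": 0.03, "arable": 0.07, "forest": 0.69,
    "waterbody": 0.11, "wetland": 0.10,
}

DEFAULT_SUBCATEGORY_WEIGHTS = {
    # Arable shares follow the national accounting (9/4/5/81 % of category,
    # i.e. ~9 % of cropland on organic soils).
    "arable": {"livestock_production": 0.09, "organic_annual": 0.04,
               "organic_perennial": 0.05, "mineral_all_crops": 0.82},
    "forest": {"mineral_soil": 0.83, "drained_peatland": 0.17},
    "waterbody": {"river": 0.04, "lake_class_1": 0.06, "lake_class_2": 0.20,
                  "lake_class_3": 0.30, "lake_class_4": 0.25, "lake_class_5": 0.15},
    "wetland": {"peat_production": 0.03, "mire": 0.97},
    "artificial": {"energy": 0.2, "industry": 0.15, "road_traffic": 0.25,
                   "machinery": 0.1, "residential_combustion": 0.2, "waste": 0.1},
}

# Mire class mixtures by zone: forested mires dominate the south, sedge and
# other fens the north.
DEFAULT_MIRE_MIX = {
    "southern": {"mire_class_1": 0.50, "mire_class_2": 0.15,
                 "mire_class_3": 0.15, "mire_class_4": 0.20},
    "northern": {"mire_class_1": 0.10, "mire_class_2": 0.40,
                 "mire_class_3": 0.30, "mire_class_4": 0.20},
}


@dataclass
class SyntheticConfig:
    seed: int = 0
    shape: tuple[int, int] = (120, 120)
    cell_size: float = 250.0
    n_regions: int = 5
    n_northern: int = 1  # last n region ids are the northern zone
    category_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_FRACTIONS))
    subcategory_weights: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SUBCATEGORY_WEIGHTS.items()})
    mire_mix: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MIRE_MIX.items()})
    n_lakes: int = 120
    lake_area_range_km2: tuple[float, float] = (0.005, 300.0)  # log-uniform; below 1 ha excluded
    macrophyte_cover_prob: float = 0.3
    macrophyte_cover_max: float = 0.15
    n_rivers: int = 30
    smoothing_sigma: float = 3.0
    coefficient_sd_fraction: float = 0.1

    def __post_init__(self):
        total = sum(self.category_fractions.values())
        if any(f < 0 or f > 1 for f in self.category_fractions.values()) or total > 1 + 1e-9:
            raise ValueError(f"category fractions must lie in [0,1] and sum <= 1, got {total}")
        if not 1 <= self.n_northern < self.n_regions:
            raise ValueError("n_northern must be in [1, n_regions)")

    @property
    def northern_regions(self) -> tuple[int, ...]:
        return tuple(range(self.n_regions - self.n_northern + 1, self.n_regions + 1))

    @property
    def region_ids(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_regions + 1))


def default_true_coefficients(sd_fraction: float = 0.1) -> CoefficientTable:
    """A plausible "true" coefficient table (Gg gas km^-2 yr^-1).

    Magnitudes follow the implied national coefficients: organic cropland
    CO2 of order 2-3 Gg km^-2, river evasion ~5, lake evasion a few tenths,
    mire CH4 of order 0.3-0.5 and ecosystem CO2 net uptake ~0.1-0.2.
    Mineral cropland carries a southern/northern zone split to exercise
    zonal lookup. Uncertainty half-widths are sd_fraction x value.
    """
    rows: list[dict] = []

    def add(category, subcategory, gas, value, term="flux", zone="national"):
        rows.append({"category": category, "subcategory": subcategory, "gas": gas,
                     "term": term, "zone": zone, "value": value,
                     "sd": abs(value) * sd_fraction, "unit": "Gg/km2", "basis": "gas"})

    add("arable", "organic_annual", "CO2", 2.9)
    add("arable", "organic_perennial", "CO2", 2.1)
    add("arable", "mineral_all_crops", "CO2", 0.020, zone="southern")
    add("arable", "mineral_all_crops", "CO2", 0.032, zone="northern")
    add("forest", "drained_peatland", "CH4", 0.00034)
    add("forest", "drained_peatland", "CO2", 0.0)
    add("forest", "drained_peatland", "N2O", 0.000148)
    add("waterbody", "river", "CO2", 5.28)
    for i, (ev, di, eb) in enumerate([(0.30, 0.0030, 0.0028), (0.22, 0.0020, 0.0018),
                                      (0.16, 0.0012, 0.0010), (0.12, 0.0008, 0.0006),
                                      (0.10, 0.0005, 0.0004)], start=1):
        add("waterbody", f"lake_class_{i}", "CO2", ev, term="co2_evasion")
        add("waterbody", f"lake_class_{i}", "CH4", di, term="ch4_diffusion")
        add("waterbody", f"lake_class_{i}", "CH4", eb, term="ch4_ebullition")
    add("waterbody", "lake_macrophyte", "CH4", 0.060, term="macrophyte_phragmites")
    add("waterbody", "lake_macrophyte", "CH4", 0.040, term="macrophyte_equisetum")
    add("wetland", "peat_production", "CH4", 0.0021)
    add("wetland", "peat_production", "CO2", 1.75)
    add("wetland", "peat_production", "N2O", 0.00033)
    for cls, (ch4, n2o, co2net) in enumerate([(0.010, 0.00002, -0.20),
                                              (0.018, 0.00001, -0.10),
                                              (0.014, 0.00001, -0.12),
                                              (0.008, 0.00000, -0.15)], start=1):
        add("wetland", f"mire_class_{cls}", "CH4", ch4)
        add("wetland", f"mire_class_{cls}", "N2O", n2o)
        add("wetland", f"mire_class_{cls}", "CO2", co2net, term="ecosystem_net")
    return CoefficientTable(pd.DataFrame(rows))


@dataclass
class SyntheticLandscape:
    """Generated inputs plus the generator's direct-multiplication ground truth."""

    config: SyntheticConfig
    grid: LandscapeGrid
    municipality: np.ndarray
    proxy: np.ndarray
    lakes: pd.DataFrame
    rivers: pd.DataFrame
    sector_totals: pd.DataFrame  # municipality, category, sector, gas, value_gg, biogenic
    forest_inputs: pd.DataFrame  # region, component, value_gg (harvest C >=0, NEE CO2 <0)
    coefficients: CoefficientTable
    populations: dict[int, int]
    ground_truth: pd.DataFrame  # region, category, component, gas, co2eq_tg
    area_scale: dict[tuple[str, str], float] = field(default_factory=dict)

    def areas(self, by_region: bool = False) -> pd.DataFrame:
        """Subcategory areas from the grid, with calibration scales applied."""
        df = self.grid.subcategory_areas(by_region=by_region).copy()
        if self.area_scale:
            scale = [self.area_scale.get((c, s), 1.0)
                     for c, s in zip(df["category"], df["subcategory"])]
            df["area_km2"] = df["area_km2"] * scale
        return df

    def region_areas(self) -> dict[int, float]:
        reg = self.grid.region
        ids, counts = np.unique(reg[reg > 0], return_counts=True)
        return {int(i): float(n) * self.grid.cell_area_km2 for i, n in zip(ids, counts)}

    def zone(self, region: int) -> str:
        return zone_of_region(region, northern=self.config.northern_regions,
                              valid=self.config.region_ids)


def _assign_categories(rng, shape, fractions, sigma):
    """Rank-threshold a smoothed field so category cell counts hit fractions."""
    fieldv = gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    order = np.argsort(fieldv.ravel(), kind="stable")
    n = order.size
    cat = np.zeros(n, dtype=np.int16)  # 0 = excluded
    start = 0
    for name in ("artificial", "arable", "forest", "waterbody", "wetland"):
        count = int(round(n * fractions.get(name, 0.0)))
        cat[order[start:start + count]] = CATEGORY_CODE[name]
        start += count
    return cat.reshape(shape)


def _weighted_draw(rng, keys, weights_map, size):
    keys = list(keys)
    w = np.array([weights_map[k] for k in keys], dtype=float)
    w = w / w.sum()
    return rng.choice(len(keys), size=size, p=w), keys


def generate_landscape(config: SyntheticConfig) -> SyntheticLandscape:
    """Generate a landscape bundle; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    shape = config.shape
    nr, nc = shape
    cell_area = (config.cell_size / 1000.0) ** 2

    # Regions: contiguous Voronoi blocks of random seed points.
    seeds = rng.uniform(0, [nr, nc], size=(config.n_regions, 2))
    rows, cols = np.mgrid[0:nr, 0:nc]
    centers = np.column_stack([rows.ravel() + 0.5, cols.ravel() + 0.5])
    _, nearest = cKDTree(seeds).query(centers)
    region = (nearest + 1).astype(np.int16).reshape(shape)

    category = _assign_categories(rng, shape, config.category_fractions,
                                  config.smoothing_sigma)

    # Subcategories by per-cell mixture draws; mire classes by zone.
    subcategory = np.zeros(shape, dtype=np.int16)
    northern = set(config.northern_regions)
    for cat_name, weights in config.subcategory_weights.items():
        mask = category == CATEGORY_CODE[cat_name]
        idx = np.flatnonzero(mask.ravel())
        if idx.size == 0:
            continue
        if cat_name == "wetland":
            draws, keys = _weighted_draw(rng, weights, weights, idx.size)
            is_mire = np.array([keys[d] == "mire" for d in draws])
            flat_sub = subcategory.ravel()
            flat_sub[idx[~is_mire]] = SUBCATEGORY_CODE[("wetland", "peat_production")]
            # zone-dependent mire class mixture
            reg_flat = region.ravel()
            for zone, mix in config.mire_mix.items():
                zmask = np.array([
                    (reg_flat[i] in northern) == (zone == "northern") for i in idx])
                sel = idx[is_mire & zmask]
                if sel.size:
                    d2, k2 = _weighted_draw(rng, mix, mix, sel.size)
                    flat_sub[sel] = [SUBCATEGORY_CODE[("wetland", k2[d])] for d in d2]
            subcategory = flat_sub.reshape(shape)
        else:
            draws, keys = _weighted_draw(rng, weights, weights, idx.size)
            flat_sub = subcategory.ravel()
            flat_sub[idx] = [SUBCATEGORY_CODE[(cat_name, keys[d])] for d in draws]
            subcategory = flat_sub.reshape(shape)

    grid = LandscapeGrid(category=category, subcategory=subcategory,
                         region=region, cell_size=config.cell_size)

    # Municipalities: each region split in two along its median column.
    municipality = np.zeros(shape, dtype=np.int32)
    for r in config.region_ids:
        mask = region == r
        med = np.median(cols[mask])
        municipality[mask & (cols <= med)] = r * 10 + 1
        municipality[mask & (cols > med)] = r * 10 + 2
    proxy = rng.gamma(2.0, 1.0, size=shape)

    # Lake registry: log-uniform areas; sub-1-ha lakes generated then excluded.
    lo, hi = config.lake_area_range_km2
    areas = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_lakes))
    lake_rows = []
    for i, a in enumerate(areas):
        cls = classify_lake_size(float(a))
        if cls is None:
            continue  # below the 1 ha accounting minimum
        covers = {}
        for sp in ("phragmites", "equisetum"):
            covers[sp] = (rng.uniform(0, config.macrophyte_cover_max)
                          if rng.uniform() < config.macrophyte_cover_prob else 0.0)
        lake_rows.append({
            "id": i, "area_km2": float(a), "size_class": cls,
            "cover_phragmites": covers["phragmites"],
            "cover_equisetum": covers["equisetum"],
            "region": int(rng.integers(1, config.n_regions + 1)),
        })
    lakes = pd.DataFrame(lake_rows)

    river_rows = []
    for i in range(config.n_rivers):
        kind = "polygon" if rng.uniform() < 0.5 else "line"
        river_rows.append({
            "id": i, "kind": kind,
            "area_km2": float(rng.uniform(1, 20)) if kind == "polygon" else np.nan,
            "length_km": float(rng.uniform(5, 200)) if kind == "line" else np.nan,
            "region": int(rng.integers(1, config.n_regions + 1)),
        })
    rivers = pd.DataFrame(river_rows)

    # Municipal sector totals (Gg gas yr^-1): artificial area sources plus the
    # agricultural activity sectors; one biogenic-CO2 row per municipality.
    sector_gases = {
        ("artificial", "energy"): ("CO2",),
        ("artificial", "industry"): ("CO2",),
        ("artificial", "road_traffic"): ("CO2",),
        ("artificial", "machinery"): ("CO2",),
        ("artificial", "residential_combustion"): ("CH4", "CO2", "N2O"),
        ("artificial", "waste"): ("CH4", "N2O"),
        ("arable", "livestock_production"): ("CH4", "N2O"),
        ("arable", "field_cultivation"): ("CO2", "N2O"),
    }
    scale = {"CO2": 40.0, "CH4": 1.5, "N2O": 0.02}
    sector_rows = []
    for m in sorted(np.unique(municipality[municipality > 0])):
        for (cat_name, sector), gases in sector_gases.items():
            for gas in gases:
                sector_rows.append({
                    "municipality": int(m), "category": cat_name, "sector": sector,
                    "gas": gas, "value_gg": float(rng.uniform(0.1, 1.0) * scale[gas]),
                    "biogenic": False,
                })
        sector_rows.append({"municipality": int(m), "category": "artificial",
                            "sector": "energy_biogenic", "gas": "CO2",
                            "value_gg": float(rng.uniform(1, 10)), "biogenic": True})
    sector_totals = pd.DataFrame(sector_rows)

    # Forest inputs per region: harvested C (Gg C yr^-1) and NEE (Gg CO2 yr^-1,
    # negative = sequestration), for each soil class.
    forest_rows = []
    for r in config.region_ids:
        for assortment in ("timber", "energywood"):
            for soil in ("mineral_soil", "drained_peatland"):
                base = 150.0 if assortment == "timber" else 20.0
                forest_rows.append({"region": r, "component": f"harvest_{assortment}_{soil}",
                                    "value_gg": float(rng.uniform(0.5, 1.5) * base)})
        forest_rows.append({"region": r, "component": "nee_mineral_soil",
                            "value_gg": float(-rng.uniform(500, 2000))})
        forest_rows.append({"region": r, "component": "nee_drained_peatland",
                            "value_gg": float(-rng.uniform(20, 200))})
    forest_inputs = pd.DataFrame(forest_rows)

    coefficients = default_true_coefficients(config.coefficient_sd_fraction)
    populations = {r: int(rng.integers(50_000, 2_000_000))
                   for r in config.region_ids}

    landscape = SyntheticLandscape(
        config=config, grid=grid, municipality=municipality, proxy=proxy,
        lakes=lakes, rivers=rivers, sector_totals=sector_totals,
        forest_inputs=forest_inputs, coefficients=coefficients,
        populations=populations, ground_truth=pd.DataFrame())
    landscape.ground_truth = _direct_ground_truth(landscape)
    return landscape


def _direct_ground_truth(ls: SyntheticLandscape) -> pd.DataFrame:
    """Fluxes by direct multiplication — the oracle the pipeline must match.

    Deliberately plain arithmetic (no engine calls except the shared
    coefficient lookup values, re-read here from the raw table) so the
    pipeline and the oracle are independent code paths.
    """
    cfg = ls.config
    coef = {}
    for r in ls.coefficients.table.itertuples():
        coef[(r.subcategory, r.gas, r.term, r.zone)] = r.value

    def c(sub, gas, term="flux", zone="national"):
        if (sub, gas, term, zone) in coef:
            return coef[(sub, gas, term, zone)]
        return coef[(sub, gas, term, "national")]

    rows = []

    def emit(region, category, component, gas, gas_gg):
        rows.append({"region": region, "category": category, "component": component,
                     "gas": gas, "co2eq_tg": gas_gg * GWP100[gas] / 1000.0})

    areas = ls.areas(by_region=True)

    # Sector totals (municipal -> region, biogenic excluded).
    mun_region = {m: m // 10 for m in ls.sector_totals["municipality"].unique()}
    for r in ls.sector_totals.itertuples():
        if r.biogenic:
            continue
        emit(mun_region[r.municipality], r.category, r.sector, r.gas, r.value_gg)

    # Coefficient-driven land subcategories.
    for row in areas.itertuples():
        cat, sub, region, area = row.category, row.subcategory, int(row.region), row.area_km2
        zone = ls.zone(region)
        if cat == "arable" and sub in ("organic_annual", "organic_perennial",
                                       "mineral_all_crops"):
            emit(region, cat, sub, "CO2", area * c(sub, "CO2", zone=zone))
        elif cat == "forest" and sub == "drained_peatland":
            for gas in ("CH4", "CO2", "N2O"):
                emit(region, cat, "drained_peat_soil_" + gas, gas,
                     area * c(sub, gas))
        elif cat == "wetland" and sub == "peat_production":
            for gas in ("CH4", "CO2", "N2O"):
                emit(region, cat, "peat_production_" + gas, gas, area * c(sub, gas))
        elif cat == "wetland" and sub.startswith("mire_class"):
            emit(region, cat, f"{sub}_CH4", "CH4", area * c(sub, "CH4"))
            emit(region, cat, f"{sub}_N2O", "N2O", area * c(sub, "N2O"))
            emit(region, cat, f"{sub}_CO2net", "CO2",
                 area * c(sub, "CO2", term="ecosystem_net"))

    # Lakes per feature.
    for lake in ls.lakes.itertuples():
        sub = f"lake_class_{int(lake.size_class)}"
        area = lake.area_km2
        cover = lake.cover_phragmites + lake.cover_equisetum
        open_area = area * (1 - cover)
        emit(lake.region, "waterbody", "lake_co2", "CO2",
             area * c(sub, "CO2", "co2_evasion"))
        ch4 = open_area * (c(sub, "CH4", "ch4_diffusion") + c(sub, "CH4", "ch4_ebullition"))
        ch4 += area * lake.cover_phragmites * c("lake_macrophyte", "CH4", "macrophyte_phragmites")
        ch4 += area * lake.cover_equisetum * c("lake_macrophyte", "CH4", "macrophyte_equisetum")
        emit(lake.region, "waterbody", "lake_ch4", "CH4", ch4)

    # Rivers per feature (3.5 m width rule for line geometries).
    for river in ls.rivers.itertuples():
        area = river.area_km2 if river.kind == "polygon" else river.length_km * NARROW_RIVER_WIDTH_KM
        emit(river.region, "waterbody", "river_co2", "CO2", area * c("river", "CO2"))

    # Forest harvest (C -> CO2) and NEE inputs.
    for r in ls.forest_inputs.itertuples():
        if r.component.startswith("harvest"):
            emit(r.region, "forest", r.component, "CO2", r.value_gg * 44.0 / 12.0)
        else:
            emit(r.region, "forest", r.component, "CO2", r.value_gg)

    return pd.DataFrame(rows)


def calibrate_to_areas(landscape: SyntheticLandscape,
                       target: Mapping[tuple[str, str], float]) -> SyntheticLandscape:
    """Rescale subcategory areas (and registries) to match a target table.

    Target keys are (category, subcategory); the aggregate keys
    ('artificial', 'all'), ('waterbody', 'lakes') and
    ('wetland', 'undrained_mires') scale all their member subcategories by
    one common factor. Grids are untouched — calibration is a
    per-subcategory multiplicative area scale applied in accounting, with
    lake/river registries rescaled consistently (size-class labels are kept
    fixed). Downstream fluxes scale linearly with the areas. A nonzero
    target for a subcategory absent from the landscape is rejected.
    """
    current = landscape.areas()
    cur = {(r.category, r.subcategory): r.area_km2 for r in current.itertuples()}

    def members(cat, sub):
        if sub == "all":
            return [k for k in cur if k[0] == cat]
        if (cat, sub) == ("waterbody", "lakes"):
            return [k for k in cur if k[0] == "waterbody" and k[1].startswith("lake_class")]
        if (cat, sub) == ("wetland", "undrained_mires"):
            return [k for k in cur if k[0] == "wetland" and k[1].startswith("mire_class")]
        return [(cat, sub)]

    scale = dict(landscape.area_scale)
    lake_factor = river_factor = None
    for (cat, sub), tgt in target.items():
        keys = members(cat, sub)
        base = sum(cur.get(k, 0.0) for k in keys)
        if base == 0:
            if tgt != 0:
                raise ValueError(f"target {tgt} km2 for {(cat, sub)} but landscape has none")
            continue
        f = tgt / base
        for k in keys:
            scale[k] = scale.get(k, 1.0) * f
        if (cat, sub) == ("waterbody", "lakes"):
            lake_factor = f
        if (cat, sub) == ("waterbody", "river"):
            river_factor = f

    lakes = landscape.lakes.copy()
    registry_lake_factor = None
    if lake_factor is not None and len(lakes):
        registry_lake_factor = target[("waterbody", "lakes")] / lakes["area_km2"].sum()
        lakes["area_km2"] = lakes["area_km2"] * registry_lake_factor
    rivers = landscape.rivers.copy()
    if river_factor is not None and len(rivers):
        from .engines import river_area
        f = target[("waterbody", "river")] / river_area(rivers)
        rivers["area_km2"] = rivers["area_km2"] * f
        rivers["length_km"] = rivers["length_km"] * f

    out = replace(landscape, lakes=lakes, rivers=rivers, area_scale=scale)
    out.ground_truth = _direct_ground_truth(out)
    return out
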