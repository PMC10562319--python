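"""Land-cover grids, subcategory classification and area accounting.

The landscape is represented as co-registered row-major rasters (origin at
the north-west corner, 0-based indices) of land-cover category, subcategory
and administrative region, on a square accounting grid (default 250 m, cell
area 0.0625 km2). Finer-resolution binary masks (e.g. 16 m forest-soil
layers) are brought onto the accounting grid by exact area-weighted overlap,
since the accounting cell size need not be an integer multiple of the fine
cell size.

Subcategory classifiers implement the closed class lists of the accounting
scheme: five lake size classes, organic/mineral cropland split by soil-map
unit crossed with annual/perennial crops, four undrained-mire classes driven
by a data-table rule, and a southern/northern zone lookup by region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "SUBCATEGORIES",
    "ORGANIC_SOIL_UNITS",
    "LAKE_CLASS_BOUNDS",
    "LandscapeGrid",
    "MireClassificationRule",
    "classify_lake_size",
    "classify_cropland",
    "zone_of_region",
    "resample_fractions",
    "area_table_from_subcategory_areas",
    "area_accounting",
]

CATEGORIES = ("excluded", "artificial", "arable", "forest", "waterbody", "wetland")

SUBCATEGORIES: dict[str, tuple[str, ...]] = {
    "artificial": ("energy", "industry", "road_traffic", "machinery",
                   "residential_combustion", "waste"),
    "arable": ("livestock_production", "organic_annual", "organic_perennial",
               "mineral_all_crops"),
    "forest": ("mineral_soil", "drained_peatland"),
    "waterbody": ("river", "lake_class_1", "lake_class_2", "lake_class_3",
                  "lake_class_4", "lake_class_5"),
    "wetland": ("peat_production", "mire_class_1", "mire_class_2",
                "mire_class_3", "mire_class_4"),
}

# Integer raster codes: 0 = none/excluded; categories and subcategories each
# get a stable global code.
CATEGORY_CODE = {name: i for i, name in enumerate(CATEGORIES)}
SUBCATEGORY_CODE: dict[tuple[str, str], int] = {}
_code = 1
for _cat in CATEGORIES[1:]:
    for _sub in SUBCATEGORIES[_cat]:
        SUBCATEGORY_CODE[(_cat, _sub)] = _code
        _code += 1
CODE_SUBCATEGORY = {v: k for k, v in SUBCATEGORY_CODE.items()}

# Soil-map units treated as organic cropland soils.
ORGANIC_SOIL_UNITS = frozenset({
    "Gleyic Podzol", "Umbric Gleysol", "Fibric Histosol", "Terric Histosol",
})

# Lake size classes, km2, half-open [lower, upper); class 5 unbounded above.
LAKE_CLASS_BOUNDS = ((0.01, 0.1), (0.1, 1.0), (1.0, 10.0), (10.0, 100.0),
                     (100.0, np.inf))
MIN_LAKE_AREA_KM2 = 0.01  # 1 ha


def classify_lake_size(area_km2: float, min_area: float = MIN_LAKE_AREA_KM2) -> int | None:
    """Return the lake size class 1-5 for an area in km2.

    Classes are half-open intervals [lower, upper); class 5 is [100, inf).
    Lakes below the 1 ha minimum are excluded from accounting and signalled
    with ``None`` (not an exception).
    """
    if not area_km2 > 0:
        raise ValueError(f"lake area must be positive, got {area_km2}")
    if area_km2 < min_area:
        return None
    for i, (lo, hi) in enumerate(LAKE_CLASS_BOUNDS, start=1):
        if lo <= area_km2 < hi:
            return i
    return len(LAKE_CLASS_BOUNDS)  # pragma: no cover


def classify_cropland(soil_class: str, crop_type: str, *,
                      organic_units: frozenset[str] = ORGANIC_SOIL_UNITS,
                      known_units: frozenset[str] | None = None,
                      strict: bool = True) -> str:
    """Map (soil-map unit, annual|perennial) to an arable subcategory.

    Organic soils split by crop type into ``organic_annual`` /
    ``organic_perennial``; every other known unit maps to
    ``mineral_all_crops``. In strict mode an unknown soil unit is rejected;
    in lenient mode it defaults to mineral.
    """
    if crop_type not in ("annual", "perennial"):
        raise ValueError(f"crop_type must be 'annual' or 'perennial', got {crop_type!r}")
    if soil_class in organic_units:
        return "organic_annual" if crop_type == "annual" else "organic_perennial"
    if known_units is not None and soil_class not in known_units:
        if strict:
            raise ValueError(f"unknown soil-map unit {soil_class!r}")
    return "mineral_all_crops"


def zone_of_region(region_id: int,
                   northern: Sequence[int] = (17, 18, 19),
                   valid: Sequence[int] | None = None) -> str:
    """Southern/northern zone of a region (default: regions 17-19 northern).

    ``valid`` restricts the accepted region ids (default 1-19); synthetic
    landscapes may pass their own id set and northern subset.
    """
    ids = set(valid) if valid is not None else set(range(1, 20))
    if region_id not in ids:
        raise ValueError(f"unknown region id {region_id}")
    return "northern" if region_id in set(northern) else "southern"


@dataclass
class MireClassificationRule:
    """Attribute lookup mapping mire site attributes to mire classes 1-4.

    The rule table is data, not code: rows of (productivity, fertility,
    main_class) -> mire_class. ``classify`` returns a class for each input
    row and counts combinations absent from the table instead of raising,
    so unclassifiable area is surfaced rather than silently dropped.
    """

    table: pd.DataFrame  # columns: productivity, fertility, main_class, mire_class

    KEY = ("productivity", "fertility", "main_class")

    def __post_init__(self):
        missing = (set(self.KEY) | {"mire_class"}) - set(self.table.columns)
        if missing:
            raise ValueError(f"mire rule table missing columns {sorted(missing)}")
        if self.table.duplicated(subset=list(self.KEY)).any():
            raise ValueError("mire rule table has duplicate attribute combinations")
        self._lookup = {
            tuple(row[k] for k in self.KEY): int(row["mire_class"])
            for _, row in self.table.iterrows()
        }

    def classify_one(self, productivity: str, fertility: str, main_class: str) -> int | None:
        return self._lookup.get((productivity, fertility, main_class))

    def classify(self, attributes: pd.DataFrame) -> tuple[pd.Series, int]:
        """Classify attribute rows; returns (classes with NaN for gaps, n_unclassified)."""
        keys = list(zip(*(attributes[k] for k in self.KEY)))
        classes = pd.Series([self._lookup.get(k) for k in keys],
                            index=attributes.index, dtype="float")
        return classes, int(classes.isna().sum())


@dataclass
class LandscapeGrid:
    """Co-registered category / subcategory / region rasters.

    ``category`` and ``subcategory`` hold the integer codes of
    ``CATEGORY_CODE`` / ``SUBCATEGORY_CODE``; ``region`` holds region ids
    (0 = unassigned, only legal on excluded cells). ``cell_size`` is the
    cell edge in metres; cell area is cell_size^2.
    """

    category: np.ndarray
    subcategory: np.ndarray
    region: np.ndarray
    cell_size: float = 250.0
    origin: tuple[float, float] = (0.0, 0.0)  # NW corner (x, y)

    def __post_init__(self):
        if not (self.category.shape == self.subcategory.shape == self.region.shape):
            raise ValueError("category, subcategory and region rasters must share a shape")
        bad = (self.region <= 0) & (self.category != CATEGORY_CODE["excluded"])
        if bad.any():
            raise ValueError(f"{int(bad.sum())} non-excluded cells lack a region")

    @property
    def shape(self) -> tuple[int, int]:
        return self.category.shape

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def subcategory_areas(self, by_region: bool = False) -> pd.DataFrame:
        """Cell-count areas (km2) per (category, subcategory[, region])."""
        rows = []
        sub = self.subcategory.ravel()
        reg = self.region.ravel()
        if by_region:
            df = pd.DataFrame({"code": sub, "region": reg})
            counts = df[df.code > 0].groupby(["code", "region"]).size()
            for (code, region), n in counts.items():
                cat, s = CODE_SUBCATEGORY[int(code)]
                rows.append((cat, s, int(region), n * self.cell_area_km2))
            return pd.DataFrame(rows, columns=["category", "subcategory", "region",
                                               "area_km2"])
        codes, counts = np.unique(sub[sub > 0], return_counts=True)
        for code, n in zip(codes, counts):
            cat, s = CODE_SUBCATEGORY[int(code)]
            rows.append((cat, s, n * self.cell_area_km2))
        return pd.DataFrame(rows, columns=["category", "subcategory", "area_km2"])


def _overlap_matrix(n_fine: int, fine_size: float, n_coarse: int,
                    coarse_size: float) -> np.ndarray:
    """1-D interval-overlap lengths between coarse and fine cells (metres)."""
    w = np.zeros((n_coarse, n_fine))
    for i in range(n_coarse):
        lo, hi = i * coarse_size, (i + 1) * coarse_size
        j0 = max(int(lo // fine_size), 0)
        j1 = min(int(np.ceil(hi / fine_size)), n_fine)
        for j in range(j0, j1):
            w[i, j] = max(0.0, min(hi, (j + 1) * fine_size) - max(lo, j * fine_size))
    return w


def resample_fractions(fine_mask: np.ndarray, fine_size: float,
                       coarse_size: float) -> np.ndarray:
    """Fractional cover of a fine binary mask on a coarser co-registered grid.

    Exact area-weighted overlap (separable along rows and columns), valid
    for any size ratio — in particular 16 m -> 250 m, where the coarse cell
    is not an integer multiple of the fine cell. The two grids must share
    the origin and span the same extent (rejected otherwise). Total covered
    area is conserved exactly up to floating-point rounding.
    """
    fine_mask = np.asarray(fine_mask, dtype=float)
    nr, nc = fine_mask.shape
    for n in (nr, nc):
        extent = n * fine_size
        if abs(extent / coarse_size - round(extent / coarse_size)) > 1e-9:
            raise ValueError(
                f"fine extent {extent} m is not a whole number of {coarse_size} m "
                "coarse cells; grids do not align")
    mr = int(round(nr * fine_size / coarse_size))
    mc = int(round(nc * fine_size / coarse_size))
    wr = _overlap_matrix(nr, fine_size, mr, coarse_size)
    wc = _overlap_matrix(nc, fine_size, mc, coarse_size)
    frac = wr @ fine_mask @ wc.T / coarse_size**2
    return np.clip(frac, 0.0, 1.0)


def area_table_from_subcategory_areas(areas: Mapping[tuple[str, str], float]) -> pd.DataFrame:
    """Build the area-accounting table from (category, subcategory) -> km2.

    Returns subcategory rows with the category share and total-area share in
    percent; category totals are sums of their subcategories by
    construction.
    """
    df = pd.DataFrame(
        [(c, s, a) for (c, s), a in areas.items()],
        columns=["category", "subcategory", "area_km2"],
    )
    cat_tot = df.groupby("category")["area_km2"].transform("sum")
    total = df["area_km2"].sum()
    df["fraction_of_category_pct"] = np.where(cat_tot > 0, 100 * df["area_km2"] / cat_tot, 0.0)
    df["fraction_of_total_pct"] = 100 * df["area_km2"] / total if total > 0 else 0.0
    return df


def area_accounting(grid: LandscapeGrid,
                    registries: Mapping[str, pd.DataFrame] | None = None) -> pd.DataFrame:
    """Area table for a landscape grid, waterbody areas from registries.

    Land areas come from cell counts; lake and river areas are taken from
    the feature registries when supplied (mapped polygon/line geometry is
    more accurate than 250 m cell counts for water), replacing the gridded
    waterbody rows. Narrow line rivers contribute length x 3.5 m.
    """
    areas: dict[tuple[str, str], float] = {}
    for _, row in grid.subcategory_areas().iterrows():
        areas[(row["category"], row["subcategory"])] = row["area_km2"]
    if registries:
        if "lakes" in registries:
            lakes = registries["lakes"]
            areas = {k: v for k, v in areas.items()
                     if not (k[0] == "waterbody" and k[1].startswith("lake_class"))}
            for cls, a in lakes.groupby("size_class")["area_km2"].sum().items():
                areas[("waterbody", f"lake_class_{int(cls)}")] = float(a)
        if "rivers" in registries:
            from .engines import river_area  # runtime import: engines uses this module
            areas[("waterbody", "river")] = river_area(registries["rivers"])
    return area_table_from_subcategory_areas(areas)
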