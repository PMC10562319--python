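"""Readers/writers for grids, registries and reports, plus run configuration.

Rasters travel as ESRI ASCII grid text (one header block, whitespace-
separated rows, north-west origin), vector registries and tables as CSV
(UTF-8, comma separator, '.' decimal, no thousands separators). All layers
of a bundle must share the grid geometry (shape, cell size, origin);
mismatches are rejected at load. Report CSVs are deterministic — identical
inputs give byte-identical files — and carry a provenance comment header
(package version, config hash, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engines import CoefficientTable
from .landcover import LandscapeGrid
from .synthetic import SyntheticConfig, SyntheticLandscape

log = logging.getLogger("landghg")

__all__ = ["RunConfig", "write_ascii_grid", "read_ascii_grid",
           "save_landscape", "load_landscape", "write_reports"]

MODES = ("published", "pipeline", "synthetic")


@dataclass
class RunConfig:
    """Validated run configuration for the three CLI modes."""

    mode: str
    inputs_dir: str | None = None
    out_dir: str = "out"
    seed: int = 0
    macrophyte_mode: str = "substitute"
    strict: bool = True
    net_sd_override_tg: float | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "pipeline" and not self.inputs_dir:
            raise ValueError("pipeline mode requires inputs_dir")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        try:
            return cls(**data)
        except TypeError as e:
            raise ValueError(f"invalid run config {path}: {e}") from None

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ------------------------------------------------------------------ rasters

def write_ascii_grid(path: str | Path, array: np.ndarray, cell_size: float,
                     origin: tuple[float, float] = (0.0, 0.0),
                     nodata: float = -9999) -> None:
    """Write a raster as ESRI ASCII grid text (row 0 = northern edge)."""
    a = np.asarray(array)
    nrows, ncols = a.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {origin[0]}\n")
        fh.write(f"yllcorner {origin[1] - nrows * cell_size}\n")
        fh.write(f"cellsize {cell_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        fmt = "%d" if np.issubdtype(a.dtype, np.integer) else "%.10g"
        np.savetxt(fh, a, fmt=fmt)


def read_ascii_grid(path: str | Path, dtype=None) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Read an ESRI ASCII grid; returns (array, cell_size, NW origin)."""
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = np.atleast_2d(data)
    if data.shape != (nrows, ncols):
        raise ValueError(f"{path}: header says {(nrows, ncols)}, data is {data.shape}")
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    if dtype is not None:
        data = data.astype(dtype)
    return data, cell, origin


# -------------------------------------------------------------- landscapes

_GRIDS = ("category", "subcategory", "region", "municipality", "proxy")
_TABLES = ("lakes", "rivers", "sector_totals", "forest_inputs",
           "coefficients", "ground_truth")


def save_landscape(landscape: SyntheticLandscape, outdir: str | Path) -> None:
    """Persist a landscape bundle as ASCII grids + CSV tables + YAML config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cs = landscape.grid.cell_size
    write_ascii_grid(outdir / "category.asc", landscape.grid.category, cs)
    write_ascii_grid(outdir / "subcategory.asc", landscape.grid.subcategory, cs)
    write_ascii_grid(outdir / "region.asc", landscape.grid.region, cs)
    write_ascii_grid(outdir / "municipality.asc", landscape.municipality, cs)
    write_ascii_grid(outdir / "proxy.asc", landscape.proxy, cs)
    landscape.lakes.to_csv(outdir / "lakes.csv", index=False)
    landscape.rivers.to_csv(outdir / "rivers.csv", index=False)
    landscape.sector_totals.to_csv(outdir / "sector_totals.csv", index=False)
    landscape.forest_inputs.to_csv(outdir / "forest_inputs.csv", index=False)
    landscape.coefficients.table.to_csv(outdir / "coefficients.csv", index=False)
    landscape.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
    pd.DataFrame(sorted(landscape.populations.items()),
                 columns=["region", "population"]).to_csv(
        outdir / "populations.csv", index=False)
    cfg = dataclasses.asdict(landscape.config)
    cfg["shape"] = list(landscape.config.shape)
    cfg["lake_area_range_km2"] = list(landscape.config.lake_area_range_km2)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def load_landscape(indir: str | Path) -> SyntheticLandscape:
    """Load a landscape bundle; rejects geometry mismatches between layers."""
    indir = Path(indir)
    for name in ("config.yaml", "coefficients.csv", "category.asc"):
        if not (indir / name).exists():
            raise FileNotFoundError(f"missing required input file: {indir / name}")
    with open(indir / "config.yaml") as fh:
        cfg = yaml.safe_load(fh)
    cfg["shape"] = tuple(cfg["shape"])
    cfg["lake_area_range_km2"] = tuple(cfg["lake_area_range_km2"])
    config = SyntheticConfig(**cfg)

    grids = {}
    geom = None
    for name in _GRIDS:
        arr, cell, origin = read_ascii_grid(indir / f"{name}.asc")
        if geom is None:
            geom = (arr.shape, cell, origin)
        elif (arr.shape, cell, origin) != geom:
            raise ValueError(
                f"{name}.asc geometry {(arr.shape, cell, origin)} does not match "
                f"the bundle geometry {geom}")
        grids[name] = arr
    grid = LandscapeGrid(
        category=grids["category"].astype(np.int16),
        subcategory=grids["subcategory"].astype(np.int16),
        region=grids["region"].astype(np.int16),
        cell_size=geom[1])

    tables = {name: pd.read_csv(indir / f"{name}.csv") for name in _TABLES}
    pops = pd.read_csv(indir / "populations.csv")
    return SyntheticLandscape(
        config=config, grid=grid,
        municipality=grids["municipality"].astype(np.int32),
        proxy=grids["proxy"],
        lakes=tables["lakes"], rivers=tables["rivers"],
        sector_totals=tables["sector_totals"],
        forest_inputs=tables["forest_inputs"],
        coefficients=CoefficientTable(tables["coefficients"]),
        populations=dict(zip(pops["region"].astype(int), pops["population"].astype(int))),
        ground_truth=tables["ground_truth"])


# ---------------------------------------------------------------- reports

def _provenance(config: RunConfig | None) -> str:
    chash = config.config_hash() if config else "none"
    seed = config.seed if config else "none"
    return f"# landghg {__version__} config={chash} seed={seed}\n"


def write_reports(outdir: str | Path, tables: dict[str, pd.DataFrame],
                  config: RunConfig | None = None,
                  scalars: dict | None = None) -> list[Path]:
    """Write report tables (and optional scalars) as deterministic CSV/JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = _provenance(config)
    written = []
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, float_format="%.6g", lineterminator="\n")
        log.info("wrote %s (%d rows)", path, len(df))
        written.append(path)
    if scalars is not None:
        path = outdir / "scalars.json"
        with open(path, "w") as fh:
            json.dump(scalars, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(path)
    return written
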