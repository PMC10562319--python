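# Methods

## Scope and model

`landghg` is an emission-factor (activity × coefficient) inventory, not a
process model. Everything upstream of the coefficients — forest growth,
soil decomposition, energy-system dispatch — is out of scope and enters as
inputs: per-region harvested carbon and net ecosystem exchange (NEE) for
forest, municipal sector totals for artificial surfaces and agricultural
activities. The package's own contribution is the accounting algebra
(molar-mass and GWP₁₀₀ conversion, quadrature uncertainty combination, net
and intensity definitions), the land-cover classification rules, the
linear flux engines, the proxy-based spatial allocation, and the
regional/national aggregation.

Sign convention: emission to the atmosphere positive, sequestration
negative, everywhere. Canonical internal mass unit is Gg gas yr⁻¹ (Tg and
Mg only at I/O); coefficients are Gg gas km⁻² yr⁻¹, with elemental-basis
rows (C or N) converted at lookup via the molar-mass ratio. Molar masses
default to the integer inventory values (CO₂ 44, CH₄ 16, N₂O 44, C 12,
N 14); GWP₁₀₀ = 1 / 28 / 265 for CO₂ / CH₄ / N₂O.

## Key parameters and defaults

| Parameter | Default | Unit | Why |
|---|---|---|---|
| accounting cell size | 250 | m | resolution of the gridded inventory; cell area 0.0625 km² |
| lake size classes | 0.01–0.1, 0.1–1, 1–10, 10–100, ≥100 | km² | half-open `[lo, hi)` intervals; the class list prints overlapping endpoints, and half-open is the only self-consistent reading (100 km² → class 5) |
| minimum lake area | 0.01 | km² | 1 ha accounting threshold; smaller lakes return an "excluded" signal, not an error |
| narrow-river width | 3.5 | m | assumed mean width of rivers mapped as lines (<5 m wide) |
| southern/northern split | regions 1–16 / 17–19 | — | zonal cropland coefficients; configurable for synthetic region sets |
| GWP set | AR5, 100-yr | — | fixed default; alternative metrics are a non-goal |
| national population | 5 503 664 | persons | per-capita denominator (31 Dec 2020) |

## Uncertainty

Printed component uncertainties are treated as abstract half-widths of
unspecified coverage; only the combination algebra is asserted. Components
combine as the root sum of squares, which reproduces the published totals
(√(1.97²+3.54²+4.81²+1.92²+1.84²)=6.83; √(6.83²+13.70²)=15.31 ≈ the
printed 15.30). Where a published net uncertainty is Monte-Carlo-derived
rather than quadrature (forest net ±10.30, wetland net ±4.40), the rollup
accepts an override half-width carried through unchanged. Areas are treated
as exact — only coefficient uncertainty propagates; this matches the source
accounting and can be revisited by supplying area sds in a sensitivity
study.

## Classification rules

* **Cropland**: organic soils are the soil-map units Gleyic Podzol, Umbric
  Gleysol and Fibric/Terric Histosol; organic × (annual|perennial) and a
  single mineral class for everything else. Unknown units are rejected in
  strict mode, defaulted to mineral with a warning in lenient mode.
* **Mires**: a data-table lookup from (forest productivity, site fertility,
  site main class) onto four classes — productive forested mires, sedge
  fens, other open/sparsely treed fens, ombrotrophic bogs. The shipped
  mapping (`mire_classes_synthetic.csv`) is a synthetic stand-in
  constructed by this package with the ecologically expected structure
  (productive treed sites → class 1, rich open sites → fens, poor sites →
  bogs); swap in a transcribed table for production use. Attribute
  combinations absent from the table are counted and reported, never
  silently dropped.
* **Mire CO₂ coefficient**: derived from a long-term carbon balance under
  the convention CO₂-C = −(accumulation + CH₄-C + leaching), i.e. net
  ecosystem CO₂ uptake supplies the carbon that accumulates in peat or
  leaves by other routes. The closure identity
  accumulation = −CO₂C − CH₄C − leachC is tested symbolically.
* **Macrophytes**: emergent-vegetation CH₄ substitutes for the open-water
  diffusion+ebullition flux on the covered fraction (default); an additive
  mode is available since the source description does not fix the choice.

## Resampling

Fine binary masks (16 m soil/forest layers) are brought to the 250 m grid
by exact area-weighted overlap, computed separably as 1-D interval-overlap
matrices (250 is not a multiple of 16, so nearest-neighbour or block means
would not conserve area). Conservation is verified against a brute-force
shapely polygon-intersection oracle on small grids.

## Spatial allocation

Municipal sector totals are spread over each municipality's grid cells with
weights proportional to a non-negative proxy; an all-zero proxy falls back
to a uniform spread, an empty municipality is an error, and biogenic-CO₂
rows allocate zero. Allocation conserves each municipal total to
representation precision. In the pipeline, allocation is restricted to the
municipality's cells of the source's land-cover category, falling back to
the whole municipality when it has none.

## Synthetic landscapes

The generator emulates the statistical structure of the real inputs:
contiguous Voronoi regions, category fields from a smoothed Gaussian noise
field thresholded by rank to hit the published category shares (artificial
3 %, arable 7 %, forest 69 %, waterbody 11 %, wetland 10 %), subcategories
drawn from mixture weights matching the published subcategory shares,
log-uniform lake areas over [0.005, 300] km² so all five size classes and
the 1 ha exclusion are exercised, zone-dependent mire-class mixtures (fens
dominate the north), and a "true" coefficient table at the magnitudes
implied by the published fluxes. All randomness flows from a single seeded
generator; runs are byte-reproducible.

What it does **not** emulate: realistic geography, spatial autocorrelation
beyond smoothing (no engine depends on it), hydrology-conditioned peat
placement, or climate-driven coefficient variation. Passing the end-to-end
oracle test therefore demonstrates accounting correctness — that the
pipeline is the exact linear map defined by the coefficients — not the
realism of any coefficient value.

Calibration to a target area table is a per-subcategory multiplicative
scale applied in accounting (grids untouched, registries rescaled
consistently, lake size-class labels kept fixed); fluxes scale linearly
with it.

## Numerical choices and problem sizes

Default test landscapes are 60×60 cells with 4 regions (the acceptance
script uses the same size), which exercises every engine and keeps the
whole suite in seconds; generator behaviour is size-independent by
construction (linearity). Oracle-equality assertions use a relative
tolerance of 1e-9 to absorb summation-order differences; identity checks on
published tables use the tables' printing precision (±0.01 Tg on fluxes,
±0.01 on intensities, ±0.1 on per-capita).

## Known limitations

* The published area table is internally inconsistent at the ±0.05 % level
  (arable subcategories sum to 22 421 km² against a printed total of
  22 537; the printed grand total matches the former); the package carries
  printed totals as data and recomputes leaf sums, documenting both.
* Two intensity denominators exist at national level — the accounted
  land-cover area (306 954 km²) and the total region area (336 887 km²) —
  giving 0.18 vs 0.16 Gg CO₂eq km⁻² yr⁻¹; both are computed and labelled.
* Per-region populations are not shipped; regional per-capita values are
  validated through the implied-population identity, and only the national
  per-capita is recomputed directly.
* Raster and vector I/O use plain-text formats (ESRI ASCII grids, CSV
  registries) with a shared-geometry check standing in for CRS handling;
  there is no coordinate reprojection.
* Wood-product carbon storage is intentionally not modelled: all harvested
  carbon counts as an immediate emission.
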