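# landghg

Spatially explicit greenhouse-gas accounting for boreal landscapes.

Regional and municipal climate planning needs to know where emissions and
carbon sinks sit in the landscape, not just the national totals. `landghg`
implements a land-cover based GHG inventory for that purpose: the landscape
is classified on a 250 m accounting grid into five categories — artificial
surfaces, arable land, forest, waterbodies and wetlands — and their
subcategories (lake size classes, organic/mineral cropland soils,
drained/undrained peat, four undrained-mire classes). Empirical area-based
emission coefficients turn areas into CH₄, CO₂ and N₂O fluxes, sector
totals from external emission models are gridded by spatial proxies, and
everything is rolled up to regional and national net emissions with
combined uncertainties.

The package was built around the published national accounting for mainland
Finland (18 regions, reference period 2017–2025), whose summary tables ship
with the package and serve as the desk-scale verification surface.

## The accounting model

For a subcategory *i* with area *Aᵢ* (km²) and an empirical coefficient
*cᵢ,g* for gas *g* (Gg gas km⁻² yr⁻¹):

```
F_i,g   = A_i · c_i,g                       (mass flux, Gg gas yr⁻¹)
σ_i,g   = A_i · σ(c_i,g)                    (areas treated as exact)
E_i,g   = GWP₁₀₀(g) · F_i,g                 (CO₂-equivalents; 1 / 28 / 265)
```

Fluxes stated as elemental carbon or nitrogen are converted by molar-mass
ratio (C→CO₂ ×44/12, C→CH₄ ×16/12, N→N₂O ×44/28). Harvested forest carbon
is counted as an immediate CO₂ emission (no wood-product storage); forest
and mire ecosystem CO₂ exchange (NEE) enters as negative sequestration
fluxes. Net emission is emission plus (negative) sink; uncertainty
half-widths combine in quadrature, √Σσᵢ², with externally derived
(Monte-Carlo) net uncertainties carried through as overrides. Emission
intensity is 1000·net(Tg)/area(km²) in Gg CO₂eq km⁻² yr⁻¹, per-capita net
is net(Tg)·10⁶/population in Mg CO₂eq yr⁻¹.

Sector totals (energy, industry, traffic, waste, agriculture) are inputs
from external emission models, allocated onto grid cells proportionally to
a non-negative proxy layer within each municipality; allocation conserves
every municipal total exactly, and biogenic-CO₂ rows are excluded to avoid
double counting.

## Worked example

Reproduce the national tables from the packaged transcriptions:

```
$ landghg reproduce-published --out out/published
total emission 147.15 (± 6.83) TgCO2eq/yr
net emission   53.96 (± 15.31) TgCO2eq/yr
per capita     9.8 MgCO2eq/yr
```

Total emissions to the atmosphere are 147.15 Tg CO₂eq yr⁻¹ (sum of the five
category totals; quadrature of their uncertainties gives ± 6.83);
sequestration of 93.19 Tg (forest −89.28, undrained mires −3.91) offsets
63 % of that, leaving a net of ~53.9 Tg, or 9.8 Mg CO₂eq per person for the
5 503 664 inhabitants. The written reports (`table2.csv`, `table3.csv`,
`rollup.csv`, `ledger.csv`) contain the per-source rows, regional summaries
and the source→atmosphere→sink flux ledger.

The full gridded pipeline runs on synthetic landscapes with known ground
truth:

```
$ landghg make-synthetic --seed 3 --size 60 --regions 4 --out out/ls
$ landghg run-pipeline --inputs out/ls --out out/run
national net emission 3.298 TgCO2eq/yr
```

The generated bundle stores the generator's direct-multiplication ground
truth; the pipeline reproduces it to machine precision (this is the core
end-to-end test).

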