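# fpm — multi-model land and water footprint accounting

`fpm` computes **consumption-based land footprints (LF)** and **green/blue
water footprints (WF)** of agricultural products: how much cropland, grazing
land and consumptive water use a population appropriates along global supply
chains, attributed to the countries where production actually happened.  It
is written for industrial-ecology and food-system researchers who want to
compare the main accounting model families on the same data — and to test
accounting code against worlds whose true attribution is known.

Two engines share one data model:

* **Physical trade tracing (PHYS-style).**  Bilateral trade flows of derived
  products are converted to primary-crop equivalents through a commodity
  tree (extraction rates, with mass or value allocation of by-products such
  as oil and cake), re-exports are resolved by an origin-tracing linear
  system, feed and grazing footprints are embedded into livestock products,
  and origin-resolved tonnes are turned into hectares and cubic metres with
  the *producing* country's yields and water coefficients.
* **Supply–use / Leontief footprinting (MRIO-style).**  Multi-regional
  supply, use, final-demand and extension tables are linearized into a
  technical-coefficient system; final demand pulls total output through the
  Leontief inverse, with mass/value allocation for multi-output industries
  and *min*/*max* food-classification scenarios for what counts as food.

A **grazing module** implements harmonized grazing accounting: country
grazing-land productivity from a pasture × NPP grid overlay (at most 75% of
aboveground NPP usable), grass intake translated into a hypothetical grazed
area (capped at 80% of a country's land area where productivity is very
low), grazing intensity, and grazing green water from evapotranspiration
over the grazed area.

Because the real global databases are large and partly proprietary, the
package ships a **synthetic world generator**: small, mass-balanced trade
worlds with re-export chains, processing chains and feed-mediated livestock
supply chains, emitted together with their exact generative ground truth
(shipment paths, origin shares, footprints).  Every accounting stage is
tested against that ground truth and against independent oracles.

## The core computations

For one commodity with production vector $P$ and bilateral flow matrix $T$
(origin × destination, tonnes), each country's supply pool is
$D_i = P_i + \sum_j T_{ji}$ and the export-share matrix is
$B_{ji} = T_{ji}/D_j$.  Under proportional mixing the embodied-production
matrix is

$$F = \hat{P}\,(I - B)^{-1},$$

whose column $i$ splits $D_i$ by country of primary production; consumption
$C_i = D_i - \sum_j T_{ij}$ inherits its pool's composition.  Footprints
follow as $\mathrm{LF} = t/y_o$ (yield of origin $o$) and
$\mathrm{WF} = t \cdot w_o$ (per-tonne green/blue coefficients of origin).

The MRIO engine computes $x = (I - A)^{-1} y$ for technical coefficients
$A$ and final demand $y$, and applies extension intensities $e$ (ha or m³
per unit output) node-wise, grouping by producing region for origins.
Multi-output processes allocate burdens by output shares — mass
($s_o = r_o / \sum r$) or value ($s_o = r_o p_o / \sum r p$).

Grazing: $\mathrm{LF} = \min(\text{grass intake}/p_c,\;0.8 \cdot
\text{land area})$ with $p_c$ the pasture-area-weighted usable ANPP, and
grazing green WF $=$ grazed area × ET rate.

## Worked example

```bash
fpm generate --config config.yaml --out out   # synthetic world + ground truth
fpm trace    --config config.yaml --out out   # physical tracing engine
fpm mrio     --config config.yaml --out out   # supply-use/Leontief engine
fpm report   --config config.yaml --out out   # comparison tables
```

with a config like

```yaml
run:   {scenario_id: demo, allocation_mode: mass, food_scenario: min}
world: {n_countries: 8, n_crops: 5, n_livestock: 2, n_processed: 2,
        trade_density: 0.35, reexport_depth: 2, seed: 42}
paths: {dataset: out/dataset}
```

prints, for the tracing engine,

```
indicator                   LF_crop_ha  LF_grazing_ha    WF_blue_m3   WF_green_m3
model_variant food_class
PHYS-mass     food        1.609444e+06   19197.520826  1.790004e+08  4.002587e+09
```

and the cross-model comparison ends with identical `all` totals for both
engines (spread 0 to ~1e-8):

```
    indicator food_class  MRIO-mass-min    PHYS-mass          min          max       spread
   LF_crop_ha        all   1.609444e+06 1.609444e+06 1.609444e+06 1.609444e+06 0.000000e+00
   WF_green_m3       all   4.002587e+09 4.002587e+09 4.002587e+09 4.002587e+09 0.000000e+00
```

Read: consumers in this 8-country world appropriate 1.61 Mha of cropland,
19.2 kha of grazing land, 4.0 km³ of green and 0.18 km³ of blue water per
year, attributed identically by both model families on a world that obeys
their shared proportional-mixing assumption.  The per-engine *food* rows
differ slightly because the tracing engine reports processed by-products
under their primary crop (inheriting its food class) while the MRIO keeps
them as own products — the product-resolution effect that drives
classification differences between model families on real data too.

The library surface mirrors the pipeline: `generate_world`,
`build_share_system` / `trace_origins` / `attach_intensities`,
`to_primary_equivalents` / `embed_feed`, `compute_grazing_accounts`,
`sut_to_coefficients` / `leontief_footprint` / `classify_food`,
`phys_footprint` / `mrio_footprint`, and `decompose` / `compare_models` /
`per_capita_area` / `per_capita_water`.  See `docs/methods.md` for the
model assumptions and numerical choices.

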