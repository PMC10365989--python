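# Methods

This note documents the accounting models implemented in `fpm`, their
assumptions, the parameters that matter, what the synthetic worlds do and do
not emulate, and the numerical choices.

## 1. Physical trade tracing

**Model.** For each commodity, country supply pools mix domestic production
and imports; every tonne leaving a pool (export or consumption) carries the
pool's origin composition (*proportional mixing*).  With production vector
$P$, flows $T$, supply $D_i = P_i + \sum_j T_{ji}$ and export shares
$B_{ji} = T_{ji}/D_j$, embodied production is $F = \hat P (I-B)^{-1}$ and
the origin share of producer $m$ in consumer $i$ is $F_{mi}/D_i$.  The
linear system resolves re-export chains of any depth, including cycles
(spectral radius of $B$ is below 1 whenever any production is positive
after reconciliation).

**Solvers.** The default is a dense direct solve; a fixed-point geometric
series $\hat P \sum_k B^k$ (truncated at `solve_tolerance`) is exposed as
both fallback and independent test oracle.  The direct solve is used up to
2,000 countries; beyond that the iterative path should be preferred.

**Inconsistent data.** When a country's reported exports exceed its supply,
its export row is scaled proportionally so its row sum of $B$ equals
$1 - 10^{-9}$; scaling reduces downstream imports, so the adjustment
iterates to a fixed point and every step is logged.  Exports from a country
with zero supply are an error.  Negative apparent consumption is clipped at
zero with a logged residual.

**Primary equivalents.** A derived product's flows expand to parent tonnes
as (mass / extraction rate) × allocation share of that output, composed
along the commodity-tree path to the primary.  Allocation shares are mass
($r_o/\sum r$) or value ($r_o p_o / \sum r p$) per multi-output process;
single-output processes take share 1, so path order is unambiguous.  The
complete output bundle of one tonne of parent always maps back to one
tonne, so conversion conserves primary mass.  In the end-to-end tracing
pipeline the *production* vectors of derived commodities are not folded
into primary production (the primary harvest is already on the books; only
the derived *flows* are merged), which keeps the merged system balanced.
Commodities with no tree path are either an error or excluded with a
warning (`untracked_commodities`).

**Feed and livestock.** Reported feed use is subtracted from a country's
apparent consumption of the feed crop, proportionally across origins, and
accumulated into a per-country feed pool alongside the grazing footprints.
The pool is attributed to livestock products $p$ by weight
$w_p Q_{cp} / \sum_q w_q Q_{cq}$ (global or country-specific weights;
uniform when no table is given; weights are a user input because no
canonical global set is published).  Livestock products are then traced
through their own trade matrices, carrying their producing country's
per-tonne feed intensity.  Live-animal trade is outside the tracing path.

**Intensities.** Land uses the origin country's yield (ha = t / (t/ha));
water uses the origin's green and blue per-tonne coefficients, carried as
separate indicators throughout.  A total WF is never stored; it is always
green + blue.

## 2. Supply–use / Leontief engine

**Construction.** The economy is linearized into *producer* nodes (one per
region–industry–output; multi-output industries are split into virtual
per-commodity producers whose inputs and extensions carry the industry's
mass or value output share — the same allocation rule as the commodity
tree) and *pool* nodes (one per region–commodity, fed by domestic producers
and by exporters' pools in proportion to bilateral trade).  All users of a
commodity in a region draw on its pool, so imports of re-exporters chain
through their own pools and origins resolve through the Leontief inverse
exactly as in physical tracing.  Because the declared use-table schema
carries no origin column, cross-regional sourcing is derived inside the
engine from the trade tensor via supply-proportional import shares — the
standard construction of a multi-regional system from national tables plus
bilateral trade.  The engine is unit-agnostic: physical or monetary units
are a property of the input tables, not of the algebra.

**Computation.** $x = (I-A)^{-1}y$ per final-demand cell, solved directly
(never by explicit inversion beyond a documented cap of 5,000 nodes; the
power series is the oracle).  Spectral radius ≥ 1 raises a
non-productive-economy error; an industry with inputs but no output is a
structure error.  Footprints are extension intensities applied node-wise to
the pulled output, grouped by producing-node region for origins.

**Food classification.** Commodities carry classes `food_certain`,
`food_possible`, `nonfood`.  The *min* scenario counts only certain food;
*max* adds possible food.  Food + non-food equals the unclassified total in
both scenarios by construction; which commodities are "possible food" is a
user-editable input.

## 3. Grazing accounting

Country grazing-land productivity is the pasture-area-weighted mean of
usable ANPP over the country's grid cells, with `npp_usable_fraction`
(default **0.75**) of aboveground NPP assumed consumable by livestock.  The
paper-style average is specified only as a per-country mean; the
pasture-area weighting is this package's choice because weighting by the
resource base is the physically meaningful mean.  The grazing land
footprint is a *hypothetical* area: grass intake divided by productivity,
capped at `land_cap_fraction` (default **0.80**) of the country's land area
for very low productivity; the cap is an absorbing upper bound and is
flagged.  "Available land area" for the cap is the country's total cell
area (not pasture only) — an explicit assumption, logged.  Grazable
biomass is pasture area × productivity and grazing intensity is intake as
a percentage of it; intensity may exceed 100% (flagged), and whether excess
intake should be reallocated is out of scope — it is only flagged.  Grazing
green water is the grazed area × the country ET rate (m³/ha), with no blue
component; by default the *capped* area is used so land and water stay
harmonized, with the uncapped alternative behind `grazing_wf_uses_cap`.

Note the footprint depends only on the intake/productivity ratio: the same
footprint arises from extensive grazing of a large area or intensive
grazing of a small one.  The illustrative two-case example in the test
suite exercises exactly this; in the intensive case (100% of a 25 km²
pasture) the low-productivity cap is not part of the illustration and is
left inert.

## 4. Synthetic worlds

The generator emulates the structure of global agricultural statistics at
desk scale: sparse bilateral trade with re-export chains, heterogeneous
yields and water coefficients, multi-output processing, and feed-mediated
livestock chains, with every table assembled from one set of generative
flows so that mass balance holds exactly and the supply–use system equals
the trade system by construction.

Key structural choices:

* Countries are assigned to layers `0..reexport_depth+1`; trade runs only
  to strictly higher layers, so per-commodity flows are acyclic and chain
  length is bounded.  An optional flag adds one two-country cycle to
  exercise the non-nilpotent solve path (validated against the
  geometric-series oracle rather than path enumeration).
* Derived products (processed goods, livestock products) ship one hop to
  top-layer *sink* countries only, sinks export nothing and raise no
  livestock.  This removes the configurations in which the two engines'
  mixing assumptions genuinely diverge (a country re-exporting after
  importing a derived product), so the worlds satisfy the shared
  proportional-mixing assumption exactly and cross-engine totals agree to
  numerical precision.
* Per-product grass requirements are proportional to feed requirements
  (one global ratio), so attributing the pooled feed footprint by feed
  weights is exact.
* Documented parameter ranges (log-uniform unless stated): crop production
  1e3–1e6 t, yields 0.5–10 t/ha, green water 200–4000 m³/t, blue water
  5–500 m³/t, land areas 1e3–1e5 km², cell ANPP 63–630 t/km², ET 1000–6000
  m³/ha, prices 200–2000 per t (by-products 50–630), per-hop export
  fractions 0.1–0.6.  All draws come from one seeded generator; identical
  parameters and seed give byte-identical datasets.

Ground truth (shipment paths, origin shares, footprints) is computed by
iterative flow propagation and explicit path enumeration — never by the
engines' direct solves — so recovery tests compare two independent routes.

**What passing these tests shows — and does not.**  The worlds certify the
accounting algebra: conservation, exact origin attribution under
proportional mixing, allocation and classification identities, engine
equivalence.  They are *not* calibrated to real-world magnitudes, contain
no statistical discrepancies (except via the perturbation operator, which
applies multiplicative lognormal noise for robustness testing), no stock
changes, no intra-annual dynamics, and no processing/drinking water.  Real
data violate proportional mixing to an unknown degree; results on real
databases inherit that assumption.

## 5. Reporting conventions

Stored values are full precision in base units (ha, m³); Mha and km³
appear only in reporting.  Per-capita conversions are
$\text{ha/person} = 10^6 \cdot \text{Mha}/\text{pop}$ and
$\text{l/person/day} = 10^{12} \cdot \text{km}^3/(\text{pop} \cdot d)$ with
$d$ = 365 by default even for leap reference years, because the printed
conversions in the literature this package mirrors are consistent with
365.  Display rounding is decimal half-up, applied only at display.
Product groups and country→continent maps are user tables; decompositions
conserve the grand total along every axis (the water-colour axis restricts
to water indicators by definition).

## 6. Test problem sizes

The default test worlds use 6–10 countries, 4–5 crops, up to 2 processed
and 2 livestock commodities and re-export depth 2; the tracing-oracle
battery runs 200 random worlds of up to 20 countries.  These sizes keep the
full suite in seconds while exercising every code path; all algebra is
dimension-independent.
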