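# Methods

## Model overview

`seatea` evaluates, per ocean grid cell, the full cost chain of farmed
macroalgae from seeded line to climate benefit. The chain is deliberately
linear-algebraic: every pathway quantity is a ratio of annualized dollars
(or tCO₂) per km² to annual harvest (tDW km⁻² yr⁻¹), so results scale
exactly with yield and parameter values, and a single-cell evaluation of
the composed chain can be checked against a one-line formula (the test
suite does this for thousands of random draws).

Two pathways are modelled per simulation:

- **Sinking (CDR).** The harvest (wet weight = 10 × dry weight) is barged
  `d_sink` km to a sinking site, the barge returns via the farm to port
  with replaced equipment. Gross removal per km² is
  `k_atm · k_fseq · 0.30 · (44/12) · s_dw`: 30% of dry mass is carbon,
  44/12 converts C to CO₂, `k_fseq` is the site's 100-yr sequestration
  fraction and `k_atm` discounts for air–sea disequilibrium and
  phytoplankton nutrient competition. Transport and production emissions
  are netted off; cells whose net removal is not positive are excluded
  from every aggregate rather than carried as negative removals.
- **Products (avoided emissions).** The harvest is barged straight to
  port, converted to food, feed or fuel, and sold at a globally uniform
  market value (a scalar by design — regional price formation is out of
  scope). The climate benefit is the GWP₁₀₀ CO₂-eq embodied in the
  conventional product displaced, net of chain emissions; CO₂ and CO₂-eq
  are tracked in one accounting unit because the substitution factors
  already fold in non-CO₂ gases.

Equipment transport to the farm is a one-way leg (the return is carried by
the sinking/product legs); the sinking route explicitly pays the
farm→sink→farm→port legs for equipment. Maintenance emissions combine
round trips from port (`2·d_port` per trip, `n_mnt/a_mnt` trips per km²)
plus a fixed patrol distance `d_mnt` per km² of farm; the patrol term is
implemented exactly as stated, i.e. not scaled by trip count.

## Parameter ranges

All scalar parameters are uniform random variables. Ranges are built from
literature values by fixed rules (`params.build_range`):

- ≥2 literature values → [min, max] treated as the 5th/95th percentiles;
- a single value → value ∓/± 50%;
- floors deliberately extended: capital cost down to $10,000 km⁻² yr⁻¹
  (hypothetical autonomous farms), transport and maintenance emissions
  down to 0 (zero-emission vessels);
- bounds rounded to parameter-specific increments (e.g. capital/operating/
  harvest costs to $10,000, line cost to $0.05 m⁻¹, transport emissions to
  5×10⁻⁶ tCO₂ t⁻¹ km⁻¹, substitution factors to 0.1); conversion costs
  round outward (low down, high up).

Rounding is half-away-from-zero so that, e.g., a $0.225 t⁻¹ km⁻¹ transport
cost becomes the published $0.10–$0.35 range. Three rows (capital, seeded
line, harvest cost) cannot be reconstructed from the handful of literature
values carried in the bundled table alone; their final bounds are pinned
to the published model ranges via an explicit `override`, while the
unrounded literature span is retained for the mean-parameter set.

Parameters never published in the sources available here — insurance,
license, labour and other operating costs, equipment mass (`m_eq`),
maintenance trip geometry (`n_mnt`, `a_mnt`, `d_mnt`), conversion costs
and emissions — ship as documented placeholders flagged
`placeholder: true` in `data/parameter_ranges.yaml`, chosen at plausible
magnitudes (e.g. `m_eq` 50–150 t km⁻² yr⁻¹, labour $25,000–75,000 km⁻²
yr⁻¹). Replace them from primary data for any real-world use; the file is
the single source of truth and is user-swappable per run.

Yield uncertainty enters as a discrete draw of one of five percentile maps
(5/25/50/75/95). A standard normal deviate is mapped to the five labels by
probability bins whose edges sit at the midpoint probabilities (0.15,
0.375, 0.625, 0.85), giving P = (0.15, 0.225, 0.25, 0.225, 0.15) — the
median map most likely, the tails least. The mapping itself is a design
choice (only "selected from a normal distribution" is specified upstream);
the bin edges are configurable constants.

The **mean parameter set** used for sink-route optimization takes the
midpoint of each parameter's *unrounded* literature span — except
transport and maintenance emissions, whose floors are first extended to
zero and then averaged, and the atmospheric removal fraction, whose mean
is set to 0.7 (midpoint of its deliberately extended 0.4–1.0 model range;
the unrounded-literature rule is ambiguous for ranges that were extended
by construction).

## Sink-route optimization

For each candidate sequestration fraction q ∈ {0.01, …, 1.00}: the source
set is every ocean cell whose local fraction, snapped *down* to the 0.01
grid, reaches q; a multi-source shortest-path transform gives each cell
its distance to that set; and the full sinking chain is evaluated with
`d_sink` = that distance and `k_fseq` = q. Each cell keeps the q that
minimizes $ per tCO₂ removed. Snapping down guarantees sinking in place is
always a candidate, so the optimized cost is never worse than the local
option (asserted in tests). Ties break toward smaller distance, then
larger q. The transform runs once per q (100 multi-source runs over a
shared cached graph), not per cell. q values with empty source sets are
skipped; cells for which no q yields positive net removal fall back to
sinking in place and are flagged.

The ocean graph is 8-connected with great-circle (haversine) edge weights
between cell centres; longitude wraps when the grid spans 360°; land is
impassable. Connectivity and metric are design choices validated against
an independent Dijkstra implementation on dozens of random grids. Ocean
cells unreachable from any port are masked (NaN distance) and drop out of
all pathways.

## Monte Carlo

Default desk ensemble: n = 500 per nutrient scenario on the 1° synthetic
grid (the full-scale analysis uses n = 5,000 at 1/12°; both are config
knobs — `RunConfig.n_sims`). One root seed spawns independent child
streams per simulation index, so results are reproducible and independent
of execution order. The sink assignment is computed once with mean
parameters and shared across simulations; per-draw re-optimization would
be a different (much costlier) design and is deliberately not done.

Per-cell cost distributions are summarized by empirical inverse-CDF
(nearest-rank) quantiles, computed independently per cell; a simulation in
which a cell's pathway is invalid contributes nothing to that cell's
distribution (not an infinity). Per-simulation scalar summaries record the
average cost within the cheapest 1% and 2% of ocean area: area-weighted
for $/tDW production cost, benefit-weighted (total dollars over total tons
of benefit) for $-per-ton-of-climate-benefit, matching the "average cost
per tCO₂" semantics of cumulative supply curves.

## Aggregation

`cheapest_fraction` sorts valid cells by cost (stable tie-break on cell
index) and accumulates area until the target fraction of *total ocean
area* is reached, including the crossing cell. Supply curves integrate
benefit density (tCO₂ km⁻² yr⁻¹) over that ordering and report Gt yr⁻¹;
marginal cost is non-decreasing by construction. Growth-rate arithmetic is
compound: rate = (target/current)^(1/horizon) − 1, with today's farmed
area at 2,700 km² and horizons of 30 years (by 2050) or 10 years (by
2030) — conventions that reproduce the published 12%/18%/42%/14% figures
at integer rounding.

## Synthetic world

The generator emulates the *structure* of the real inputs, not their
geography:

- equal-angle lat/lon grid (default 1°, vs 1/12° at full scale) with land
  as contiguous smoothed-noise blobs at a configurable fraction;
- smooth random fields for depth (50–6,000 m), significant wave height
  (0–6 m) and sequestration fraction (0.05–0.95); ports on random coastal
  cells; distance-to-port by the same over-water transform used for
  sinking; shipping-lane and MPA masks as smoothed-noise exceedance sets
  (the thresholds that define them at full scale — >2.25×10⁸ AIS signals,
  MPAs >20 km² — are documented constants of the mask generator);
- four seaweed types with Gaussian |latitude| affinity envelopes. Peak
  median yields anchor to reported magnitudes (6,000 tDW km⁻² yr⁻¹
  tropical red, 2,000 temperate brown); the best ocean cell of each type
  is normalized to its peak so the calibration is seed-robust. Line
  spacings follow farming practice: 0.25 m off-bottom lines for tropical
  reds, 0.5 m for tropical browns and temperate reds (net culture), 1.5 m
  kelp longlines — the spacing choice is what makes seeded line the
  dominant average cost share, as observed at full scale.
- percentile maps scale the median by ordered multipliers
  (0.5, 0.8, 1.0, 1.2, 1.5) with a smooth ±10% perturbation, sorted
  cell-wise so monotonicity holds exactly. The inter-percentile spread of
  yield uncertainty is not constrained upstream; it is a free,
  configurable parameter here. The limited-nutrient scenario multiplies
  ambient yields by one shared smooth factor in (0.4, 1.0].

What passing tests on this world do **not** show: absolute dollar figures
comparable to the full-scale analysis (those depend on real yield maps,
bathymetry and port networks), realistic coastline/port geometry, seasonal
or interannual yield variability, or spatial correlation between yield and
wave/depth fields (independent fields here). Qualitative structure —
ordering of pathway costs, dominance of yield and seeded-line cost,
monotonicities — is what transfers.

## Numerical choices

- Validity masks use a strictly positive threshold (10⁻⁹ tCO₂ tDW⁻¹) on
  net removal/avoided emissions to keep the cost-per-ton division well
  conditioned; upstream, only "negative" cells are excluded.
- Per-km² emission terms are computed per km² and normalized by yield once
  at the end of each chain, preserving the printed structure (the gross
  sequestration term is dimensionally per-ton; it is applied per km² so
  the final ratio is exact).
- Zero-yield cells are masked (NaN), never divided through; NaNs propagate
  to validity masks, not to aggregates.
- Cost fields are stored float32 in ensembles (memory), computed float64.
- NetCDF output is classic (NetCDF-3 via the SciPy engine) with CF-style
  lat/lon dims and masks as int8 variables — plain-text-toolable and
  dependency-light.

## Known limitations

- Placeholder parameter rows (flagged in the YAML) are magnitude guesses,
  not literature values; conclusions sensitive to them should be rerun
  with real data.
- Market value is globally uniform and demand is unbounded: no
  price-equilibrium or displacement-market modelling.
- The sequestration fraction is a static scalar field; no durability or
  re-ventilation dynamics beyond the 100-yr fraction.
- `k_atm` is a scalar stand-in for Earth-system nutrient-competition
  dynamics; a coupled model would resolve it spatially.
- Parameters are sampled independently (no correlation structure), which
  is the stated upstream design but inflates joint-tail scenarios.
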