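# Technoeconomic parameter ranges for the Monte Carlo analysis.
#
# Each entry either lists the published literature values ("literature") from
# which the model range is constructed (multiple values -> [min, max] treated
# as 5th/95th percentiles; a single value -> value -/+ 50%), or states an
# explicit model range ("range"). Bounds are then rounded to the stated
# increment ("rounding"; mode "nearest" by default, "out" rounds the low end
# down and the high end up). "extend_low_to" lowers the floor of a range
# before rounding (used for capital costs and transport/maintenance emissions
# to admit future low-cost / zero-emission technology). "override" pins the
# final model range where the published range cannot be reconstructed from
# the values available here. "mean" / "mean_uses_extended" control the
# fixed parameter set used for the sink-route optimization.
#
# Entries flagged "placeholder: true" are documented assumptions standing in
# for values that were not published in the sources available to this
# package; replace them with measured values when available.

constants:
  wet_dry_ratio: 10.0          # t wet weight per t dry weight
  carbon_fraction: 0.30        # tC per tDW of macroalgal biomass
  ocean_area_total_km2: 3.6e8  # global ocean surface area
  current_farm_area_km2: 2700.0
  depth_threshold_m: 500.0     # capital-cost depth multiplier applies above
  swh_threshold_m: 3.0         # capital-cost wave multiplier applies above

parameters:
  c_capbase:
    units: "USD km^-2 yr^-1"
    description: "Annualized capital cost before depth/wave multipliers"
    literature: [929676.0, 550000.0, 950000.0, 375910.0, 210580.0]
    rounding: 10000.0
    extend_low_to: 10000.0
    override: [10000.0, 1000000.0]
  k_d:
    units: "fraction"
    description: "Capital-cost multiplier for depth > 500 m"
    range: [0.0, 1.0]
  k_w:
    units: "fraction"
    description: "Capital-cost multiplier for significant wave height > 3 m"
    range: [0.0, 1.0]
  c_slbase:
    units: "USD m^-1"
    description: "Seeded line cost per metre (includes hatchery costs)"
    literature: [1.38, 0.13]
    rounding: 0.05
    override: [0.05, 1.45]
  c_ins:
    units: "USD km^-2 yr^-1"
    description: "Annual insurance cost"
    literature: [36000.0]
    rounding: 1000.0
    placeholder: true
  c_lic:
    units: "USD km^-2 yr^-1"
    description: "Annual aquaculture license cost"
    literature: [2000.0]
    rounding: 1000.0
    placeholder: true
  c_lab:
    units: "USD km^-2 yr^-1"
    description: "Annual labour cost excluding harvest labour"
    literature: [50000.0]
    rounding: 1000.0
    placeholder: true
  c_opbase:
    units: "USD km^-2 yr^-1"
    description: "Other operating and maintenance costs"
    literature: [40000.0]
    rounding: 10000.0
    placeholder: true
  c_harvbase:
    units: "USD km^-2 per harvest"
    description: "Cost per harvest (includes harvest labour, excludes transport)"
    literature: [381265.0, 138000.0]
    rounding: 10000.0
    override: [120000.0, 400000.0]
  c_transbase:
    units: "USD t^-1 km^-1"
    description: "Barge transport cost per ton of material per km"
    literature: [0.225]
    rounding: 0.05
  e_transbase:
    units: "tCO2 t^-1 km^-1"
    description: "Barge transport emissions per ton of material per km"
    literature: [0.00003]
    rounding: 0.000005
    extend_low_to: 0.0
    mean_uses_extended: true
  e_mntbase:
    units: "tCO2 km^-1"
    description: "Maintenance vessel emissions per km travelled"
    literature: [0.0023653]
    rounding: 0.0005
    extend_low_to: 0.0
    mean_uses_extended: true
  n_mnt:
    units: "trips km^-2 yr^-1"
    description: "Maintenance trips per km^2 per year"
    literature: [26.0]
    placeholder: true
  a_mnt:
    units: "km^2 per trip"
    description: "Farm area tended per maintenance trip"
    literature: [1.0]
    placeholder: true
  d_mnt:
    units: "km"
    description: "Distance travelled around each km^2 for maintenance"
    literature: [10.0]
    placeholder: true
  m_eq:
    units: "t km^-2 yr^-1"
    description: "Annualized equipment mass transported per km^2"
    literature: [100.0]
    placeholder: true
  k_atm:
    units: "fraction"
    description: "Atmospheric removal fraction (air-sea disequilibrium and nutrient competition)"
    range: [0.4, 1.0]
    mean: 0.7
  v_cprice:
    units: "USD km^-2 yr^-1"
    description: "Carbon price credited to sunk seaweed (baseline: none)"
    range: [0.0, 0.0]

  # --- product-pathway parameters, one block per end use -----------------
  v_mkt_food:
    units: "USD tDW^-1"
    description: "Market value of seaweed sold as food"
    range: [500.0, 800.0]
  v_mkt_feed:
    units: "USD tDW^-1"
    description: "Market value of seaweed sold as animal feed"
    range: [400.0, 500.0]
  v_mkt_fuel:
    units: "USD tDW^-1"
    description: "Market value of seaweed sold as biofuel feedstock"
    range: [400.0, 500.0]
  e_subprod_food:
    units: "tCO2-eq tDW^-1"
    description: "GHG emissions avoided by replacing conventional food"
    range: [1.0, 6.0]
    rounding: 0.1
  e_subprod_feed:
    units: "tCO2-eq tDW^-1"
    description: "GHG emissions avoided by replacing conventional feed"
    range: [1.0, 3.1]
    rounding: 0.1
  e_subprod_fuel:
    units: "tCO2-eq tDW^-1"
    description: "GHG emissions avoided by replacing fossil fuel"
    range: [0.7, 1.0]
    rounding: 0.1
  c_conv_food:
    units: "USD tDW^-1"
    description: "Cost of converting seaweed to food products"
    literature: [150.0]
    rounding: 10.0
    rounding_mode: out
    placeholder: true
  c_conv_feed:
    units: "USD tDW^-1"
    description: "Cost of converting seaweed to animal feed"
    literature: [100.0]
    rounding: 10.0
    rounding_mode: out
    placeholder: true
  c_conv_fuel:
    units: "USD tDW^-1"
    description: "Cost of converting seaweed to biofuel"
    literature: [200.0]
    rounding: 10.0
    rounding_mode: out
    placeholder: true
  e_conv_food:
    units: "tCO2 tDW^-1"
    description: "Emissions from converting seaweed to food products"
    literature: [0.02]
    rounding: 0.01
    placeholder: true
  e_conv_feed:
    units: "tCO2 tDW^-1"
    description: "Emissions from converting seaweed to animal feed"
    literature: [0.02]
    rounding: 0.01
    placeholder: true
  e_conv_fuel:
    units: "tCO2 tDW^-1"
    description: "Emissions from converting seaweed to biofuel"
    literature: [0.1]
    rounding: 0.01
    placeholder: true
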