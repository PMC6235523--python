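# Methods

## Scope and accounting basis

`ncskit` computes annual climate mitigation for a portfolio of 21
land-stewardship pathways in a fixed target year, relative to a
business-as-usual baseline. The unit canon is: extents in Mha, per-area
fluxes in Mg CO2e ha⁻¹ yr⁻¹, totals in Tg CO2e yr⁻¹; Pg appears only in
formatted output at 2 significant figures, and reported percentages are
rounded to the nearest integer, matching the precision conventions of
published NCS assessments.

Non-CO2 gases are converted to CO2e with an explicit, overridable factor
set. The default is AR5 100-year GWP (CH4 28, N2O 265). Tidal-wetland CH4
uses a sustained-flux GWP (CH4 45) by default because reconnecting a
freshened marsh changes a persistent flux rather than emitting a single
pulse; pulse GWPs understate the warming effect of sustained flux changes.
Every report states the factor set used, since the choice is a genuine
degree of freedom in land-sector accounting.

Saturation is carried as per-pathway metadata (years at the stated rate)
and does not decay the annual rates: all estimates are for a year within
each pathway's saturation window. Avoided-emission pathways driven by
CH4/N2O (nutrient, manure, rice, tidal wetlands) do not saturate and carry
an infinite saturation entry.

## Pathway models

**Reforestation.** Raster screening marks a cell eligible when tree cover
< 25%, the land-cover class is one where forest is the native cover
(forest, shrubland by default; never grassland — afforesting native
grassland is excluded on biodiversity grounds), and no exclusion mask
(urban, impervious, major road, Histosol) fires. Cropland and pasture are
retained for food production by default; a bounded `released_cropland_mha`
mimics a set-aside release. Mitigation is area × sequestration rate with an
albedo discount on the conifer-dominated fraction:
`rate_eff = rate · (1 − conifer_frac · albedo_discount)`. The discount
magnitude is not a settled constant; the default is 0 (off) and the factor
used is always reported.

**Fire management.** An expected-value cohort model: each year a fraction
(default 5%) of the treatable area (default 20 Mha) is treated from
currently unprotected land, emitting `rx_emission` (8 Mg CO2e ha⁻¹) once;
treated land cannot burn for 20 years (only directly treated land is
protected); untreated land burns with annual probability p, emitting
80 Mg CO2e ha⁻¹ (combustion plus foregone net ecosystem production). The
annual benefit is avoided expected wildfire emissions minus treatment
emissions, averaged over a 20-year horizon; early years are net-negative
and the average is reported. The default p = 26/840 ≈ 0.031 yr⁻¹ is
back-solved so the default scenario yields 18 Tg CO2e yr⁻¹. A seedable
stochastic mode (Bernoulli ignition on equal-area units, coupled
with/without-program draws) exists for validation; its expectation equals
the deterministic mode.

**Avoided conversion.** Committed-emission accounting, with all emissions
assigned to the conversion year. Forest: clearing rate × the fraction of
clearing that is persistent conversion × per-ha biomass emissions, with the
soil pool excluded (evidence on soil response to forest conversion is
conflicting). Grassland/shrubland: per-ha emissions are 28% of the 1-m
soil-C stock plus root (and shrub aboveground) biomass C, times 44/12. The
default stock (121.75 Mg C ha⁻¹) makes the soil term 125 Mg CO2e ha⁻¹ and
the default root+shrub C (≈8.0 Mg C ha⁻¹) makes that soil term 81% of the
per-ha total — the two internal-consistency anchors for this pathway. Root
biomass can alternatively be predicted from mean annual temperature and
precipitation through a configurable linear regression clamped at zero;
the regression form is a placeholder for a fitted climate model whose
coefficients the caller supplies.

**Cropland nutrient management.** Baseline field (N2O) and upstream
(fertilizer manufacture) emissions grow 4.6% to the BAU year. An N-rate
reduction r cuts upstream emissions proportionally and field emissions by
`1 − (1−r)^k`: marginal fertilizer drives disproportionate N2O, so the
response is superlinear. k ≈ 1.612 is calibrated once by root-finding
(Brent, tol 1e-10) so r = 22% gives a 33% field cut; with baseline
emissions split field:upstream = 7:4, the combined cut is exactly 29%
(the emission-weighted mean), and baselines are scaled so the default
scenario mitigates 52 Tg CO2e yr⁻¹. The 7:4 split is the unique solution
of the one-unknown equation `w·0.33 + (1−w)·0.22 = 0.29`.

**Biochar.** Residue mass × char yield × char C fraction × permanence ×
44/12, with permanence 0.796 (the fraction of char C persisting beyond
100 years) and no N2O/CH4 side terms. Defaults (93 Tg residue, yield 0.5,
C fraction 0.7) are back-solved to a 95 Tg CO2e yr⁻¹ maximum.

**Blue carbon.** Tidal wetlands: marsh extent × freshened fraction (27%)
× avoided CH4 flux, converted under the sustained-flux GWP; the default
flux (≈0.58 Mg CH4 ha⁻¹ yr⁻¹) is back-solved so 1.7 Mha of marsh yields
12 Tg CO2e yr⁻¹. Avoided seagrass loss: extent × 1.5% yr⁻¹ loss × stored C
× 50% atmospheric release × 44/12. Seagrass restoration: historic extent ×
restorable fraction × sediment sequestration rate; the restorable-fraction
interval (29–52%) supplies the CI endpoints and its midpoint the default
mean.

**Improved plantations.** The biologically optimal rotation is the
tabulated age maximizing mean annual increment (stand C / age); the
annualized per-ha gain is the MAI difference between biological and
economic rotations (linear interpolation off tabulated ages for the
economic rotation), floored at 0 and converted by 44/12.

**Scalar pathways.** Natural forest management, urban reforestation, cover
crops, alley cropping, windbreaks, grazing optimization, grassland
restoration, legumes in pastures, rice, manure, and peatland restoration
are extent × rate products with rates supplied by the primary literature
or external models; they dispatch through one audited kernel that attaches
pool splits and co-benefit tags. Anchored values: cover crops 88 Mha at
0.32 Mg C ha⁻¹ yr⁻¹ (= 1.173 Mg CO2e) → 103 Tg; windbreaks on 5% of the
17.6 Mha that would benefit (0.88 Mha) → 5 Tg; warm-temperate peatland
restoration at 8.2 Mg CO2e ha⁻¹ yr⁻¹; grassland restoration on 2.1 Mha of
former set-aside cropland.

## Uncertainty propagation

Reported 95% intervals are fitted per pathway: symmetric → normal with
σ = width/3.92; degenerate → point mass; asymmetric → two-piece normal
hinged at the reported mean with one-sided σ = half-width/1.96. Two
combiners are provided for independent pathways:

- **quadrature** (default): the portfolio mean is the exact sum of means
  and each side's half-widths combine as √Σ hwᵢ² — the standard
  inventory-style propagation for independent sums, and deterministic;
- **Monte Carlo**: per-pathway draws from the fitted families are summed;
  the empirical mean and 2.5/97.5 percentiles are reported; draws for
  nonnegative pathways are truncated at 0; output is bit-reproducible per
  seed.

The headline report uses quadrature. The two-piece convention hinges the
pieces at the reported mean, which is then the distribution's *mode*; its
sampling mean shifts by √(2/π)(σ_hi − σ_lo) per pathway, so a Monte Carlo
portfolio over asymmetric inputs is displaced upward relative to the sum
of reported means and would violate the invariant that the portfolio mean
equal that sum. Quadrature preserves the invariant and reproduces the
asymmetric portfolio interval transparently; the MC combiner is
cross-checked against quadrature on symmetric inputs (agreement within 2%
of the half-width at 10⁵ draws) and kept for sensitivity analysis.
Inter-pathway correlation is not modelled; whether real pathway errors are
correlated is unknown, and a correlation matrix is out of scope.

## Synthetic data: what it does and does not emulate

The generator produces (a) toy landscapes — per-cell land cover from
configurable class probabilities, lognormal 1-m soil C (mean
122 Mg C ha⁻¹, CV 0.3, so the grassland per-ha anchors hold at the mean),
smooth temperature/precipitation gradients plus noise, Beta-distributed
conifer fraction on forest, and class-conditional boolean masks — and
(b) the 21-row parameter table.

The table's *fixture* mode carries the ten headline pathway maxima (307,
267, 107, 103, 95, 82, 52, 38, 18, 12 Tg) and eleven smaller pathways
that are **synthetic**: their individual values are not published at this
granularity, so they are back-solved to satisfy every published aggregate
simultaneously — remainder sum 122 Tg; each ≤ 12 Tg so the headline ten
are the ten largest; manure ≥ 12 Tg (its published low-cost value);
tranche sums 299/914/1095 Tg at USD 10/50/100; avoided-gas pool total
88 Tg. Per-pathway CIs are likewise back-solved: half-widths proportional
to each mean and scaled so portfolio quadrature reproduces the 900–1600 Tg
interval exactly. Pool splits are fixture values chosen so the
mitigation-weighted decomposition rounds to 63/29/7 (which sum to 99 —
the report therefore prints unrounded fractions alongside rounded ones).

Consequently, passing tests demonstrate that the *accounting engine*
reproduces the published arithmetic from its stated inputs; they do not
validate the national spatial analysis (full-resolution land-cover,
soils, forest-inventory, and disturbance processing), which no toy
landscape can stand in for. Grid-based tests exercise masking, counting,
and unit logic at 10²–10⁴-cell scale.

## Numerical choices

- Interval fitting treats |lo_hw − hi_hw| ≤ 1e-9 (relative) as symmetric.
- Tranche and pool-split validation tolerances are 1e-9; estimate/pool
  consistency 1e-6 relative.
- `percent_of_reference` rejects non-positive references; `area_times_rate`
  rejects negative extents but allows negative rates (penalty terms).
- Degenerate fire inputs: horizon and protection ≥ 1 year enforced;
  treatment each year is capped at currently unprotected land.
- Rotation gain is floored at 0; the economic rotation must lie within the
  tabulated curve (error otherwise); ties in MAI resolve to the earliest
  tabulated age via argmax.
- Parameter CSVs are parsed with round-trip float precision so serialized
  tables reproduce totals bit-identically.
- Monte Carlo requires ≥ 1000 draws; percentile CIs are clamped to bracket
  the empirical mean.

## Problem sizes

Default test and demonstration sizes: 100×100-cell landscapes of 100-ha
cells (1 Mha domain; 200×200 for frequency checks), 10⁵ Monte Carlo draws,
200 replicates for CI-coverage simulation, 25 randomized regimes for the
fire-model oracle, and exhaustive cell enumeration on grids ≤ 10⁴ cells.
These sizes make every check fast while keeping binomial/Monte Carlo error
well inside the asserted tolerances.

## Known limitations

- No leakage modelling, no monetary valuation of co-benefits, no
  net-present-value discounting: prices enter only as tranche ceilings.
- Committed-emission accounting is instantaneous; multi-decade emission
  profiles after conversion are not tracked.
- The three-step MAC granularity matches the published price points;
  continuous supply curves would need finer tranche data.
- Co-benefit flags are qualitative metadata passthrough, not scores.
- The root-biomass climate regression is structural: its coefficients must
  come from a fitted external model.
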