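# ncskit

Portfolio accounting for **natural climate solutions (NCS)** — conservation,
restoration, and improved land-management interventions that increase carbon
storage or avoid greenhouse-gas emissions on natural and working lands.
`ncskit` implements 21 pathway-specific mitigation estimators (reforestation
through seagrass restoration), propagates per-pathway 95% confidence
intervals to a portfolio interval, builds marginal-abatement-cost (MAC)
curves at carbon-price ceilings, and emits tabular reports — all runnable
end to end on synthetic landscapes and tabulated parameters, with no
external data downloads.

It is written for analysts who need a tested, reusable engine for
land-sector mitigation arithmetic: every estimator is a pure function with
explicit units, every published-style aggregate is recomputed rather than
hard-coded, and the synthetic-data module generates inputs with the
statistical structure the analysis assumes.

## The model

Every pathway estimate reduces to CO2e accounting on an annual basis:

- **area × rate**: extent (Mha) × per-area flux (Mg CO2e ha⁻¹ yr⁻¹) → Tg CO2e yr⁻¹
  (the unit product is exact: 1 Mha × 1 Mg ha⁻¹ = 1 Tg);
- **CO2-equivalence**: CO2e = CO2 + f_CH4·CH4 + f_N2O·N2O, default AR5
  100-year GWP (f_CH4 = 28, f_N2O = 265); tidal-wetland CH4 uses a
  sustained-flux GWP (f_CH4 = 45) because the intervention changes a
  persistent flux;
- **portfolio CI**: with independent pathways, each side's 95% half-widths
  combine in quadrature, hw = √Σᵢ hwᵢ²; a Monte Carlo combiner over
  interval-fitted families (normal / two-piece normal / lognormal / uniform)
  is available as a cross-check;
- **MAC curve**: per-pathway cumulative tranches at USD 10/50/100 per
  Mg CO2e merge into a portfolio step function; mitigation at price P is the
  cumulative value at the largest ceiling ≤ P.

Bespoke pathway models include raster eligibility screening for
reforestation (tree cover < 25%, native-forest classes, urban/impervious/
road/Histosol exclusions), an expected-value prescribed-fire vs. wildfire
accrual model, committed-emission accounting for avoided forest and
grassland conversion (28% soil-C loss to 1 m; soil pool excluded for
forest), a nonlinear nitrogen-rate emission cascade, biochar permanence
arithmetic, blue-carbon accounting, and rotation extension to the maximum
mean annual increment.

## Worked example

```python
from ncskit import synthetic, report, abatement

table = synthetic.generate_parameter_table()          # 21 pathways
print(report.summary_text(table), end="")
```

prints

```
NCS portfolio summary
=====================
pathways:               21
maximum mitigation:     1.2 Pg CO2e/yr (1203.0 Tg; 95% CI 0.9 to 1.6 Pg)
share of net emissions: 20.8% of 5794.5 Tg CO2e/yr (~21%)
pool decomposition:     biomass 63.3%, soil 29.4%, avoided_ch4_n2o 7.3%
available at USD    10: 299.0 Tg CO2e/yr (24.9% of maximum)
available at USD    50: 914.0 Tg CO2e/yr (76.0% of maximum)
available at USD   100: 1095.0 Tg CO2e/yr (91.0% of maximum)
CI method:              quadrature (seed=0)
CO2e basis:             AR5 GWP100 (CH4 28, N2O 265); tidal wetlands on SGWP (CH4 45)
```

Reading the numbers: the 21 pathways sum to a maximum additional mitigation
of 1.2 Pg CO2e yr⁻¹ (95% CI 0.9–1.6), about 21% of national net emissions
in the 2016 reference year; 299 Tg yr⁻¹ (25% of the maximum) is available
at or below USD 10 per Mg CO2e, and 91% at USD 100; 63% of the potential is
plant-biomass sequestration, 29% soil sequestration, and 7% avoided
CH4/N2O.

The same pipeline is scriptable from the shell:

```bash
ncskit simulate --seed 3 --out demo/        # .asc layers + parameter CSV
ncskit report demo/pathway_params.csv       # headline block
ncskit mac demo/pathway_params.csv --price 50
```

Individual estimators are plain functions:

```python
from ncskit.pathways import fire_management_benefit, FireRegimeParams
fire_management_benefit(FireRegimeParams())   # 18.0 Tg CO2e/yr
```

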