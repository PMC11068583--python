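# peatghg

Greenhouse-gas flux harmonization and long-term carbon-stock simulation
for rewetted and afforested peatlands.

Drained peatlands mineralize their peat and emit CO2 for centuries;
rewetting stops the loss at the price of higher CH4 emissions. Deciding
between restoration and continued afforestation therefore needs two
things this package provides for boreal/temperate bogs and fens:

1. **A harmonized flux compilation.** Published annual net ecosystem
   exchange (NEE, as CO2-C), CH4-C and N2O-N fluxes from rewetted sites
   come in a zoo of units (mg CO2-C m⁻² h⁻¹, t CO2-eq ha⁻¹ yr⁻¹,
   mmol CH4 m⁻² h⁻¹, …). `peatghg` ships a machine-readable encoding of a
   published multi-site compilation with every value and unit string as
   printed, converts any flux to canonical **kg element ha⁻¹ yr⁻¹**
   (negative = uptake), aggregates per site category, and computes
   CO2-equivalent balances

       B = NEE_C·44/12 + g_CH4·CH4_C·16/12 + g_N2O·N2O_N·44/28

   under GWP100 (g_CH4 = 25, g_N2O = 298) and GWP500 (7.6, 153).

2. **A 300-year carbon-stock model.** An annual-step pool model (peat,
   stem, branch, coarse-root, harvest-residue carbon plus timber export)
   driven by piecewise-linear stem-increment and peat-flux schedules with
   fixed allometry (branches 12 % of stem biomass, coarse roots 19 % of
   above-ground biomass; 420 kg m⁻³ wood at 50 % C). Six packaged
   scenarios compare pristine bogs and bog forests with drained managed
   forests and three after-uses of cutover peat extraction sites, all
   starting from the same 686 t C ha⁻¹ peat stock (2 m of peat at
   34.3 kg C m⁻³).

A synthetic-data module generates category-structured flux tables with
known ground truth and deliberately mixed unit dialects, plus perturbed
scenario parameter sets, so the whole pipeline is testable offline.

## Worked example

Category balances from the packaged compilation:

```sh
peatghg balance --gwp 100 --gwp 500 --out balance.json
```

The `rewetted_forest` entry reads (abridged):

```json
{
 "category": "rewetted_forest",
 "gases": {
  "nee": {"n": 4, "mean": -927.5, "mean_rounded": -928},
  "ch4": {"n": 5, "mean": 232.2,  "mean_rounded": 232},
  "n2o": {"n": 6, "mean": 0.323,  "mean_rounded": 0}
 },
 "co2eq": {"100": 4490.6, "500": -970.1}
}
```

The four multi-site review rows of this category average to
−928 kg CO2-C ha⁻¹ yr⁻¹ — rewetted forests are a CO2 sink — while the
CH4 source (232 kg CH4-C ha⁻¹ yr⁻¹ with a fifth, single-site record
included) flips the net climate effect between horizons: warming at
GWP100 (+4491 kg CO2-eq ha⁻¹ yr⁻¹), cooling at GWP500 (−970), because
methane's potency fades from 25 to 7.6.

Simulating the restoration of a cutover peat-extraction site:

```sh
peatghg simulate --scenario restored_bog --years 300 --out traj.csv
```

prints

```json
{"cumulative_export_c": 0.0, "final_total_c": 728.6, "horizon": 300,
 "mean_annual_change_full": 0.142, "neutrality_year": 20,
 "scenario": "restored_bog"}
```

the site stops losing carbon in year 20 and thereafter sequesters
0.22 t C ha⁻¹ yr⁻¹, ending with more carbon (728.6 t C ha⁻¹) than it
started with. The drained managed forest scenario instead loses
0.9 t C ha⁻¹ yr⁻¹ from peat — about 0.53 t C ha⁻¹ yr⁻¹ at ecosystem
level once stand growth and the 100-year harvest cycle are accounted.

`peatghg report --out-dir results/` runs everything (balances at both
horizons, all six scenario trajectories, diagnostics) into one JSON +
text report; `peatghg synth` and `peatghg harmonize --mode literal` cover
the synthetic-data and unit-conversion stages. The same functionality is
importable (`peatghg.simulate`, `peatghg.balance_report`, …); see
`docs/methods.md` for the model description and design choices.

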