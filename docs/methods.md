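# Methods

## Scope

`peatghg` does three things: (1) it stores a literature compilation of
annual greenhouse-gas fluxes from boreal and temperate rewetted peatlands
with full unit provenance and harmonizes it to canonical units; (2) it
aggregates the harmonized fluxes into per-category means and converts them
to CO2-equivalent balances under selectable global-warming-potential (GWP)
factor sets; (3) it simulates 300-year carbon-stock trajectories of six
peatland land-use scenarios with an annual-step pool model and reports
trajectory diagnostics (carbon-neutrality year, mean annual carbon
change over stated windows).

## Flux table and unit harmonization

Each record keeps its values exactly as printed by the source — a point, a
min-to-max range, or a mean with a standard deviation/error — together
with the unit string its source reported. A value cell is reduced to a
single number by `collapse`: points and central values pass through,
ranges take the arithmetic midpoint (the sources give no within-range
distribution, and the midpoint is the only choice invariant under
symmetric widening).

The converter recognizes the unit dialects appearing in the compilation's
footnotes plus canonical forms, factorized into three independent parts:

* amount basis — element mass (CO2-C, CH4-C, N2O-N), molecule mass
  (×12/44, ×12/16, ×28/44 respectively), molar amount (×12 g C or
  28 g N per mol; N2O carries two N atoms), or CO2-equivalent mass
  (rescaled but kept on its equivalence basis and flagged);
* area — m² → ha (×10⁴);
* time — s/h/d → yr with a fixed 365-day, 8760-hour year. Leap-day
  handling is deliberately omitted: the inputs are annualized literature
  values and the effect is below 0.1 %.

Conversions are exact linear factors, so converting and back-converting
reproduces the input to floating-point precision.

**Two harmonization modes.** The compilation's caption declares the
tabulated numbers to be kg C (or kg N) ha⁻¹ yr⁻¹ already, while the
per-source footnotes list the original studies' units — and for several
rows those two statements are mutually inconsistent by orders of
magnitude. The default `paper` mode trusts the caption (values taken at
face value as canonical), which is the reading under which the published
category means (−928 kg CO2-C ha⁻¹ yr⁻¹ and 218 kg CH4-C ha⁻¹ yr⁻¹ for
rewetted forests) are exactly reproduced as unweighted means of the review
rows. The `literal` mode pushes each value through its footnote unit
instead; both readings stay available, and the fixture's `ambiguous` flag
plus note column record every cell whose printed form admits more than
one reading. Growing-season-only rates (`season_only`) are converted
per-time literally and excluded from annual category means — the sources
give no defensible season-to-year extrapolation rule.

## Category aggregation and CO2-equivalent balance

Category statistics are unweighted arithmetic means (no weighting by study
duration or area — the published means are plainly unweighted), computed
over the values present for each gas; empty selections raise an explicit
"no data" error rather than reporting zero. Display rounding is
half-away-from-zero to integer kg (−927.5 → −928).

The CO2-equivalent balance of per-gas means (NEE_C, CH4_C, N2O_N) is

    B = NEE_C·44/12 + g_CH4·CH4_C·16/12 + g_N2O·N2O_N·44/28   [kg CO2-eq ha⁻¹ yr⁻¹]

with GWP factor sets (25, 298) at the 100-year horizon and (7.6, 153) at
500 years; a (34, 298) climate–carbon-feedback variant ships for
sensitivity runs and users can supply any `GWPSpec`. The operator is
linear in each gas, so the balance of category means equals the mean of
per-record balances whenever all records report all three gases.

The subsets behind some published per-category means (open-peatland and
paludiculture NEE, shallow-lake/open-bog/paludiculture CH4) are not
uniquely identifiable from the printed table; the package reports its own
means for those categories and documents the gap rather than forcing a
match.

## Carbon-stock model

State: peat, stem, branch, coarse-root and harvest-residue carbon pools
(t C ha⁻¹) plus cumulative timber export, on integer years. All scenarios
start from the same peat stock, 686 t C ha⁻¹ — a 2 m peat column at
34.3 kg C m⁻³ — so trajectories differ only through management. Tree
biomass derives from stem volume V (m³ ha⁻¹) via wood density
420 kg m⁻³ and carbon fraction 0.5 (Scots-pine-typical values; the
compilation cites literature without printing numbers), with branches
12 % of stem biomass and coarse roots 19 % of above-ground biomass, so
total stand carbon is 0.279888 t C per m³ of stem volume. Fine roots are
not a pool; their turnover is absorbed into the net peat-flux schedule.

Rates are piecewise-linear annual schedules (linear interpolation between
breakpoints, constant after the last), evaluated at the year a step
arrives at; after a harvest the increment schedule restarts from stand
age zero. Step order within a year: stem growth (pools re-derived
allometrically), peat flux, first-order residue decay (0.05 yr⁻¹, the
decayed mass leaving the ecosystem), then any harvest due at the boundary.
A harvest exports stem carbon (no wood-product pool — removed timber is
an immediate ecosystem loss, the conservative convention when only stems
are removed), moves branch and root carbon to the residue pool, and
resets the stand. Harvests fall at whole multiples of the 100-year cycle
strictly inside the horizon; the end state is the standing, pre-harvest
ecosystem, which is what makes the drained-forest 300-year ecosystem loss
land in the 0.4–0.6 t C ha⁻¹ yr⁻¹ band even though its peat alone loses
0.9 t C ha⁻¹ yr⁻¹. Driving the peat pool below zero halts the simulation
with the failing year. Every step satisfies the bookkeeping identity
Δ(total + export) = peat flux + biomass growth − residue decay to
10⁻⁹ t C, and the model is bit-deterministic.

Scenario defaults (all overridable via YAML config):

| scenario | V₀ (m³ ha⁻¹) | increment (m³ ha⁻¹ yr⁻¹) | peat flux (t C ha⁻¹ yr⁻¹) | harvest |
| --- | --- | --- | --- | --- |
| pristine_open_bog | 3 | 0 | +0.22 | — |
| pristine_bog_forest | 100 | 0.1 | +0.072 | — |
| drained_managed_bog_forest | 0 | 4 | −0.9 | 100 yr |
| restored_bog | 0 | 0 | −2.0 → 0 by yr 20, then +0.22 | — |
| regenerated_unmanaged_forest | 0 | 0 (to yr 20) → 4 by yr 50 → 0.1 by yr 160 | −2.0 → 0 by yr 50 → +0.072 by yr 160 | — |
| managed_forest_on_cutover | 0 | 6 | −1.0 | 100 yr |

Calibration notes. The pristine-bog-forest peat flux +0.072 makes the
ecosystem's total change ≈ +0.1 t C ha⁻¹ yr⁻¹ once the 0.1 m³ yr⁻¹ stand
increment (0.028 t C yr⁻¹) is counted; the regenerated forest converges to
the same schedule by year 160 and therefore to the same 0.1 t C ha⁻¹ yr⁻¹
rate. The restored bog's initial −2.0 t C ha⁻¹ yr⁻¹ bare-cutover loss is a
calibrated round number placing carbon neutrality at year 20, after which
the site accumulates like a pristine open bog (+0.22). Literature quotes a
1.8 / 1.0 t C ha⁻¹ yr⁻¹ pair of peat-loss rates for drained former bogs
without an unambiguous referent; both are exposed as named presets
(`DRAINED_PEAT_LOSS_PRESETS`) and neither replaces the defaults. Whether
the 686 t C ha⁻¹ initial stock includes standing vegetation is not
stated for forested initial states; it is implemented as peat-only with
vegetation added on top. Lateral dissolved-organic-carbon export is not
modelled (it is only qualitatively bounded in the source literature);
users can fold a constant into a scenario's peat-flux schedule.

## Synthetic data

The generator draws per-category, per-gas values from a normal
distribution with known mean and sd in canonical units (defaults seeded
from the published category means), then re-expresses each value in a
randomly chosen reporting dialect by the exact inverse of the converter.
Value draws and dialect choices use separate seeded streams, so the
underlying value stream is invariant to the dialect mix — which is what
lets the tests show that harmonized means are unbiased by unit
representation. A signed log-normal option provides heavy tails for
robustness checks. The generator emulates the category/mixed-unit
structure of a literature compilation, not real peatland variability: no
spatial or temporal autocorrelation, no reporting bias, no correlated
gases. Passing recovery tests therefore validate the pipeline's
bookkeeping, not any ecological claim.

`perturb_scenario` multiplies every schedule rate and allometric ratio by
independent uniform factors in [1−a, 1+a] (a ≤ 0.5), leaving structural
fields untouched. Because the restored bog's year-20 zero crossing is a
breakpoint, pure amplitude scaling leaves the neutrality year at 20 — a
property the tests verify over 100 seeds.

## Problem sizes and numerical choices

Simulations run the full 300-year horizon (301 annual states, six
scenarios — milliseconds each). Statistical properties are tested at
100 seeds × 50 records per category, the scale at which a 3-standard-error
recovery criterion is meaningful. Tolerances: unit round-trips and the
step bookkeeping identity at 10⁻⁹ (pure floating-point pipelines), the
regenerated-forest convergence rate at ±0.005 t C ha⁻¹ yr⁻¹ (its exact
value, 0.09999, reflects the 0.279888 t C m⁻³ biomass factor). Ties in
`neutrality_year` cannot occur (the first non-negative annual change is a
strict scan); equal-endpoint range cells collapse to that endpoint.

## Known limitations

* The peat-flux schedules are prescribed, not process-based: no
  water-table, temperature or substrate feedbacks, and no CH4/N2O
  dynamics inside the stock model (those live in the flux compilation).
* Category means inherit every idiosyncrasy of the underlying
  compilation (mixed methods, periods and site ages); the package
  reproduces, it does not meta-analyze.
* The `paper` harmonization mode is a documented editorial judgement
  about an internally inconsistent table, not a physical conversion.
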