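# Methods

## Model structure

The package costs a hypothetical mandatory fortification program for a
widely consumed condiment vehicle (bouillon cubes) over a 10-year horizon
on an annual time step. Model years 1..`startup_years` (default 2) are the
start-up phase — planning, equipment purchase and installation, label
redesign, training — during which no fortification occurs and hence no
premix is bought. The remaining years are the operational phase:
production-side QA/QC, government monitoring, and premix procurement.

The total program cost is the exact sum of five components: firm and
government start-up costs, firm and government operational costs, and
premix cost (`TPC = SUC_F + SUC_G + OPC_F + OPC_G + PMX`). All values are
constant 2021 USD; no discount rate and no inflation are applied, so
totals are plain sums over years.

Only the population varies over time. Per-capita availability of the
vehicle, the domestic/imported split, the industrially-produced
(fortifiable) share, compliance with the standard, unit prices and wage
rates are held constant over the horizon. This is a deliberate modelling
assumption, not a software limitation: every such parameter accepts an
explicit per-year schedule through the line-item mechanism where that
matters (e.g. inspection intensity).

## Demand and premix quantities

National daily consumption is the sum over subnational strata of
`population x share x reach x intake` (reach = fraction consuming, intake
= g/day per consumer). Annual vehicle volume in MT is
`availability (g/capita/day) x population x 365 x 1e-6`; a year is 365
days. The volume splits exactly into domestic and imported streams by the
domestic share, and each stream's fortified part is
`stream x industrial_share x compliance` — compliance is the fraction of
product fortified to 100% of the standard, applied identically to
domestic and imported product.

Published national consumption totals are not exactly recomposable from
the published *rounded* per-stratum reach and intake values. The packaged
scenarios therefore carry a calibrated `availability_override`
(national daily consumption / population), and the strata remain for
structure and sensitivity work; the override and the strata-derived value
agree within ~2% (tested). The Nigeria override, 3.6332179 g/capita/day,
is calibrated so the 2023 annual volume reproduces the published 294,641
MT; it then reproduces every other published annual volume within 1 MT.

## Premix cost calculator

For each nutrient line, the fortificant amount per kg of vehicle is
`target_level x (1 + overage) / activity`: the target is grossed up by a
degradation overage (0.30 for the vitamins in the reference formulation,
0 for minerals) and divided by the compound's micronutrient mass fraction.
The addition rate (mg premix per kg vehicle) is an explicit input — a
helper suggests the smallest 250 mg/kg multiple at or above 110% of the
fortificant subtotal, but never silently overrides configuration. An inert
excipient fills the remaining premix mass at its own price, and the
blender's up-charge is added per kg of finished premix:

```
price/kg = sum_k (amount_k / addition_rate) x price_k
         + (excipient mass / addition_rate) x excipient price
         + up-charge
```

Landed prices per channel are `base x (1 + duty) + transport` (ad valorem
duty, flat per-kg transport/distribution/storage adder), and the premix
cost per MT of vehicle is `landed x addition_rate x 1e-3`. For the Nigeria
scenario the imported-product channel excludes the premix import duty
(the premix embedded in imported cubes is not cleared through domestic
customs) but keeps the transport adder; this reconciles the published
8-year premix total and its ~92/8 domestic/imported cost split. For
Senegal and Burkina Faso, where essentially all premix enters as imports,
the duty is applied on both channels.

Unit conventions (µg vs mg, dietary folate equivalents) are the caller's
concern: `level_from_nrv` takes an explicit conversion factor rather than
a nutrient lookup table.

## Cost schedules

A cost line item is `quantity x unit_price x scope multiplier x
year-schedule multiplier`, grossed up by markups that combine
**additively** (equipment duty 10% + shipping 10% + VAT 8% gross up the
equipment subtotal by exactly 1.28 — the multiplicative alternative does
not reproduce the published equipment total). Scope multipliers are the
factory count, the port count, or 1 for national items. Year schedules
express phase membership, periodic items (household monitoring in one
operational year), and intensity changes (factory inspections and their
sample reagents halve from the fourth operational year; import and
commercial monitoring stay constant).

Management/overhead is modelled as value-based percentages rather than
line items: firms pay 5% of the **domestic-channel** premix value
(procurement in hard currency, transport, storage, inventory
reconciliation; imported-product premix is managed by foreign producers),
and government pays 5% of its annual **monitoring** subtotal (factory,
import, commercial and household monitoring — not social marketing,
surveillance or training; the published yearly management figures pin this
base down, including the household-monitoring year).

Degenerate inputs behave predictably: zero compliance zeroes premix and
firm management while leaving all government costs unchanged; zero
fortified volume makes cost-per-MT undefined (reported as null, not an
exception); items scheduled at 0 contribute nothing.

## Calibration of the packaged scenarios

Published tables round unit costs to whole dollars; the published
subtotals, not the rounded unit prices, are treated as authoritative.
Packaged unit values are therefore stored unrounded, each calibrated to
reproduce its published subtotal exactly: factory inspection 161.9375
(96 inspections → 15,546), external lab test 62.28125 (96 tests → 5,979),
training session 249.125, labeling 327.125, government training session
4,982.625, factory labor wage 10,093.75, QA wage 12,617.25. Test reagents
carry per-context prices ($8/test in factory contexts, $7.63/test in
import/commercial monitoring), matching the respective published totals;
the published tables are internally inconsistent on this unit price and
the package does not attempt to resolve the intent.

Government start-up line items for Nigeria are not published; the scenario
stores category-level items (planning and laboratory equipment = 80% of
the two-year total, plus social marketing and training) calibrated so the
two-year government total equals the published combined start-up total
minus the itemized factory side (910,730 − 194,174 = 716,556).

The Senegal and Burkina Faso scenarios are flagged `approximate`: their
itemized schedules are not published, so each carries four aggregate line
items calibrated to published phase totals and government/industry share
splits, population series grown geometrically from the published 2021
base (2.6%/yr and 2.8%/yr), and availability derived from published
national consumption. They are intended for cross-country comparison of
summary metrics (notably cost per consumer reached), not for line-item
analysis. Out-year (operational years 5-8) government line items are
unpublished for every country; the Nigeria model's 8-year government
operational total is accordingly ~5% below the published decomposition,
and the 10-year grand total agrees within ~0.01%.

## Summary metrics

Cost per MT divides the 10-year TPC by cumulative fortified tonnage over
the operational years. Cost per consumer reached divides the mean annual
operational-phase cost (firm + government + premix) by the mean consuming
population over the operational years — the only definition that
reproduces the published per-consumer values for all three countries, and
documented here as a calibrated interpretation. Product requirements
(fortified MT/year, premix MT/year) are operational-phase annual
averages. Stakeholder shares are government, industry and premix
fractions of TPC (premix is reported as its own payer category because it
is ultimately passed to consumers through retail prices).

Sensitivity analysis is one-at-a-time: `sweep` deep-copies the scenario,
sets one numeric parameter per grid value, and re-runs the full engine.
No probabilistic uncertainty propagation is attempted.

## Random scenarios and what the tests show

`random_scenario(seed)` draws structurally valid configurations
(1-300M population, 1-15 strata, 1-6 nutrients, feasible addition rates,
random schedules and markups) for property testing: the five-component
identity, equivalence with an independent brute-force recomputation
(< 1e-9 relative), price homogeneity, monotonicity, and the
zero-compliance limit. These scenarios exercise the arithmetic, not
realism: they do not emulate correlated demographics, realistic premix
chemistry, or coherent cost structures, so passing property tests shows
the engine computes its stated model exactly — not that the model fits
any particular country.

## Known limitations

* Costs only: no nutritional benefit, coverage-to-adequacy, or
  cost-effectiveness modelling.
* No price pass-through behaviour; premix is reported as a payer category,
  not traced to retail prices.
* Constant prices and rates over the horizon; sweeps, not time series,
  address price uncertainty.
* Compliance is a single constant fraction — no ramp-up, no
  voluntary/mandatory dynamics.
* No partial-year proration: a model year is wholly start-up or wholly
  operational.
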