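# Methods

## The valuation model

`sroikit` implements the five-step SROI procedure (scope/stakeholders →
outcome mapping → evidencing and valuing → impact adjustment → ratio and
sensitivity) as a deterministic valuation pipeline over a declarative
`Scenario`.

Per outcome line the annual benefit is

    B_i = population × incidence_i × risk_reduction_i × unit_value_i × retention,
    retention = (1 − deadweight)(1 − displacement)(1 − attribution).

The case-study source never states this formula explicitly; it is the
engine's declared model, and it reproduces seven of the fourteen published
per-outcome values exactly (diarrhea, respiratory infection, acute otitis
media, higher IQ, type-1 diabetes, SIDS, hypertension). The remaining
seven published values (NEC, obesity, type-2 diabetes, breast cancer,
cardiovascular disease, formula cost, ovarian cancer) cannot be derived
from their own published inputs under any formula we could reconstruct;
they are carried on the fixture as `printed_value` annotations and the
engine always reports its own arithmetic alongside — discrepancies are
surfaced (WARN log lines on fixture runs), never silently matched.

### Streams, discounting, ratio

- **Drop-off** is modelled as geometric decay from year 2 onward:
  v_t = B_i (1 − δ)^(t−1), so year 1 pays the full annual value. The
  source says only that a share of benefits "declines over time"; the
  geometric form is the package's design choice (the standard SROI
  convention, and the only one consistent with a single annual rate).
- **Discounting** is end-of-period: NPV = Σ v_t (1+r)^(−t). The timing
  convention is likewise a design choice; the default rate is 4%/year,
  the recommended public-sector rate in the case study's setting.
- **Ratio**: SROI = (benefit basis − investment) / investment.
  `evaluate(mode="simple")` uses the annual benefit total as the basis —
  the reading that reproduces the case study's headline 55:1;
  `mode="npv"` uses the summed per-outcome NPV.
- **Rounding**: reported money rounds half-up to whole AUD (matches every
  reconcilable published row, e.g. 117.79 → 118, 8.57 → 9); reported
  integer ratios truncate toward zero (matches all six reproducible
  published sensitivity ratios, where round-to-nearest would fail three).
- **Payback** assumes uniform within-year accrual:
  months = 12 × investment / annual basis. The case study prints 0.63
  months, which no combination of its printed totals yields (12 ×
  24,433.80 / 1,375,050 = 0.21); the engine reports its own value.

### The published-total override

The case study's printed benefit total (AUD 1,375,050) does not equal the
sum of its printed rows (1,398,140), nor does the engine's row-sum
(1,321,865) equal either. `Scenario.total_benefit_override` holds a
published total so headline-ratio reproduction can use it while the
computed sum stays inspectable in every result. Sensitivity perturbations
keep the override coherent exactly: an adjustment change rescales it by
(1−new)/(1−old), a global value multiplier k scales it by k, and a change
to one outcome's incidence/risk-reduction/unit-value shifts it by that
outcome's reference annual value × (new/old − 1), preferring the
outcome's `printed_value` as the reference. Population changes do **not**
rescale the override: the one published population scenario (twins and
triplets) states no derivable mapping from birth multiplicity to the
valuation inputs, so no general rule is defensible.

### Tunable parameters

| Parameter | Units | Case-study default | Meaning |
|---|---|---|---|
| population | dyads/year | 1000 | annual birth cohort |
| deadweight | fraction | 0.05 | would have occurred anyway |
| displacement | fraction | 0.20 | displaced other activity |
| attribution | fraction | 0.25 | caused by other actors |
| drop_off | fraction/year | 0.20 | annual benefit decay from year 2 |
| discount_rate | fraction/year | 0.04 | end-of-period discounting |
| investment | AUD/year | 24,433.80 | annual program cost |
| duration_years | years | 3 / 30 / 15 / 2 | per outcome group: acute infant conditions 3; lifelong infant risks and cognition 30; maternal chronic-disease risks 15; formula purchase 2 |

Fractions are accepted as decimals or percent strings ("26%" → 0.26,
"0.008%" → 0.00008 — percent-of-one throughout). The exclusive
breastfeeding rate (97% at discharge) is stored as metadata but **not**
multiplied into the valuation by default: reverse-engineering the
reconcilable published rows shows they value the full cohort of 1000, not
970. `apply_breastfeeding_rate=True` exposes the alternative.

Fixture gaps filled by the package (both rows are among the documented
non-reconcilable ones either way): the type-2-diabetes proxy cell is
blank in the published proxy table, so the diabetes-treatment proxy
AUD 3131 is reused; the formula-cost line has no incidence/risk-reduction
pair, so the breastfeeding initiation rate (0.97) and exclusive-feeding
rate (0.154) stand in.

## Sensitivity analysis

`one_way_table` is strictly one-at-a-time: each perturbation is applied
to the base scenario independently and never compounded, matching the
row-per-change layout of published deterministic sensitivity tables.
Drop-off and discount-rate rows are evaluated in `npv` mode (they have no
effect on an annual basis); all other rows in `simple` mode. For
adjustment rows the reported ratio satisfies the closed form
trunc(((1−new)/(1−old)) × basis/investment − 1), the identity the tests
check exactly. `tornado_rank` orders rows by |Δ ratio| descending with
input order breaking ties.

The built-in `table4` set reproduces the published new-case ratios for
attribution → 50% (36), deadweight → 50% (28), displacement → 0% (69),
obesity odds-ratio variants (53, 57), the breast-cancer lower variant
(53), and total value ×0.5 / ×2 (27, 111). Three published rows are each
one unit away from every rounding convention tried (SIDS variants print
40/66 vs the engine's 41/65; the breast-cancer upper variant prints 57 vs
56); the engine reports its own arithmetic and the tests assert those
values as documented discrepancies. The published drop-off → 50% (16) and
discount → 6% (51) ratios presuppose stream arithmetic the source does
not disclose; the operations exist and run in `npv` mode, but their
published targets are not reproduction claims. Note the published
sensitivity table restates the breast-cancer base odds ratio as 4.3%
while the evidence table prints 4%; the built-in set pins
`base_value=0.043` so the published rescaling arithmetic is followed.

`monte_carlo_psa` extends the deterministic analysis with seeded draws
(point / uniform / triangular, bounds validated against each parameter's
range). It evaluates the ratio on the *computed* outcome sum with any
published-total override stripped — otherwise unit-value draws could not
move an override-based ratio. Identical (seed, n, specs) gives identical
summaries.

## Synthetic scenarios

`GeneratorSpec`/`generate_scenario` produce structurally valid random
scenarios for property-based testing: proxies sampled log-uniformly over
20–90,000 AUD (the four orders of magnitude the case study's proxy table
spans), durations from {2, 3, 15, 30} years, adjustments inside [0, 0.5],
cohorts of 200–5000, and investment drawn as 0.5–20% of the expected
annual benefit so ratios are always defined and plausible. One integer
seed drives a single `numpy` Generator; suites use consecutive seeds.
The generator emulates the *shape* of real SROI inputs, not their joint
epidemiology — incidence and odds ratios are sampled independently, so
passing property tests demonstrate algebraic correctness (NPV oracle
agreement, monotonicity, linearity, determinism) and nothing about
real-world effect sizes.

## Numerical choices and degenerate inputs

- All arithmetic in double precision; NPV closed-form vs year-by-year
  brute force agrees to 1e−9 relative (property-tested on 100 seeded
  scenarios plus hypothesis-generated streams).
- Zero incidence or risk reduction yields a zero benefit line, not an
  error; `duration_years < 1`, non-positive investment and negative
  discount rates are domain errors; all-zero adjustments (retention 1)
  are valid.
- Validation never clamps: out-of-range inputs are reported as
  field-addressed violations (`validate_scenario` returns them as data;
  loaders raise).
- Test and acceptance problem sizes: 100 synthetic scenarios for the
  property suites and 10,000 Monte Carlo draws for the linearity check —
  the whole suite completes in a few seconds.

## Known limitations

- No cost-effectiveness machinery (ICER/QALY), no currency conversion
  (all values AUD), no Sobol/variance-based sensitivity indices, no
  plotting (tornado data is emitted as CSV).
- The seven non-reconcilable published rows and the published
  total/net-yield/payback inconsistencies are documented and surfaced but
  cannot be resolved from the published material.
- Odds ratios are treated directly as relative risk reductions, as the
  source does; for common outcomes this overstates risk reduction.
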