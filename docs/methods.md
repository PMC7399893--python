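# Methods

## The model

`clts_cba` implements an ex-post societal cost–benefit analysis of a
community-led total sanitation (CLTS) intervention in 24 rural Ethiopian
villages, evaluated incrementally against routine health-extension-worker
(HEW) activity over the useful life of an improved latrine (T = 10 years,
constant 2016 international dollars).

The present value of benefits is

    TB_PV = sum_{t=1..T} sum_{k=1..3} B_tk (1+r)^-t

with three components per age band k ∈ {<5, 5–14, ≥15}:

1. **Averted mortality** — deaths averted × VSL_t. Deaths averted are
   cases averted × a case-fatality rate; the value of a statistical life is
   transferred from a US reference value by
   `VSL = VSL_ref × (GNI_local / GNI_ref)^elasticity`.
2. **Averted morbidity** — cases averted × per-case cost of illness:
   treatment (inpatient/outpatient blend), transport, meals, accommodation,
   one working day (8 h) of caregiver or own sick time, and HEW time.
   A "case" is a diarrhoea-day throughout; the under-5 effect is 1.5660
   days averted per child-year, scaled to the other bands by the baseline
   prevalence ratios 0.27 and 0.21. Self-treatment is valued at zero.
3. **Accessibility time savings** — people who switched from walking to an
   open-defecation site, communal latrine, or neighbour's latrine to their
   own latrine save `trips/day × minutes/60 × 365` hours per year, valued
   at the band's value of time. Under-5 time is not valued. Trip frequency
   is 6/day for women and 1/day for men (band average 3.5 at a 0.5 sex
   split).

Costs combine a top-down program ledger (training, facilitation,
management; capital rows for vehicles stored already prorated to project
duration), a bottom-up community/local ledger (people × hours × hourly
income, plus latrine construction materials at units × unit price and
construction time at the adult wage), and recurring operation & maintenance
and hygiene education, each 10 % of *annualized* initial capital per year.
Annualization uses the standard annuity factor `A(n,r) = (1-(1+r)^-n)/r`;
paying `f × K/A` for n years discounts back to exactly `f × K`, so the
O&M/education PV is independent of the discount rate — an identity the
tests check on a rate grid rather than assume. The 10 % base includes
program and community capital jointly (the printed 9,892 equals 10 % of
98,917, which supports the joint reading).

NPV = TB_PV − TC_PV; BCR = TB_PV / TC_PV; per-household and per-community
metrics divide NPV by 1,737 households and 24 communities.

## Timing and growth conventions

Flows occur at the end of year t and are discounted by (1+r)^-t. Incomes,
the VSL, and HEW wages are survey (time-0) values growing at g = 2 %/year,
valued in year t at `base × (1+g)^t`. Unit costs that are not income-linked
(treatment, transport, meals, accommodation) stay constant. The base
discount rate is r = 0.03: back-solving the published caregiver-time
present values for the rate yields 0.03000 independently in all three age
bands under this convention, and the same convention reproduces the
published lifespan sensitivity bounds to 0.1 %. The alternative
`(1+g)^(t-1)` indexing fits no single rate and was rejected.

Scenario dynamics follow the same `^t` convention: behavioural slippage
multiplies all three benefit quantities by `(1-s)^t` (s = 3.5 %/year by
default; sunk initial costs and O&M/education are unchanged), and the
population-growth variant scales populations by `(1+pg)^t` (default
2.5 %/year).

## Calibration of the packaged base case

Values printed in the source evaluation are carried as printed: populations
(1301/3804/4608), the trial effect and band ratios, CFRs
(0.07/0.05/0.03 %), the VSL transfer inputs and the printed transfer value
45,194 (kept as an override because direct computation of the transfer with
the printed, rounded GNI inputs gives 45,029), the 56 % facility
care-seeking share, 5 % hospitalization among cases, the 8-hour care day,
hourly income 0.67 (1286.4/year over 1920 working hours), value-of-time
fractions 0.5 (adults) and 0.25 (school-age), and both cost ledgers
line-by-line.

Unit quantities that the evaluation reports only inside present-value
aggregates (per-case treatment/transport/meal/accommodation costs, HEW
hours per case, communal-latrine trip minutes, and the switch fractions)
were back-solved from those aggregates under the printed anchors, and are
stored in `data/base_case.toml` with full precision. Consequences a user
should know:

- The sick/care day is valued at the adult fraction for under-5 cases (an
  adult caregiver loses the time) and at the band's own fraction otherwise
  — this is the only assignment consistent with the published per-band
  values.
- HEW time per facility-seeking case differs by band (≈3.25 h for under-5s,
  ≈0.82 h for older cases), so the care-seeking parameters carry an
  explicit `hew_hours_per_case` field.
- The reported deaths averted (14/3/5) are not equal to cases × CFR for
  the two older bands; the config pins them via `deaths_averted_override`
  together with the base-case case totals they refer to
  (`deaths_override_case_basis`). The engine converts the pair into an
  effective deaths-per-case rate, so horizons, effect sizes, and scenario
  multipliers scale deaths with cases instead of freezing the calibrated
  totals. The published per-band mortality values are mutually
  inconsistent under any single discount convention; the model reproduces
  their sum to 0.1 % and every other benefit cell to display rounding.
- The narrative's "20 pp switched from neighbours' latrines, 5 minutes per
  trip" jointly overshoots the corresponding published present value
  several-fold; the packaged config keeps the printed 5 minutes and the
  back-solved fraction (6.1 % of adults).

## Sensitivity analysis

One-way bounds follow the published design: latrine lifespan {5, 15}
years, adult value-of-time fraction {0.25, 0.75}, school-age fraction
{0, 0.5}, discount rate {0, 0.08}, trial effect at its 95 % CI bounds
{0.2, 2.6} days, and VSL elasticity {1.0, 2.0} (the elasticity range is a
package choice; varying it un-pins the VSL override, otherwise the bar
would collapse). Lifespan and adult-fraction changes touch every field
they imply (horizon; own-time and caregiver valuation), via named setter
aliases.

The Monte Carlo analysis draws parameters independently: effect ~ normal
(mean 1.566, sd from the CI half-width) truncated at 0; lifespan ~
triangular(5, 10, 15) rounded to whole years (the horizon is integral);
fractions and the discount rate uniform over their one-way ranges;
elasticity uniform(1, 2). One seeded generator produces columns in
declared parameter order, so adding a parameter never perturbs earlier
columns; identical (seed, n, distributions) reproduce results exactly.
Quantiles use linear interpolation between order statistics. The published
95 % credible intervals depend on an unavailable distribution table and
are treated as context, not reproduction targets; the packaged defaults
are documented and overridable.

## Synthetic trial generator

The generator emulates the trial the calibration came from: 24 villages
per arm, ~72 households per village of mean size 5.6, band mix
0.134/0.392/0.474, a 140-day diary for ~18 under-5 children per village
(with 75–100 % completion, matching the observed ~121 person-days per
child), control daily prevalence 773/52,467 (5.4 days/child-year), and an
intervention/control prevalence ratio of 0.71. Cluster correlation enters
through a mean-one lognormal village frailty (log-sd 0.35) multiplying the
arm prevalence; there is no within-child serial correlation — the simplest
structure consistent with a longitudinal-prevalence estimand. Care
episodes are runs of consecutive positive diary days, assigned
facility/drugstore/home/no care (0.56/0.03/0.04/0.37) with
hospitalization at 5 % of episodes (stay 1 + Poisson(4) days, mean 5).
Latrine states, trip minutes (normal around 9/7/5 minutes), and lognormal
household incomes (mean hourly 0.67) complete the rosters.

The effect estimator is a cluster-summary ratio of unweighted village-mean
longitudinal prevalences with a within-arm village-resampling percentile
bootstrap — deliberately simpler than the trial's covariate-adjusted,
stratified analysis, and honest about that approximation; it is unbiased
at the design size (relative error < 1 %, CI coverage ≈95 % over 200
replicates). Other parameters are recovered as sample proportions and
means; `switch_share_<source>` (prior use × switching) is the
population-share quantity that maps onto the CBA's switch fractions, while
`switch_<source>` is the conditional probability among prior users.
Strata with no observations fall back to the generating config and are
flagged. What passing recovery tests show is that the estimators are
consistent for data with this generative structure — not that real diary
data are free of recall bias, informative dropout, or seasonal confounding,
none of which are simulated.

## Numerical choices and degenerate inputs

- The annuity factor uses `expm1`/`log1p` with the r → 0 limit (= n) below
  1e-12, so tiny rates cannot underflow to a zero divisor.
- All internal arithmetic is full precision; CSVs round to 2 decimals and
  summary displays to integers, half-up, at write time only.
- BCR is undefined at zero total costs: scenario runs and table writers
  refuse rather than emit infinities.
- Validation is collect-all: `validate()` returns every violated rule with
  the field name, and loading fails listing all of them; unknown config
  keys are errors (fail-fast against typos).
- Ledger rows must use exactly one valuation form (money amount, people ×
  hours × rate, or units × unit price); the packaged community ledger
  stores the bottom-up triples, which reproduce the printed subtotals to
  <0.03 %.

## Problem sizes

The default test run generates trials at the full study design (48
villages, ~860 diaried children) and uses 200 replicates × 200 bootstrap
resamples for coverage, ~1 minute total; the acceptance script runs the
full pipeline plus five simulated trials in a few seconds.

## Known limitations

- Per-band mortality values cannot all be reproduced (inconsistent as
  published); only their aggregate is.
- The slippage and population-growth headline variants depend on appendix
  inputs; the package reproduces them to 0.5 % and 1.5 % respectively with
  its own documented defaults.
- No currency conversion, inflation adjustment, equity weighting, or
  cost-effectiveness (ICER) outputs; benefits beyond diarrhoea (helminths,
  nutrition, well-being, schooling) are out of scope by design.
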