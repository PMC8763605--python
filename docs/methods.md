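# Methods

`copecba` implements a trial-based cost–benefit analysis (CBA) of the COPE
program (Care of Persons with Dementia in their Environments) delivered
alongside Connecticut's home- and community-based services (HCBS). The unit
of analysis is the *dyad* — a person living with dementia and their family
caregiver — observed for one year before randomization (baseline, BL) and
one year after (month 12, M12). The package covers five stages: unit-cost
tables, a microcosting engine, a calibrated synthetic cohort, the
difference-in-difference (DID) analysis, and the HCBS payment-model and
cost-sharing calculators.

## Costing model

All costs are expressed in 2019 USD from an HCBS decision-maker
perspective, plus caregiver time as an indirect (societal) cost. Costing is
bottom-up: each utilization record (one quantity of one service for one
dyad-period) is multiplied by a unit cost.

**Wages.** Every wage enters in 2015 dollars (the source year of the
occupational wage data), is loaded with a 31.3% fringe-benefit rate, and is
inflated to 2019 with an annual CPI-style index:
`wage_2019 = w_2015 × (1 + 0.313) × I_2019 / I_2015`. Fringe and inflation
commute; the package applies fringe first as a presentational choice. The
packaged index is the CPI-U annual series (2015–2019), giving a 2015→2019
factor of ≈1.0786. The analysis the package reproduces cites an inflation
source without printing the factor, so the index is configuration, and
every exact reproduction test is written against quantities that do not
depend on it (the payment-model chain starts from already-inflated printed
components).

**Category rules.**

| category | rule |
|---|---|
| inpatient, ED | diagnosis-specific mean charge ÷ 3.4 (cost-to-charge ratio 1/3.4) |
| nursing home, long-term | days × facility's published daily rate |
| nursing home, rehabilitation | days × federal per-diem (2015, inflated) |
| respite | days × 8 h × HHA wage (fringe, inflated) — an HHA-time proxy |
| visiting nurse / HHA | visits × 30 min / 60 min × wage (fringe, inflated) |
| outpatient | visits × median procedure cost for the visit type (2015, inflated) |
| medications | doses × wholesale acquisition cost per dose |
| DME | units × reimbursement value |
| social worker | visits × 1 h × $31.09/h (2015; fringe, inflated) |
| meals | meals × $11.92 (2019) |
| transportation | round trips × $1.50 senior bus fare (2015, inflated) |
| adult day care | days × 8 h × $12.80/h (2019) |
| mileage | miles × $0.58/mile |
| caregiver time | min(weekly hours, 112) × 52 weeks × replacement wage |

Caregiver time uses the replacement-wage method: an employed caregiver with
a known occupation is valued at that occupation's wage; otherwise the HHA
wage applies. The 16 h/day cap is applied weekly as 16 × 7 = 112 h/week
because caregiving hours are reported per week — daily resolution does not
exist in the data. This makes per-dyad caregiver cost concave and
non-decreasing in reported hours and constant above 112 h/week.

Records whose `attribute` is `precosted` carry their cost directly in the
quantity field (unit rate 1). Intervention-delivery lines (training, OT/APN
time, travel time, debriefing, supplies, laboratory testing) are costed
upstream from program accounting records and always enter this way; the
synthetic cohort uses the same dialect for every category. The care-plan
line is ordinary care-management (CM) utilization: months × $108.10/month.

Money is never rounded internally. Rounding (half-up, to cents or dollars)
happens only at report rendering; this is load-bearing for the
payment-model chain, where $739.22 is reachable only from the unrounded
$528.0125 ($528.01 × 1.4 would display as $739.21).

**Lookup tables.** The diagnosis-charge, procedure-cost, drug-price,
equipment and facility-rate tables packaged in `data/default_costs.yaml`
are illustrative defaults so the engine runs out of the box; real analyses
replace them with jurisdiction-specific tables (YAML or two-column CSV).
The HHA wage ($10.87/h 2015), visiting-nurse wage ($34.14/h 2015), the
rehabilitation per-diem ($450/day 2015) and the occupation wage table are
likewise stated assumptions, as the source analysis does not print them.

## Synthetic cohort

No per-dyad records are published, so the generator emulates the study
conditions: 130 COPE and 120 usual-care dyads whose per-category group
means at BL and M12 equal the published cost table. Per dyad × period ×
category the cost is zero-inflated lognormal,
`Bernoulli(1 − p₀) × LogN(μ, σ)`, with `μ = log(m/(1 − p₀)) − σ²/2` so the
unconditional mean is exactly the target `m`, and `σ² = log(1 + CV²)`.

Only the means are published. The remaining distributional choices are
assumptions, fixed once:

* `p₀` per category (e.g. 0.90 nursing home, 0.95 respite, 0.70 inpatient,
  0.10 medications, 0.05 caregiver time), reflecting that institutional
  stays are rare and expensive while medication and caregiving costs are
  near-universal;
* conditional CV 2.0 for utilization-driven categories (heavily
  right-skewed), 0.3 for the administratively stable care-plan line;
* a Gaussian copula with correlation 0.3 between a dyad's BL and M12
  positive draws — the DID variance depends directly on this, so making it
  an explicit parameter keeps the inference property tests honest;
* intervention-delivery components other than the care plan are known
  program costs and are emitted as constants (COPE arm, M12 only;
  eligibility screening and a $0.14 trace of assessment materials also
  appear under usual care, mirroring the published table).

Seeding: one root seed; each dyad's stream is `default_rng([seed, index])`,
so enlarging the cohort never reshuffles earlier dyads' draws.

What the generator does **not** emulate: within-dyad correlation across
categories, dropout, covariate structure (age, CHCPE category are
independent of costs), or time trends within a period. Passing tests
therefore demonstrate that the pipeline's estimators and intervals behave
correctly under a realistic skewed, zero-inflated cost distribution with
the published means — not that they reproduce the trial's unpublished
per-dyad variability, which is why the published CI endpoints and
significance calls are not test targets.

For the sensitivity module the generator also emits per-dyad delivery
components in which travel time and mileage are rebuilt from drawn
per-visit round-trip minutes and miles (lognormal, CV 0.3, 12 visits per
dyad) whose means are chosen so the expected component costs equal the
published ones (≈36.9 min and ≈24.5 miles per round trip under the default
config). The per-visit detail is what the travel-cap scenarios act on.

## DID analysis

Per dyad and report row, `Δ = cost_M12 − cost_BL`; the DID is the
difference of arm means of Δ. Because means are linear, each block
subtotal's DID equals the sum of its components' DIDs exactly on unrounded
data, and the grand total equals the sum of the four subtotals.

**Uncertainty.** The published report prints 95% CIs without stating the
method; this package uses a nonparametric percentile bootstrap over dyads
within arm (default B = 10 000, seeded). In the full report all rows share
the same dyad resamples, keeping intervals internally consistent; the
standalone `bootstrap_ci` draws its own. With one dyad per arm the interval
degenerates to the point estimate with a warning.

**Testing.** Two-sided Wilcoxon rank-sum tests on the per-dyad Δ, exact
when both arms have ≤12 dyads with no ties, otherwise the normal
approximation with tie and continuity corrections (via
`scipy.stats.mannwhitneyu`; an independent enumeration oracle in the test
suite verifies the exact branch over every layout with n₁, n₂ ≤ 6). If all
values in both samples coincide the p-value is 1; if each arm is internally
constant but the arms differ (deterministic program-cost rows) the p-value
is reported as not applicable rather than as a degenerate rejection.

**Family.** The Bonferroni family defaults to 18 tests at α = 0.05
(threshold .05/18 = .00278): the 15 report rows with between-dyad variation
(care plan, nine health-service rows, four formal/social rows, caregiver
time) plus the health-care and formal/social subtotals and the grand total.
The source analysis states the family size but not its composition; this
enumeration matches the count of distinct stochastic p-value rows and the
family size is configurable.

Missing category-periods are $0 by construction (cost accounting), not
missing data; no imputation, regression adjustment, or GLM modeling of
costs is performed.

## Sensitivity analysis

Five univariate delivery-efficiency scenarios and their all-at-once
minimum: training at $0, external phone work omitted, round-trip travel
time capped at 40 min/visit, round-trip mileage capped at 20 miles/visit,
debriefing at half cost. Caps act per visit by rescaling the component by
`min(observed, cap)/observed`, which equals recosting the capped quantity
at the same wage or mileage rate. The share of "work outside intervention"
attributable to removable calls is not published; it is a parameter
(default 1.0, i.e. the whole line), which is why the published ~$1 522
minimum delivery cost is reproduced only approximately on synthetic data
and is not a test target. Since the five scenarios touch disjoint
components, the combined reduction is exactly the sum of the single-scenario
reductions — a property the tests exploit as an oracle.

## Payment model and cost sharing

The Connecticut Home Care Program for Elders (CHCPE) sets monthly care-plan
limits by benefit category ($3 143 for Category 2, $6 286 for Category 3)
and cost-sharing rates (9% and 0%). The program's per-dyad delivery cost
(the nine delivery components, $2 112.05; screening included, the CM line
excluded because CM enters separately at $108.10/month) is spread over 4
delivery months, loaded with 40% agency overhead, and combined with 12
months of CM:

    share = (monthly_cost × 1.40 × 4 + 108.10 × 12) / (limit × 12)

The printed source equation is typographically garbled; this reading —
annual program cost over annual allowance — is the one that reproduces both
published percentages (11.28% and 5.64%) and is therefore adopted. The
share is homogeneous of degree zero in money, decreasing in the limit and
increasing in every cost input.

Cost-sharing feasibility compares the monthly copayment (copay/session ×
sessions/month, default $25 × 3 = $75) against the category's cost-share
ceiling (9% × $3 143 = $282.87 for Category 2; $0 for Category 3, whose
participants pay nothing). Willingness-to-pay (WTP) responses are
summarized as the median per-session value and the per-category fraction at
or above a threshold (default $25).

## Numerical and scale choices

* All test and acceptance simulations are sized to finish in minutes on one
  core: bootstrap B = 1 000 inside replication studies and 5 000–10 000 for
  single reports; 200 cohort replications for coverage; 2 000 null
  simulations for the rank-sum size check; 10 000 dyads per arm for the
  calibration check.
* Bootstrap quantiles use the default linear interpolation of
  `numpy.quantile`.
* Stochastic tests are derandomized (fixed seeds) and assert statistical
  tolerances (3 SEs for means, 2 Monte-Carlo SEs for rejection rates,
  ≥93% for nominal 95% coverage).
* Degenerate inputs: zero-quantity records cost $0; an empty record list
  aggregates to an empty cost table; a zero-variance row yields a zero-width
  CI and an NA p-value; costing failures are collected across the batch and
  reported together with dyad identifiers.

## Known limitations

* Lookup-table defaults are illustrative, not a national fee schedule.
* The generator draws categories independently within a dyad, so
  cross-category cost correlation (e.g. inpatient stays predicting
  nursing-home entry) is absent; total-cost variance is correspondingly
  conservative relative to strongly clustered real data.
* Medication records must arrive with a resolvable drug key and dose
  count; reconstructing incomplete regimens is out of scope.
* The payment model parameterizes one state's HCBS rules; other states
  enter only through the limit/share parameters.
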