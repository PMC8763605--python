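# copecba

A cost–benefit analysis (CBA) pipeline for the **COPE** program (Care of
Persons with Dementia in their Environments) delivered through Connecticut's
home- and community-based services (HCBS). It is written for health
economists and HCBS decision makers who want to (re)run a trial-based
microcosting and difference-in-difference analysis, stress-test the
program's delivery cost, and ask whether the program fits inside a state
care-plan allowance and its participants' willingness to pay.

The unit of analysis is the *dyad*: a person living with dementia and their
family caregiver, observed for a baseline year and a follow-up year in a
two-arm pragmatic trial (COPE + HCBS vs HCBS alone, 130 / 120 dyads).

## What it computes

**Microcosting.** Utilization records (hospitalizations, nursing-home days,
home-health visits, medications, meals, caregiver hours, …) are converted
to 2019 USD with category-specific rules: charges ÷ 3.4 (cost-to-charge
ratio), days × per-diem, visits × duration × wage, doses × wholesale cost.
Wages carry a 31.3% fringe load and CPI inflation; caregiver time is valued
at a replacement wage, capped at 16 h/day.

**Difference-in-difference.** For report row *k* and dyad *i*,
Δᵢₖ = costᵢₖ(M12) − costᵢₖ(BL), and

&nbsp;&nbsp;&nbsp;&nbsp;DIDₖ = mean(Δₖ | COPE) − mean(Δₖ | usual care),

with percentile-bootstrap 95% CIs over dyads and two-sided Wilcoxon
rank-sum tests under a Bonferroni family of 18 tests (threshold
.05/18 = .00278).

**Sensitivity.** Five delivery-efficiency scenarios (free training, no
external calls, 40-minute and 20-mile round-trip travel caps, half-cost
debriefing) and their all-at-once minimum, as a tornado table.

**Payment model.** Share of the CHCPE monthly care-plan limit consumed by
the program: delivery cost over 4 months, +40% overhead, plus 12 months of
care management, divided by the annual allowance; plus a cost-sharing
check of a per-session copayment against the category's 9%/0% cost-share
ceiling and surveyed willingness to pay.

**Synthetic cohort.** No per-dyad trial records are public, so a seeded
generator draws zero-inflated lognormal costs calibrated so every
arm × period × category mean matches the published cost table, letting the
whole pipeline run and be validated end-to-end.

## Worked example

Run the full pipeline on a synthetic cohort at the trial's sample sizes:

```bash
cba all --out-dir demo --seed 7 --bootstrap 2000
cba payment-model
```

The payment model prints:

```
 chcpe_category  care_plan_limit_month  cope_cost_month  cope_admin_cost_month  cm_cost_month  annual_cost_with_cm  pct_consumed
              2                 3143.0           528.01                 739.22          108.1               4254.0         11.28
              3                 6286.0           528.01                 739.22          108.1               4254.0          5.64
```

Reading: delivering COPE costs $2 112.05 per dyad, i.e. $528.01/month over
its 4 delivery months; $739.22 with 40% agency overhead; a full benefit
year (4 program months + 12 months of care management at $108.10) costs
$4 254, which consumes 11.28% of a Category 2 care-plan allowance
($3 143/month) and 5.64% of Category 3 ($6 286/month) — COPE fits easily
inside existing limits.

From `demo/did_table.csv` (seed 7), the health-service block and grand
total on this synthetic cohort:

```
subtotal_health_care: DID -7223.40 (95% CI -19765.27, 5573.40) p=0.26
total:                DID -4981.10 (95% CI -17951.02, 7904.11) p=0.72
```

Negative DID means the COPE arm's costs fell relative to usual care — a
saving — with wide intervals, as expected for heavily skewed cost data at
n = 250. The generator's true grand-total DID is −$6 667 by calibration;
any one cohort scatters around it. `demo/tornado.csv` ranks the delivery
efficiencies (free training saves the most, $218.75/dyad) and
`demo/wtp_summary.csv` shows a median willingness to pay of $50/session
with a $75/month copayment well under the $282.87 Category 2 cost-share
ceiling.

Every output is a CSV; `manifest.json` records the run configuration. Two
runs with the same seed are byte-identical.

## Library use

```python
from copecba import (CohortParams, generate_cohort, aggregate_costs,
                     UnitCostConfig, did_table)

params = CohortParams(seed=7)
dyads, records = generate_cohort(params)
lines = aggregate_costs(records, UnitCostConfig.default())
report = did_table(lines, B=2000, seed=7)
```

Unit costs live in one YAML file (`copecba/data/default_costs.yaml`); pass
`--config your_costs.yaml` or `UnitCostConfig.from_yaml(...)` to supply
jurisdiction-specific wage, charge, drug and facility tables.

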