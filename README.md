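# mhealthecon

Economic evaluation toolkit for an mHealth care-coordination intervention
for people experiencing homelessness — a population with far higher
emergency-department (ED) and inpatient use than housed groups. The package
is written for health-economics analysts and implementation researchers who
need to answer three questions about such a program from a public-payer
perspective:

1. **What does it cost?** A microcosting engine enumerates every startup
   and recurring expenditure item (participant supplies, bus passes, phone
   plans, SMS-platform fees, health-information-exchange access, personnel)
   and rolls them up to total and per-participant-per-year (PPPY) costs,
   with named exclusion scenarios.
2. **When does it pay for itself?** An exploratory financial cost-benefit
   analysis computes the *savings threshold* — the minimum percentage
   reduction in average annual health-care costs *H* at which the program's
   financial benefits equal its PPPY cost *C*:

   *s\** = 100 · *C* / *H*,  with benefit-cost ratio *B*(*s*) = (*s*/100) · *H* / *C*

   and a probabilistic sensitivity analysis (PSA) propagates uncertainty in
   *C*, the unit costs (gamma distributions), and the annual visit counts
   (Poisson) through 10,000 Monte-Carlo draws.
3. **What would scaling it cost a payer?** A 5-year budget impact analysis
   (BIA) projects the local population forward, applies eligibility and
   participation fractions, prices the program (one-time fixed startup,
   variable startup, recurring PPPY), and nets out assumed health-care
   savings.

A synthetic-data module generates expenditure ledgers and person-level
utilization tables with the same statistical structure (lognormal unit-cost
jitter; Poisson visits with gamma per-visit costs), so every stage is
testable against known ground truth.

## Worked example

```python
from mhealthecon import (
    BIAConfig, HealthcareCostParams, PSAConfig,
    annual_healthcare_cost, default_ledger, run_bia, run_psa,
    savings_threshold, summarize, summarize_psa,
)

summary = summarize(default_ledger(n_participants=60))
C = float(summary.total_pppy)                      # 2865.34 US $ PPPY
H = annual_healthcare_cost(HealthcareCostParams()) # 36917.0 US $/person/year
print(round(savings_threshold(C, H), 1))           # 7.8

print(summarize_psa(run_psa(PSAConfig(seed=2022))))
# {'median_pct': 8.2, 'mean_pct': 20.9, 'pi95_low_pct': 3.1,
#  'pi95_high_pct': 128.7, 'n_draws': 10000, 'n_excluded': 78}

table = run_bia(BIAConfig())
print(round(table.total_participants))              # 10250
print(round(table.total_financial_cost))            # 28654438
print(round(table.total_net_impact(7.0)))           # 2167300
```

Reading the numbers: the program costs $2,865.34 per participant per year
against average annual inpatient+ED costs of $36,917, so it breaks even if
it averts 7.8% of those costs — about one hospitalization or two ED visits
per participant-year. Under input uncertainty the break-even point has
median 8.2% but a long right tail (mean ≈ 21%): simulated worlds in which
participants use little care need implausibly large percentage savings.
Scaled to a metropolitan area, 10,250 participant-years over 5 years cost
$28.7M, falling to a net $2.2M if 7% of health-care costs are averted.

The `examples/` directory has one short narrative script per capability
(cost analysis, scenarios, cost-benefit, PSA, budget impact, synthetic
round-trip); each prints the numbers above with a line on what they mean.

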