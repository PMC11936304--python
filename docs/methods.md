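# Methods

This note documents the models behind `mhealthecon`, the parameters that
matter, the numerical conventions, and the design choices made where the
published evidence base left the design open. All monetary values are 2022
US dollars.

## Microcosting model (`mhealthecon.costs`)

Each expenditure item is a `(unit_cost, quantity_rule, quantity,
period_months)` tuple whose 1-year, all-participant cost is a pure function
of those fields plus the participant count *n*:

| rule | annualized cost |
|---|---|
| `per_participant_once` | unit × qty × n |
| `per_participant_per_month` | unit × qty × 12 × n |
| `per_participant_per_period` | unit × qty × (12 / period_months) × n |
| `per_program_once` | unit × qty |
| `per_program_per_month` | unit × qty × 12 |
| `per_program_per_hour`, `per_hour_total` | unit × qty (qty = annual hours) |

Money is held as exact `decimal.Decimal`; totals are therefore additive to
the cent and rounding (half-up) happens only at presentation — PPPY values
to cents, scenario tables to whole dollars. The horizon is fixed at one
year; multi-year costing lives in the budget impact module.

The packaged trial ledger (60 participants) reproduces the published
itemized tables to the cent. Two source-data inconsistencies are resolved
in the ledger itself:

* The HIE (health information exchange) data-access line prints an hourly
  rate, an hours figure, and a total that are mutually inconsistent
  (200/h × 750 h ≠ 15,000). Subtotals and grand totals are consistent with
  15,000, so the ledger stores 200/h × 75 h.
* The program-related startup items (SMS-platform implementation, training
  materials printing) are stored as one-time program totals (3,588.00 and
  618.59); the per-participant unit costs printed for them are rounded
  presentation values whose product with 60 does not equal the totals.

Personnel costs are derived from staffing rules: the case manager carries
24 participants per 20 h/week (for the 60-participant trial the observed
staffing total of 2,500 h/year — 1.25 FTE — overrides the rule's 2,600 h so
expenditure tables reproduce exactly; `trial_override=False` gives the pure
linear rule). The program coordinator spends 1 h setup + 1 h training per
participant plus 2 h/week maintenance (224 h/year at n = 60).

Scenario specifications are exclusion sets: A drops all startup items, B
the bus pass, C HIE data access, D both. Removing an item reduces every
roll-up by exactly that item's annualized cost, which the property suite
asserts for arbitrary ledgers and exclusion sets.

## Cost-benefit analysis (`mhealthecon.cba`)

Average annual health-care cost per person:

H = mean_ip · c_ip + mean_ed · c_ed = 2 × 16,609 + 3 × 1,233 = 36,917.

The unit costs (inpatient $16,609, SE $860; ED $1,233, SE $66) are national
survey estimates. The visit means (2 inpatient, 3 ED) are **configuration,
not observed constants**: they are the decomposition consistent with the
published annual total and with utilization studies in the same setting,
not literal weighted averages from a primary source, and both are exposed
as parameters. (The total is also variously printed as 36,916; the package
always computes H from components, giving 36,917, and treats 36,916 as a
rounding artifact.)

Savings threshold s\* = 100·C/H and benefit-cost ratio B(s) = (s/100)·H/C.
B is linear in s with B(0) = 0 and B(s\*) = 1 exactly (an algebraic
identity asserted to 1e-12). Presentation rounding: thresholds to 1
decimal, BCRs to 2 decimals, half-up. Benefits are purely financial averted
health-care spending; no health-outcome or quality-of-life valuation is
attempted.

## Probabilistic sensitivity analysis (`mhealthecon.psa`)

Five independent inputs per draw:

* intervention PPPY cost C ~ Gamma(mean 2,865.34, CV 0.10),
* inpatient unit cost ~ Gamma(mean 16,609, sd 860),
* ED unit cost ~ Gamma(mean 1,233, sd 66),
* inpatient visits ~ Poisson(2), ED visits ~ Poisson(3),

with gamma parameters by method of moments (shape = (mean/sd)², scale =
sd²/mean) and per-draw threshold 100·C/(n_ip·c_ip + n_ed·c_ed). Defaults:
10,000 draws, seeded `numpy` Generator (bit-identical reruns), percentiles
by linear interpolation between order statistics so the 95% probable
interval is reproducible.

Design choices that are genuinely open, and their consequences:

* **Intervention-cost dispersion.** No standard error accompanies the PPPY
  cost estimate, so the gamma spread is a coefficient of variation, default
  0.10 — roughly spanning the scenario range (2,120–2,865). The median of
  the threshold distribution is insensitive to this choice; the mean and
  the upper interval bound are not.
* **Zero-denominator draws.** A draw with no visits at all (probability
  e⁻⁵ ≈ 0.7% under the default means) has an infinite threshold. The
  default policy redraws the full joint sample (a finite reported mean
  implies infinite draws were not retained); `drop` and `cap` are provided.
* **Independence.** No correlation structure among the five inputs is
  modelled.

Under the defaults the median lands at ≈ 8.1–8.2% with a heavily
right-skewed distribution (mean ≈ 20–21%, 95% interval ≈ (3.1, ~110–130)).
Because the dispersion of C and the zero-denominator handling are modelling
choices rather than published quantities, the mean and the interval's upper
bound should be read as order-of-magnitude statements only; the acceptance
suite holds the median to ±1 percentage point and checks the skew
qualitatively (mean > median).

## Budget impact analysis (`mhealthecon.bia`)

Population P_t = 3,990 × 1.034^(t−1) over a 5-year horizon; participants
n_t = P_t × 0.60 (eligibility) × 0.80 (participation), kept unrounded
internally (displayed integers never feed back into computation). Costs per
year: a one-time fixed startup cost of 4,206.59 (SMS-platform
implementation 3,588 + training-material printing 618.59, paid in year 1
regardless of enrollment), variable startup of 195.30 per participant
(supplies), and recurring 2,599.93 per participant. Net budget impact at
savings fraction s: total cost − (s/100) × 36,917 × n_t. No discounting and
no market-share or comparator-mix dynamics are modelled.

**Inflation discrepancy.** A 2.3% medical inflation rate is stated for
future costs, but the published per-year schedule grows at exactly the
population growth rate with constant PPPY unit costs — consistent only with
uninflated costs. Reproduction mode therefore defaults `inflation_rate=0`;
the 2.3% value is available as a parameter (`MEDICAL_INFLATION_RATE`).

The exact unrounded PPPY values behind the published table are not
recoverable (its cells differ from any direct recomputation by up to
~0.05%, the source's own intermediate rounding), so the table is reproduced
to a relative tolerance of 0.1% rather than to the dollar. The cost basis
can also be taken from any ledger scenario via
`BIAConfig.from_cost_summary`, e.g. to run the BIA without HIE fees.

Break-even consistency with the CBA: in years without the fixed cost, the
net impact is exactly zero at s = 100 × (195.30 + 2,599.93)/36,917 ≈ 7.57%
— slightly below the headline 7.8% because the BIA cost basis replaces the
trial's per-participant program startup with the one-time fixed cost.

## Synthetic data (`mhealthecon.synthetic`)

The generator emulates the two input structures the analysis consumes:

* **Expenditure ledgers** with the exact packaged item structure and unit
  costs jittered by mean-1 lognormal factors (σ² = ln(1+CV²), μ = −σ²/2;
  multiplicative noise keeps costs positive), quantized to cents. CV = 0
  returns the packaged ledger, byte-identical through the CSV writer.
* **Person-level utilization**: Poisson visit counts and per-visit gamma
  costs summed per person (a sum of n iid gammas is drawn directly as a
  gamma with n-fold shape). The per-visit cost spread (default sd = 0.5 ×
  unit cost) is **not a published quantity** — the published SEs are
  standard errors of survey means — so it is an explicit free parameter.

`recover_parameters` inverts the generator by method of moments (sample
visit means; total spending over total visits), and the round-trip
generate → recover → threshold reproduces the deterministic 7.8% within
Monte-Carlo error that shrinks with the number of simulated people (tested
at 2,000 and 50,000; Ĥ within 1% at 50,000).

What passing tests show — and do not show — about real data: the generator
matches the *assumed* data-generating process (independent Poisson counts,
gamma costs, no intervention effect on utilization, no person-level
correlation between visit frequency and visit cost). Real utilization among
people experiencing homelessness is overdispersed and correlated across
services, so parameter recovery here validates the pipeline's statistics,
not the epidemiology.

## Numerical conventions and problem sizes

Decimal money with half-up presentation rounding; numpy float64 elsewhere.
Seeded `numpy.random.default_rng` for all stochastic components. Default
problem sizes (10,000 PSA draws; 10,000–50,000 simulated people in the
synthetic round-trip; 200 ledger replicates in the jitter-bias check) give
Monte-Carlo error comfortably inside every asserted tolerance while the
full suite runs in a few seconds. Degenerate inputs are defined behavior:
empty ledgers summarize to zero with a warning, zero-variance PSA
configurations collapse exactly to the deterministic threshold, and
pathological configurations (all-zero visit means with fixed counts) fail
with a diagnostic rather than looping.
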