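"""Probabilistic sensitivity analysis of the savings threshold.

Draws 10,000 joint samples — gamma-distributed intervention and unit costs,
Poisson-distributed annual inpatient/ED visit counts — and summarizes the
resulting savings-threshold distribution. The distribution is heavily
right-skewed: draws with few visits imply a small health-care denominator
and hence a very large break-even savings percentage, so the mean sits far
above the median.
"""

from mhealthecon import PSAConfig, run_psa, summarize_psa

result = run_psa(PSAConfig(seed=2022))
report = summarize_psa(result)

print(f"Draws:                    {report['n_draws']:,} "
      f"(zero-denominator redraws: {report['n_excluded']})")
print(f"Median savings threshold: {report['median_pct']}%")
print(f"Mean savings threshold:   {report['mean_pct']}%")
print(f"95% probable interval:    ({report['pi95_low_pct']}%, "
      f"{report['pi95_high_pct']}%)")
print()
print(
    "Half of the simulated worlds break even below the median; the long "
    "right tail (mean >> median) reflects uncertainty in how much care "
    "participants actually use."
)
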