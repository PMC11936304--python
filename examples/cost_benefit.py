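"""Financial cost-benefit analysis: savings threshold and BCR curve.

Combines the PPPY intervention cost C with the average annual inpatient+ED
cost H among people experiencing homelessness (2 inpatient visits x $16,609
+ 3 ED visits x $1,233 = $36,917). The savings threshold s* = 100 C/H is
the minimum % reduction in H at which financial benefits equal costs; the
benefit-cost ratio B(s) = (s/100) H / C grows linearly with the assumed
savings.
"""

from mhealthecon import (
    HealthcareCostParams,
    annual_healthcare_cost,
    bcr_curve,
    default_ledger,
    summarize,
)

params = HealthcareCostParams()
C = float(summarize(default_ledger(60)).total_pppy)
result = bcr_curve(params, C)

print(f"Intervention cost C:        ${C:,.2f} PPPY")
print(f"Annual health-care cost H:  ${annual_healthcare_cost(params):,.0f}")
print(f"Savings threshold s*:       {result.savings_threshold_pct:.1f}%")
print()
curve = result.bcr_curve
marks = curve[curve.savings_pct.isin([0, 10, 25, 50])]
print(marks.round({"bcr": 2}).to_string(index=False))
print()
b25 = curve.loc[curve.savings_pct == 25, "bcr"].iloc[0]
print(
    f"At 25% savings the BCR is {b25:.2f}: every $1 spent on the program "
    f"returns ${b25 - 1:.2f} in net health-care savings."
)
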