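"""Exclusion scenarios: how the PPPY cost and savings threshold move when
cost items are dropped.

Scenario A keeps recurring costs only; B drops the bus pass; C drops HIE
(health information exchange) data access, a trial-monitoring expense a
real-world deployment may not need; D drops both. Each row shows the
whole-dollar PPPY cost and the savings threshold — the minimum % reduction
in average health-care costs at which the program pays for itself.
"""

from mhealthecon import default_ledger, scenario_analysis, standard_scenarios

table = scenario_analysis(default_ledger(60), standard_scenarios())
cols = ["startup_pppy", "recurring_pppy", "total_pppy", "savings_threshold_pct"]
print(table[cols].to_string())
print()
print(
    "Dropping the bus pass and HIE access (scenario D) cuts the PPPY cost "
    f"to ${table.loc['D', 'total_pppy']:,} and the break-even savings to "
    f"{table.loc['D', 'savings_threshold_pct']}%."
)
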