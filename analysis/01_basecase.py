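"""Base-case cost-effectiveness of seven G-CSF prophylaxis strategies.

Evaluates no / secondary / primary prophylaxis with filgrastim, lenograstim
and pegfilgrastim over the two-phase cohort model, labels dominance, and
reports the ICERs along the efficient frontier against the NT$976,914/QALY
willingness-to-pay threshold (1x Taiwan 2022 GDP per capita).

Writes results/basecase.csv.
"""

from pathlib import Path

from gcsf_cea import (
    base_strategies,
    build_frontier,
    default_life_table,
    default_parameters,
    evaluate_strategies,
)

out_dir = Path(__file__).resolve().parents[1] / "results"
out_dir.mkdir(exist_ok=True)

params = default_parameters()
life_table = default_life_table()

frontier = build_frontier(evaluate_strategies(base_strategies(), params, life_table))
df = frontier.to_dataframe()
df.to_csv(out_dir / "basecase.csv", index=False)

print(df.round({"cost": 0, "incremental_cost": 0, "qalys": 2,
                "incremental_qalys": 2, "icer": 0}).to_string(index=False))
print()
print("Efficient frontier:", " -> ".join(frontier.labels("frontier")))
for icer in frontier.frontier_icers:
    verdict = "cost-effective" if icer < params.wtp else "NOT cost-effective"
    print(f"  frontier ICER NT${icer:,.0f}/QALY ({verdict} at NT${params.wtp:,.0f}/QALY)")
print("Dominated:", ", ".join(frontier.labels("dominated")))
print("Extended dominance:", ", ".join(frontier.labels("extended_dominated")))
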