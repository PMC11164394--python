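"""Scenario analyses.

Scenario 1 removes the reduced-dose-intensity -> long-term-mortality link
(G-CSF affects only FN incidence and FN deaths): QALYs rise for every
strategy and secondary filgrastim prophylaxis re-enters the frontier.
Scenario 2 adds the filgrastim and pegfilgrastim biosimilars at their lower
reimbursement prices: each reference product is dominated by its biosimilar.

Writes results/scenario1.csv and results/scenario2.csv.
"""

from pathlib import Path

from gcsf_cea import default_life_table, default_parameters
from gcsf_cea.sensitivity import run_scenario

out_dir = Path(__file__).resolve().parents[1] / "results"
out_dir.mkdir(exist_ok=True)

params = default_parameters()
life_table = default_life_table()

for which, title in [(1, "G-CSF has no impact on long-term survival"),
                     (2, "including biosimilars")]:
    frontier = run_scenario(which, params, life_table)
    df = frontier.to_dataframe()
    df.to_csv(out_dir / f"scenario{which}.csv", index=False)
    print(f"Scenario {which}: {title}")
    print(df.round({"cost": 0, "qalys": 2, "icer": 0})[
        ["strategy", "cost", "qalys", "status", "icer"]].to_string(index=False))
    print()
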