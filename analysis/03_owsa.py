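"""One-way sensitivity analysis: tornado tables and a threshold search.

Recomputes two comparisons' ICERs at every parameter's range endpoints:
(a) primary lenograstim prophylaxis vs no prophylaxis, and (b) primary
pegfilgrastim vs primary lenograstim prophylaxis.  Then finds the
pegfilgrastim relative risk at which comparison (b)'s ICER crosses the
willingness-to-pay threshold.

Writes results/tornado_pp_lenograstim_vs_none.csv and
results/tornado_pp_pegfilgrastim_vs_pp_lenograstim.csv.
"""

from pathlib import Path

import pandas as pd

from gcsf_cea import default_life_table, default_parameters, strategy_by_id
from gcsf_cea.sensitivity import run_tornado, threshold_search

out_dir = Path(__file__).resolve().parents[1] / "results"
out_dir.mkdir(exist_ok=True)

params = default_parameters()
life_table = default_life_table()

comparisons = {
    "pp_lenograstim_vs_none": ("pp_lenograstim", "none"),
    "pp_pegfilgrastim_vs_pp_lenograstim": ("pp_pegfilgrastim", "pp_lenograstim"),
}
for name, (a, b) in comparisons.items():
    entries = run_tornado((strategy_by_id(a), strategy_by_id(b)), params, life_table)
    df = pd.DataFrame(
        [{"parameter": e.parameter, "icer_at_low": e.icer_at_low,
          "icer_at_high": e.icer_at_high, "span": e.span} for e in entries]
    )
    df.to_csv(out_dir / f"tornado_{name}.csv", index=False)
    print(f"Tornado {name} (top 5 by ICER span):")
    print(df.head(5).round(0).to_string(index=False))
    print()

crossing = threshold_search(
    "rr_pegfilgrastim",
    (strategy_by_id("pp_pegfilgrastim"), strategy_by_id("pp_lenograstim")),
    params.wtp,
    params,
    life_table,
    bracket=(0.334, 0.5),
)
print(
    f"Primary pegfilgrastim prophylaxis stops being cost-effective vs primary\n"
    f"lenograstim when its FN relative risk exceeds {crossing:.3f} "
    f"(at WTP NT${params.wtp:,.0f}/QALY)."
)
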