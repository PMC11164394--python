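"""Strategy totals, the efficient frontier, dominance and ICERs.

Each strategy is summarised by a lifetime (total cost, total QALY) pair.
Costs arise only in the chemotherapy phase (G-CSF plus FN hospitalisation);
QALYs are chemotherapy-phase QALYs plus post-chemotherapy QALYs mixed over
the four (FN history x RDI) strata the cohort splits into at the end of
chemotherapy.  Strategies are then ordered by cost, strongly dominated ones
(at least as costly, no more effective) removed, extended dominance applied
(a strategy is removed when skipping it yields a lower incremental
cost-effectiveness ratio, i.e. the ICER sequence along the frontier must be
strictly increasing), and ICERs computed between successive frontier members
from unrounded values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .chemo import classify_rdi, run_chemo_phase
from .parameters import ParameterSet, Strategy
from .survival import LifeTable, run_post_chemo

__all__ = [
    "StrategyResult",
    "FrontierEntry",
    "Frontier",
    "evaluate_strategy",
    "evaluate_strategies",
    "build_frontier",
    "nmb",
]


@dataclass(frozen=True)
class StrategyResult:
    strategy: Strategy
    total_cost: float
    total_qalys: float


def _postchemo_pair(params: ParameterSet, life_table: LifeTable, scenario1: bool):
    """Discounted post-chemo QALYs for the (RDI>=85%, RDI<85%) strata."""
    hi = run_post_chemo(False, params.start_age, life_table, params, scenario1)
    lo = run_post_chemo(True, params.start_age, life_table, params, scenario1)
    return hi.discounted_qalys, lo.discounted_qalys


def evaluate_strategy(
    strategy: Strategy,
    params: ParameterSet,
    life_table: LifeTable,
    scenario1: bool = False,
    _postchemo: tuple[float, float] | None = None,
) -> StrategyResult:
    """Lifetime total cost and QALYs for one strategy.

    Total cost is chemotherapy-phase cost only (no discounting; all costs
    fall within the first year).  Total QALYs add, to the chemotherapy-phase
    QALYs, each survivor stratum's mass times its discounted post-chemo
    QALYs, with the RDI<85% probability depending on FN history.
    """
    chemo = run_chemo_phase(strategy, params)
    p_low = classify_rdi(chemo, params)
    q_hi, q_lo = _postchemo if _postchemo is not None else _postchemo_pair(
        params, life_table, scenario1
    )
    q_post = 0.0
    for hist, mass in (
        (False, chemo.survivors_without_history),
        (True, chemo.survivors_with_history),
    ):
        q_post += mass * ((1.0 - p_low[hist]) * q_hi + p_low[hist] * q_lo)
    return StrategyResult(
        strategy=strategy,
        total_cost=chemo.total_cost,
        total_qalys=chemo.qaly_chemo + q_post,
    )


def evaluate_strategies(
    strategies: Iterable[Strategy],
    params: ParameterSet,
    life_table: LifeTable,
    scenario1: bool = False,
) -> list[StrategyResult]:
    """Evaluate several strategies, sharing the two post-chemo survival runs."""
    pair = _postchemo_pair(params, life_table, scenario1)
    return [
        evaluate_strategy(s, params, life_table, scenario1, _postchemo=pair)
        for s in strategies
    ]


def nmb(result: StrategyResult, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold (NTD/QALY)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return result.total_qalys * wtp - result.total_cost


@dataclass(frozen=True)
class FrontierEntry:
    result: StrategyResult
    status: str  # "frontier" | "dominated" | "extended_dominated"
    icer: float | None  # vs previous frontier member; None for the cheapest


@dataclass(frozen=True)
class Frontier:
    """Cost-ordered strategies with dominance labels and frontier ICERs."""

    entries: tuple[FrontierEntry, ...]

    def __iter__(self):
        return iter(self.entries)

    def labels(self, status: str) -> list[str]:
        return [e.result.strategy.label for e in self.entries if e.status == status]

    @property
    def frontier_icers(self) -> list[float]:
        return [e.icer for e in self.entries if e.status == "frontier" and e.icer is not None]

    def to_dataframe(self) -> pd.DataFrame:
        """Results-table layout: cost-ordered rows with incremental columns.

        Incremental cost/QALY are versus the previous row in cost order;
        the ICER column shows the frontier ICER for frontier members and
        the dominance status otherwise.  Values are unrounded; round only
        at presentation.
        """
        rows = []
        prev = None
        for e in self.entries:
            row = {
                "strategy": e.result.strategy.label,
                "cost": e.result.total_cost,
                "incremental_cost": None if prev is None else e.result.total_cost - prev.total_cost,
                "qalys": e.result.total_qalys,
                "incremental_qalys": None if prev is None else e.result.total_qalys - prev.total_qalys,
                "status": e.status,
                "icer": e.icer,
            }
            rows.append(row)
            prev = e.result
        return pd.DataFrame(rows)


def _sort_key(r: StrategyResult):
    # cost ascending; ties: more effective first; residual ties: label order
    return (r.total_cost, -r.total_qalys, r.strategy.label)


def build_frontier(results: Sequence[StrategyResult]) -> Frontier:
    """Identify dominated / extended-dominated strategies and frontier ICERs.

    Strong dominance: another strategy costs no more and yields no fewer
    QALYs, with at least one strict inequality (exact ties in both are kept,
    ordered by label).  Extended dominance: among the remaining strategies in
    cost order, any member whose segment ICER is not strictly below the next
    segment's is removed, iteratively, leaving a strictly increasing ICER
    sequence.  All comparisons use exact computed values.
    """
    if not results:
        raise ValueError("need at least one strategy result")
    ordered = sorted(results, key=_sort_key)

    status = {}
    for r in ordered:
        dominated = any(
            (s.total_cost <= r.total_cost and s.total_qalys >= r.total_qalys)
            and (s.total_cost < r.total_cost or s.total_qalys > r.total_qalys)
            for s in ordered
            if s is not r
        )
        status[id(r)] = "dominated" if dominated else "frontier"

    def _segment_icer(a: StrategyResult, b: StrategyResult) -> float | None:
        dc = b.total_cost - a.total_cost
        dq = b.total_qalys - a.total_qalys
        if dc == 0 and dq == 0:
            return None  # exact tie: duplicate point, both retained
        return dc / dq if dq > 0 else float("inf")

    candidates = [r for r in ordered if status[id(r)] == "frontier"]
    # iterative extended-dominance elimination
    while len(candidates) >= 3:
        icers = [_segment_icer(a, b) for a, b in zip(candidates, candidates[1:])]
        for i in range(len(icers) - 1):
            if icers[i] is None or icers[i + 1] is None:
                continue
            if icers[i] >= icers[i + 1]:
                status[id(candidates[i + 1])] = "extended_dominated"
                del candidates[i + 1]
                break
        else:
            break

    entries = []
    prev_frontier = None
    for r in ordered:
        st = status[id(r)]
        icer = None
        if st == "frontier" and prev_frontier is not None:
            icer = _segment_icer(prev_frontier, r)
        if st == "frontier":
            prev_frontier = r
        entries.append(FrontierEntry(result=r, status=st, icer=icer))
    return Frontier(entries=tuple(entries))
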