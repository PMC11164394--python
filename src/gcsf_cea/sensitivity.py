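"""Scenario analyses, one-way sensitivity, threshold search, and PSA.

One-way sensitivity recomputes the ICER of a strategy comparison at each
parameter's range endpoints (tornado).  The threshold search finds the
parameter value at which an ICER crosses a willingness-to-pay target by
root finding.  The probabilistic sensitivity analysis (PSA) redraws every
uncertain parameter from its fitted distribution — beta or gamma by method
of moments with SE = (high - low)/3.92, log-normal with meanlog = ln(base)
and sdlog = (ln high - ln low)/3.92, prices held fixed — evaluates all
strategies per draw, and summarises the frequency with which each strategy
maximises net monetary benefit over a willingness-to-pay grid
(cost-effectiveness acceptability curves, CEAC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .cea import StrategyResult, Frontier, build_frontier, evaluate_strategies
from .parameters import (
    ParameterError,
    ParameterSet,
    Strategy,
    base_strategies,
    scenario2_strategies,
)
from .survival import LifeTable

__all__ = [
    "DistributionSpec",
    "TornadoEntry",
    "CEACData",
    "build_distributions",
    "sample_psa",
    "run_psa",
    "one_way",
    "run_tornado",
    "threshold_search",
    "solve_threshold",
    "run_scenario",
    "default_wtp_grid",
]


class DistributionFitError(ParameterError):
    """Raised when a parameter's (base, low, high) admit no valid fit."""


class NoCrossingError(RuntimeError):
    """Raised when the ICER does not cross the target within the bracket."""


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted PSA sampling distribution for one parameter."""

    name: str
    family: str  # beta | gamma | lognormal | fixed
    base: float
    args: tuple[float, ...] = ()

    @classmethod
    def fit(cls, name: str, family: str, base: float,
            low: float | None, high: float | None) -> "DistributionSpec":
        if family == "fixed":
            return cls(name, "fixed", base)
        if low is None or high is None:
            raise DistributionFitError(f"{name}: range required for {family} fit")
        if family == "lognormal":
            if base <= 0 or low <= 0:
                raise DistributionFitError(f"{name}: log-normal needs positive values")
            sdlog = (np.log(high) - np.log(low)) / 3.92
            return cls(name, "lognormal", base, (np.log(base), sdlog))
        se = (high - low) / 3.92
        var = se * se
        if family == "beta":
            if var >= base * (1 - base):
                raise DistributionFitError(
                    f"{name}: SE^2 >= p(1-p), beta moments infeasible"
                )
            nu = base * (1 - base) / var - 1.0
            return cls(name, "beta", base, (base * nu, (1 - base) * nu))
        if family == "gamma":
            if base <= 0:
                raise DistributionFitError(f"{name}: gamma needs a positive mean")
            return cls(name, "gamma", base, (base * base / var, var / base))
        raise DistributionFitError(f"{name}: unknown family {family!r}")

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "fixed":
            return self.base if size is None else np.full(size, self.base)
        if self.family == "beta":
            return rng.beta(*self.args, size=size)
        if self.family == "gamma":
            return rng.gamma(self.args[0], self.args[1], size=size)
        return rng.lognormal(self.args[0], self.args[1], size=size)


def build_distributions(params: ParameterSet) -> dict[str, DistributionSpec]:
    """Fit a sampling distribution for every parameter with a PSA family."""
    specs = {}
    for name, family in params.dist_family.items():
        base = params.value_of(name)
        low, high = params.ranges.get(name, (None, None))
        specs[name] = DistributionSpec.fit(name, family, base, low, high)
    return specs


def sample_psa(
    params: ParameterSet,
    rng: np.random.Generator,
    specs: dict[str, DistributionSpec] | None = None,
) -> ParameterSet:
    """One second-order Monte Carlo draw of the parameter set.

    Parameters are drawn independently; fixed parameters (drug prices, the
    discount rate) keep their base values.  Draw order is the sorted
    parameter-name order, so results are reproducible for a given seed.
    """
    if specs is None:
        specs = build_distributions(params)
    out = params
    for name in sorted(specs):
        spec = specs[name]
        if spec.family == "fixed":
            continue
        out = out.with_value(name, float(spec.sample(rng)))
    return out


def default_wtp_grid(params: ParameterSet, step: float = 10_000.0) -> np.ndarray:
    """0 to 1.5x the WTP threshold (1x GDP per capita) in NT$10,000 steps."""
    top = 1.5 * params.wtp
    return np.arange(0.0, top + step, step)


@dataclass(frozen=True)
class CEACData:
    """Cost-effectiveness acceptability curves from a PSA run."""

    wtp: np.ndarray
    strategies: tuple[str, ...]  # labels, column order of `probabilities`
    probabilities: np.ndarray  # shape (len(wtp), len(strategies)), rows sum to 1
    n_iter: int

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: one row per (wtp, strategy)."""
        rows = []
        for i, w in enumerate(self.wtp):
            for j, s in enumerate(self.strategies):
                rows.append({"wtp": w, "strategy": s,
                             "probability": self.probabilities[i, j]})
        return pd.DataFrame(rows)


def run_psa(
    strategies: list[Strategy],
    params: ParameterSet,
    life_table: LifeTable,
    n_iter: int = 10_000,
    seed: int = 0,
    wtp_grid: np.ndarray | None = None,
    scenario1: bool = False,
) -> CEACData:
    """Probabilistic sensitivity analysis with CEAC summary.

    Per iteration: draw a parameter set, evaluate every strategy, and record
    which maximises net monetary benefit at each willingness-to-pay value.
    Probabilities are frequencies over iterations; deterministic given the
    seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    if wtp_grid is None:
        wtp_grid = default_wtp_grid(params)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    rng = np.random.default_rng(seed)
    specs = build_distributions(params)
    counts = np.zeros((len(wtp_grid), len(strategies)), dtype=np.int64)
    for _ in range(n_iter):
        draw = sample_psa(params, rng, specs)
        results = evaluate_strategies(strategies, draw, life_table, scenario1)
        costs = np.array([r.total_cost for r in results])
        qalys = np.array([r.total_qalys for r in results])
        nmb = np.outer(wtp_grid, qalys) - costs[None, :]
        counts[np.arange(len(wtp_grid)), np.argmax(nmb, axis=1)] += 1
    return CEACData(
        wtp=wtp_grid,
        strategies=tuple(s.label for s in strategies),
        probabilities=counts / n_iter,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# one-way sensitivity and threshold analysis


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    icer_at_low: float
    icer_at_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _pairwise_icer(
    strategy_a: Strategy,
    strategy_b: Strategy,
    params: ParameterSet,
    life_table: LifeTable,
    scenario1: bool = False,
) -> float:
    res = evaluate_strategies([strategy_a, strategy_b], params, life_table, scenario1)
    dq = res[0].total_qalys - res[1].total_qalys
    dc = res[0].total_cost - res[1].total_cost
    return dc / dq


def one_way(
    parameter: str,
    comparison: tuple[Strategy, Strategy],
    params: ParameterSet,
    life_table: LifeTable,
) -> TornadoEntry:
    """ICER of A vs B at a parameter's range endpoints, all else at base."""
    if parameter not in params.ranges:
        raise ParameterError(f"parameter {parameter!r} has no sensitivity range")
    low, high = params.ranges[parameter]
    a, b = comparison
    return TornadoEntry(
        parameter=parameter,
        icer_at_low=_pairwise_icer(a, b, params.with_value(parameter, low), life_table),
        icer_at_high=_pairwise_icer(a, b, params.with_value(parameter, high), life_table),
    )


def run_tornado(
    comparison: tuple[Strategy, Strategy],
    params: ParameterSet,
    life_table: LifeTable,
    parameters: list[str] | None = None,
) -> list[TornadoEntry]:
    """One-way entries for every ranged parameter, sorted by descending span."""
    names = parameters if parameters is not None else sorted(params.ranges)
    entries = [one_way(n, comparison, params, life_table) for n in names]
    return sorted(entries, key=lambda e: e.span, reverse=True)


def solve_threshold(
    icer_fn,
    target_icer: float,
    bracket: tuple[float, float],
    tol: float = 1.0,
) -> float:
    """Root-find the parameter value where ``icer_fn`` equals the target.

    ``icer_fn`` must be monotone over the bracket.  Raises
    :class:`NoCrossingError` when the ICER minus target does not change sign
    across the bracket.  The returned value satisfies
    ``|icer_fn(x) - target| < tol`` (default NT$1/QALY).
    """
    lo, hi = bracket
    f_lo = icer_fn(lo) - target_icer
    f_hi = icer_fn(hi) - target_icer
    if f_lo == 0:
        return lo
    if f_hi == 0:
        return hi
    if np.sign(f_lo) == np.sign(f_hi):
        raise NoCrossingError(
            f"ICER - target has no sign change over [{lo}, {hi}]"
        )
    root = optimize.brentq(lambda x: icer_fn(x) - target_icer, lo, hi, xtol=1e-12)
    if abs(icer_fn(root) - target_icer) >= tol:
        raise NoCrossingError("root finding did not reach the ICER tolerance")
    return float(root)


def threshold_search(
    parameter: str,
    comparison: tuple[Strategy, Strategy],
    target_icer: float,
    params: ParameterSet,
    life_table: LifeTable,
    bracket: tuple[float, float] | None = None,
) -> float:
    """Parameter value at which the comparison's ICER crosses the target."""
    if bracket is None:
        if parameter not in params.ranges:
            raise ParameterError(
                f"parameter {parameter!r} has no range; supply a bracket"
            )
        bracket = params.ranges[parameter]
    a, b = comparison

    def icer_fn(x: float) -> float:
        return _pairwise_icer(a, b, params.with_value(parameter, x), life_table)

    return solve_threshold(icer_fn, target_icer, bracket)


# ---------------------------------------------------------------------------
# scenarios


def run_scenario(which: int, params: ParameterSet, life_table: LifeTable) -> Frontier:
    """Scenario analyses over the base strategy catalogue.

    Scenario 1 assumes G-CSF has no impact on long-term survival: the
    RDI→mortality link is severed, so both RDI strata face baseline
    mortality.  Scenario 2 adds the filgrastim and pegfilgrastim biosimilars
    (same effectiveness as their reference products, lower price).
    """
    if which == 1:
        results = evaluate_strategies(base_strategies(), params, life_table, scenario1=True)
    elif which == 2:
        results = evaluate_strategies(scenario2_strategies(), params, life_table)
    else:
        raise ValueError("scenario must be 1 or 2")
    return build_frontier(results)
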