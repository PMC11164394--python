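"""Synthetic inputs: a calibrated female life table and claims-like cohorts.

The decision model needs two external inputs that cannot ship with the
package: a national female life table and the individual-level
chemotherapy-cycle records from which the short-acting G-CSF relative risks
were estimated.  This module generates statistically faithful stand-ins:

* :func:`make_life_table` builds a Gompertz mortality schedule calibrated so
  that residual life expectancy at the cohort entry age matches a target
  (default 29.0 years at age 56, approximating a Taiwanese woman of that
  age).  The packaged ``life_table_synthetic.csv`` is this function's output
  at its defaults.
* :func:`simulate_cohort` draws per-patient, per-cycle febrile-neutropenia
  (FN) events from the same multiplicative risk model the cohort engine
  uses, including the secondary-prophylaxis trigger and FN-death truncation,
  producing a record table shaped like a per-cycle claims extraction.
* :func:`estimate_rr` re-estimates a drug's FN relative risk from such
  records, stratified by cycle tier, as a claims analysis would.

The generator emulates the risk structure only — not claims-format realism
(diagnosis codes, visit records) or regimen-level heterogeneity.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .parameters import ParameterSet, Strategy
from .survival import LifeTable

__all__ = ["make_life_table", "simulate_cohort", "estimate_rr", "EstimationError"]


class EstimationError(ValueError):
    """Raised when a relative risk is not estimable from the records."""


def _life_expectancy(qx: np.ndarray) -> float:
    """Residual life expectancy with half-cycle-corrected person-years."""
    s = np.concatenate([[1.0], np.cumprod(1.0 - qx)])
    return float(np.sum(0.5 * (s[:-1] + s[1:])))


def make_life_table(
    start_age: int = 56,
    age_cap: int = 110,
    target_e0: float = 29.0,
    b: float = 0.095,
) -> LifeTable:
    """Gompertz life table calibrated to a target residual life expectancy.

    The annual death probability is qx = min(1, a * exp(b * (age -
    start_age))) with the slope ``b`` fixed and the level ``a`` found by
    root finding so that life expectancy at ``start_age`` equals
    ``target_e0``; qx at ``age_cap`` is forced to 1 so the cohort reaches
    the dead state in finite cycles.  Deterministic (no randomness).
    """
    ages = np.arange(start_age, age_cap + 1)

    def qx_for(a: float) -> np.ndarray:
        qx = np.minimum(1.0, a * np.exp(b * (ages - start_age)))
        qx[-1] = 1.0
        return qx

    def gap(a: float) -> float:
        return _life_expectancy(qx_for(a)) - target_e0

    lo, hi = 1e-9, 1.0
    g_lo, g_hi = gap(lo), gap(hi)
    if g_hi == 0:
        return LifeTable(ages=ages, qx=qx_for(hi))
    if np.sign(g_lo) == np.sign(g_hi):
        raise ValueError(
            f"target_e0={target_e0} not achievable on ages "
            f"[{start_age}, {age_cap}] with b={b}"
        )
    a = optimize.brentq(gap, lo, hi, xtol=1e-14)
    return LifeTable(ages=ages, qx=qx_for(a))


def _resolve_assignment(
    n_patients: int,
    assignment: Strategy | Sequence[Strategy] | Mapping[int, Strategy],
) -> list[Strategy]:
    if isinstance(assignment, Strategy):
        return [assignment] * n_patients
    if isinstance(assignment, Mapping):
        return [assignment[i] for i in range(n_patients)]
    assignment = list(assignment)
    if len(assignment) != n_patients:
        raise ValueError("assignment length must equal n_patients")
    return assignment


def simulate_cohort(
    n_patients: int,
    assignment: Strategy | Sequence[Strategy] | Mapping[int, Strategy],
    params: ParameterSet,
    seed: int = 0,
    drop_fraction: float = 0.0,
) -> pd.DataFrame:
    """Simulate per-cycle FN records for a cohort under assigned strategies.

    Each alive patient contributes one record per cycle with columns
    ``patient``, ``cycle``, ``drug`` (empty when unexposed), ``exposed``,
    ``fn_event``, ``died_of_fn`` and ``fn_history`` (status at cycle start).
    FN events are Bernoulli draws from the engine's multiplicative risk
    model; secondary-prophylaxis exposure starts the cycle after a first FN;
    FN deaths truncate a patient's records.  ``drop_fraction`` removes
    records uniformly at random, a stand-in for claims exclusion filters
    whose selective structure is unknown.  Deterministic given ``seed``.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError("drop_fraction must lie in [0, 1)")
    strategies = _resolve_assignment(n_patients, assignment)
    rng = np.random.default_rng(seed)

    groups: dict[str, list[int]] = {}
    by_id: dict[str, Strategy] = {}
    for pid, strat in enumerate(strategies):
        groups.setdefault(strat.id, []).append(pid)
        by_id[strat.id] = strat

    frames = []
    for sid in sorted(groups):
        strat = by_id[sid]
        pids = np.asarray(groups[sid])
        n = len(pids)
        alive = np.ones(n, dtype=bool)
        hist = np.zeros(n, dtype=bool)
        if strat.mode == "none":
            rr12 = rr3 = 1.0
        else:
            rr12, rr3 = params.drug_rr_tiers(strat.drug)
        for cycle in range(1, params.n_cycles + 1):
            sel = alive.copy()
            if not sel.any():
                break
            if strat.mode == "primary":
                exposed = sel
            elif strat.mode == "secondary":
                exposed = sel & hist
            else:
                exposed = np.zeros(n, dtype=bool)
            tier = rr12 if cycle <= 2 else rr3
            p = np.full(n, params.p_fn_cycle1)
            if cycle >= 2:
                p *= params.rr_cycle2plus
            p = np.where(hist, p * params.rr_history, p)
            p = np.minimum(1.0, np.where(exposed, p * tier, p))
            fn = sel & (rng.random(n) < p)
            died = fn & (rng.random(n) < params.p_fn_death)
            frames.append(
                pd.DataFrame(
                    {
                        "patient": pids[sel],
                        "cycle": cycle,
                        "drug": np.where(exposed[sel], strat.drug or "", ""),
                        "exposed": exposed[sel],
                        "fn_event": fn[sel],
                        "died_of_fn": died[sel],
                        "fn_history": hist[sel],
                    }
                )
            )
            hist = hist | (fn & ~died)
            alive = alive & ~died
    records = pd.concat(frames, ignore_index=True)
    records = records.sort_values(["patient", "cycle"], kind="stable").reset_index(drop=True)
    if drop_fraction > 0.0:
        keep = rng.random(len(records)) >= drop_fraction
        records = records.loc[keep].reset_index(drop=True)
    return records


_STRATA = {"1-2": (1, 2), "3+": (3, 4, 5, 6)}


def _history_column(records: pd.DataFrame) -> pd.Series:
    """FN history at cycle start, reconstructed from each patient's records."""
    rec = records.sort_values(["patient", "cycle"], kind="stable")
    prior = rec.groupby("patient")["fn_event"].cumsum() - rec["fn_event"]
    return (prior > 0).reindex(records.index)


def estimate_rr(
    records: pd.DataFrame,
    drug: str,
    cycle_stratum: str | Iterable[int],
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """Relative risk of FN for a drug vs no prophylaxis in a cycle stratum.

    ``cycle_stratum`` is ``"1-2"``, ``"3+"`` or an explicit cycle list.
    Exposure to the drug is compared with unexposed cycles via a
    Mantel–Haenszel ratio of incidence proportions stratified by (cycle,
    FN history); FN history is a strong risk factor correlated with
    exposure through the attrition and trigger dynamics, so the crude ratio
    would be confounded.  The CI is a log-scale Wald interval whose variance
    comes from a patient-clustered linearisation of the ratio: a patient's
    early FN outcome both contributes events and reassigns their later
    history strata, so stratum counts are cross-correlated and the classical
    independent-strata (Greenland–Robins) variance undercovers on these
    records.  Influence contributions are summed per patient and centred
    within the ever-exposed / never-exposed patient groups; patients with no
    record in the stratum (e.g. dead earlier) count as zero contributions.
    """
    cycles = _STRATA.get(cycle_stratum, cycle_stratum) if isinstance(
        cycle_stratum, str
    ) else tuple(cycle_stratum)
    if isinstance(cycles, str):
        raise ValueError(f"unknown cycle stratum {cycle_stratum!r}")
    records = records.copy()
    if "fn_history" not in records.columns:
        records["fn_history"] = _history_column(records)
    sub = records[records["cycle"].isin(cycles)]
    keep = (sub["exposed"] & (sub["drug"] == drug)) | ~sub["exposed"]
    sub = sub[keep]
    if sub["exposed"].sum() == 0 or (~sub["exposed"]).sum() == 0:
        raise EstimationError("both exposure groups must be non-empty in the stratum")

    stratum = pd.factorize(
        sub["cycle"].astype(str) + "|" + sub["fn_history"].astype(str)
    )[0]
    df = pd.DataFrame(
        {
            "e": sub["exposed"].to_numpy(),
            "fn": sub["fn_event"].to_numpy().astype(float),
            "s": stratum,
            "pid": sub["patient"].to_numpy(),
        }
    )
    by_stratum = df.groupby("s")["e"]
    n1 = by_stratum.sum()
    n_tot = by_stratum.count()
    n0 = n_tot - n1
    # Mantel-Haenszel weights: exposed events weighted by the unexposed
    # share of the stratum and vice versa
    df["u"] = np.where(df["e"], df["fn"] * df["s"].map(n0 / n_tot), 0.0)
    df["v"] = np.where(~df["e"], df["fn"] * df["s"].map(n1 / n_tot), 0.0)
    per_patient = df.groupby("pid")[["u", "v"]].sum()
    ever_exposed = (
        (records["exposed"] & (records["drug"] == drug))
        .groupby(records["patient"])
        .any()
    )
    per_patient = per_patient.reindex(ever_exposed.index, fill_value=0.0)
    num, den = per_patient["u"].sum(), per_patient["v"].sum()
    if den == 0:
        raise EstimationError("no FN events in the unexposed group: RR undefined")
    if num == 0:
        raise EstimationError("no FN events in the exposed group: RR undefined")
    rr = num / den

    psi = per_patient["u"] - rr * per_patient["v"]
    var = 0.0
    for group in (True, False):
        x = psi[ever_exposed == group]
        var += float(((x - x.mean()) ** 2).sum())
    se_log = np.sqrt(var) / num

    from scipy import stats

    z = stats.norm.ppf(1 - alpha / 2)
    lo, hi = rr * np.exp(-z * se_log), rr * np.exp(z * se_log)
    return float(rr), (float(lo), float(hi))
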