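"""Exact expected-value evaluation of the six-cycle chemotherapy phase.

The cohort starts a 6-cycle, 21-day-cycle regimen with a high baseline risk
of febrile neutropenia (FN).  In each cycle an alive patient either has an FN
event or not; an FN event is fatal with probability ``p_fn_death``, and FN
survivors carry an FN history that raises their subsequent FN risk and their
probability of a reduced relative dose intensity (RDI < 85%).  The phase is
evaluated exactly as an expectation over the event tree — three alive/dead
states with cohort masses — rather than by microsimulation, so the outputs
are deterministic.

Event timing convention: FN and FN death resolve at cycle end.  A patient who
dies of FN in cycle k still accrues that cycle's prophylaxis cost, the FN
event cost, and the cycle's chemotherapy QALY less the FN hospitalisation
decrement; from the next cycle on they contribute nothing.  Fatal FN events
incur the full FN event cost.  At most one FN event can occur per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .parameters import ParameterSet, Strategy, convert_or_to_rr

DAYS_PER_YEAR = 365.25

__all__ = ["ChemoOutcome", "fn_probability", "drug_rr_for", "run_chemo_phase", "classify_rdi"]


@dataclass(frozen=True)
class ChemoOutcome:
    """Expected outcomes of the chemotherapy phase for one strategy.

    Cohort fractions (``expected_fn_deaths``, ``survivors_with_history``,
    ``survivors_without_history``) sum to 1; ``expected_fn_events`` is an
    expected count per patient and may exceed 1.  Costs are in NTD per
    patient; ``qaly_chemo`` is undiscounted (the phase ends within year 1).
    """

    strategy: Strategy
    expected_fn_events: float
    expected_fn_deaths: float
    expected_injections: Mapping[str, float] = field(default_factory=dict)
    cost_drug: float = 0.0
    cost_fn: float = 0.0
    qaly_chemo: float = 0.0
    survivors_with_history: float = 0.0
    survivors_without_history: float = 0.0

    @property
    def total_cost(self) -> float:
        return self.cost_drug + self.cost_fn


def fn_probability(
    cycle: int, has_history: bool, drug_rr: float, params: ParameterSet
) -> float:
    """Per-cycle FN probability from the multiplicative risk model.

    Baseline first-cycle risk is multiplied by the cycles-2+ relative risk
    for later cycles, the FN-history relative risk for patients with a prior
    FN, and the prophylaxis relative risk (1.0 when untreated).  The product
    is capped at 1.
    """
    if drug_rr < 0:
        raise ValueError("drug relative risk must be non-negative")
    if not 1 <= cycle <= params.n_cycles:
        raise ValueError(f"cycle must be in 1..{params.n_cycles}")
    p = params.p_fn_cycle1 * drug_rr
    if cycle >= 2:
        p *= params.rr_cycle2plus
    if has_history:
        p *= params.rr_history
    return min(1.0, p)


def drug_rr_for(
    strategy: Strategy, cycle: int, has_history: bool, params: ParameterSet
) -> float:
    """Effective prophylaxis relative risk for a state in a given cycle.

    No prophylaxis → 1.0.  Primary prophylaxis applies the drug's cycles-1–2
    tier in cycles 1–2 and the cycles-3+ tier afterwards (tiers are indexed
    by chemotherapy cycle number).  Secondary prophylaxis is untreated until
    an FN history exists, then follows the same cycle-number tiering.
    """
    if strategy.mode == "none":
        return 1.0
    if strategy.mode == "secondary" and not has_history:
        return 1.0
    rr12, rr3plus = params.drug_rr_tiers(strategy.drug)
    return rr12 if cycle <= 2 else rr3plus


def _receives_drug(strategy: Strategy, has_history: bool) -> bool:
    if strategy.mode == "primary":
        return True
    if strategy.mode == "secondary":
        return has_history
    return False


def run_chemo_phase(strategy: Strategy, params: ParameterSet) -> ChemoOutcome:
    """Evaluate the chemotherapy phase exactly for one strategy.

    Tracks cohort masses over the three live states (alive without FN
    history, alive with FN history) plus the absorbing dead state, cycle by
    cycle, accruing expected FN events and deaths, G-CSF injections and
    costs, FN event costs, and chemotherapy-phase QALYs.
    """
    m_no_hist, m_hist = 1.0, 0.0
    events = deaths = injections = cost_drug = qalys = 0.0
    q_cycle = params.u_chemo * params.cycle_days / DAYS_PER_YEAR
    q_fn_loss = params.u_fn_decrement * params.los_fn / DAYS_PER_YEAR

    drug = params.drugs[strategy.drug] if strategy.drug else None

    for cycle in range(1, params.n_cycles + 1):
        alive = m_no_hist + m_hist
        qalys += alive * q_cycle

        # prophylaxis administered at cycle start to eligible alive patients
        if drug is not None:
            treated = (m_no_hist + m_hist) if strategy.mode == "primary" else (
                m_hist if strategy.mode == "secondary" else 0.0
            )
            n_inj = treated * drug.injections_per_cycle
            injections += n_inj
            cost_drug += n_inj * drug.price

        p_no = fn_probability(
            cycle, False, drug_rr_for(strategy, cycle, False, params), params
        )
        p_hist = fn_probability(
            cycle, True, drug_rr_for(strategy, cycle, True, params), params
        )

        e = m_no_hist * p_no + m_hist * p_hist
        events += e
        deaths += e * params.p_fn_death
        qalys -= e * q_fn_loss

        # FN survivors carry history; the dead state absorbs
        surv = 1.0 - params.p_fn_death
        m_no_hist, m_hist = (
            m_no_hist * (1.0 - p_no),
            m_no_hist * p_no * surv + m_hist * (1.0 - p_hist) + m_hist * p_hist * surv,
        )

    out = ChemoOutcome(
        strategy=strategy,
        expected_fn_events=events,
        expected_fn_deaths=deaths,
        expected_injections={strategy.drug: injections} if strategy.drug else {},
        cost_drug=cost_drug,
        cost_fn=events * params.cost_fn_event,
        qaly_chemo=qalys,
        survivors_with_history=m_hist,
        survivors_without_history=m_no_hist,
    )
    total = out.survivors_with_history + out.survivors_without_history + out.expected_fn_deaths
    assert abs(total - 1.0) < 1e-12, "cohort mass not conserved"
    return out


def classify_rdi(outcome: ChemoOutcome, params: ParameterSet) -> dict[bool, float]:
    """Probability of reduced dose intensity (RDI < 85%) per history stratum.

    Survivors without FN history face the baseline probability; for
    survivors with a history the odds ratio for reduced RDI is converted to
    a risk ratio at that baseline and applied multiplicatively (capped at 1).
    Keyed by ``has_history``.
    """
    base = params.p_rdi_low_base
    rr = convert_or_to_rr(params.or_rdi_low, base)
    return {False: base, True: min(1.0, base * rr)}
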