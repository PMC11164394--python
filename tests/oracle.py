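"""Independent brute-force oracle for the chemotherapy phase.

Enumerates every event path through the six cycles (no FN / FN-survive /
FN-die per cycle, with the dead state absorbing) and accumulates
probability-weighted outcomes.  Shares no code with the expectation engine:
transition probabilities, costs and QALYs are recomputed here from the
parameter values directly.
"""

from dataclasses import dataclass, field


@dataclass
class Tally:
    events: float = 0.0
    deaths: float = 0.0
    injections: float = 0.0
    cost_drug: float = 0.0
    cost_fn: float = 0.0
    qalys: float = 0.0
    surv_hist: float = 0.0
    surv_no_hist: float = 0.0
    paths: int = 0


def enumerate_chemo_paths(strategy, params) -> Tally:
    year = 365.25
    q_cycle = params.u_chemo * params.cycle_days / year
    q_fn = params.u_fn_decrement * params.los_fn / year
    drug = params.drugs[strategy.drug] if strategy.drug else None
    if drug is not None:
        rr12, rr3 = params.drug_rr_tiers(strategy.drug)

    tally = Tally()

    def step(cycle, hist, prob, events, inj, c_drug, c_fn, qaly):
        if cycle > params.n_cycles:
            tally.events += prob * events
            tally.injections += prob * inj
            tally.cost_drug += prob * c_drug
            tally.cost_fn += prob * c_fn
            tally.qalys += prob * qaly
            if hist:
                tally.surv_hist += prob
            else:
                tally.surv_no_hist += prob
            tally.paths += 1
            return
        treated = strategy.mode == "primary" or (strategy.mode == "secondary" and hist)
        if treated:
            inj = inj + drug.injections_per_cycle
            c_drug = c_drug + drug.injections_per_cycle * drug.price
        p = params.p_fn_cycle1
        if cycle >= 2:
            p = p * params.rr_cycle2plus
        if hist:
            p = p * params.rr_history
        if treated:
            p = p * (rr12 if cycle <= 2 else rr3)
        p = min(1.0, p)
        qaly = qaly + q_cycle
        # no FN
        step(cycle + 1, hist, prob * (1 - p), events, inj, c_drug, c_fn, qaly)
        # FN, survive
        step(
            cycle + 1,
            True,
            prob * p * (1 - params.p_fn_death),
            events + 1,
            inj,
            c_drug,
            c_fn + params.cost_fn_event,
            qaly - q_fn,
        )
        # FN, die at cycle end: accrue this cycle's costs/QALYs, then nothing
        dp = prob * p * params.p_fn_death
        tally.events += dp * (events + 1)
        tally.deaths += dp
        tally.injections += dp * inj
        tally.cost_drug += dp * c_drug
        tally.cost_fn += dp * (c_fn + params.cost_fn_event)
        tally.qalys += dp * (qaly - q_fn)
        tally.paths += 1

    step(1, False, 1.0, 0, 0.0, 0.0, 0.0, 0.0)
    return tally
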