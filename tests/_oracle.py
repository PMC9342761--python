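"""Brute-force path-enumeration oracle for small cohort models.

Enumerates every state path of a fixed-horizon run, weighting each
path's accruals by its probability.  Exponential in the horizon, so
only usable for a handful of states and cycles — which is the point:
it shares no code path with the matrix-propagation engine.
"""

from __future__ import annotations


def path_enumeration_accruals(model, horizon: int, discount_rate: float):
    """Probability-weighted accruals over all state paths.

    Returns a dict with qaly_disc/qaly_undisc/cost_disc/cost_undisc,
    matching the engine's conventions: start-of-cycle accrual, entry
    costs charged at arrival cycles (entrants arriving exactly at the
    horizon are dropped), occupancy-fraction pro-rating.
    """
    states = model.states
    n = len(states)
    occ = model.occupancy
    totals = {"qaly_disc": 0.0, "qaly_undisc": 0.0,
              "cost_disc": 0.0, "cost_undisc": 0.0}

    def df(cycle: int) -> float:
        return (1.0 + discount_rate) ** (-cycle / 12.0)

    def recurse(idx, t, prob):
        u = model.utility(states[idx], t) * occ[idx] / 12.0
        c = model.running_cost(states[idx], t) * occ[idx]
        if t == 0:
            c += model.entry_cost(states[idx], 0)
        totals["qaly_disc"] += prob * u * df(t)
        totals["qaly_undisc"] += prob * u
        totals["cost_disc"] += prob * c * df(t)
        totals["cost_undisc"] += prob * c
        if t + 1 == horizon:
            return
        mat = model.transition(t)
        for j in range(n):
            p_ij = mat[idx, j]
            if p_ij == 0.0:
                continue
            if j != idx and t + 1 < horizon:
                entry = model.entry_cost(states[j], t + 1)
                if entry:
                    totals["cost_disc"] += prob * p_ij * entry * df(t + 1)
                    totals["cost_undisc"] += prob * p_ij * entry
            recurse(j, t + 1, prob * p_ij)

    for idx in range(n):
        p0 = model.initial[idx]
        if p0 > 0.0:
            recurse(idx, 0, p0)
    return totals
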