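"""Builders for the four strategy models.

Model 1 (destination therapy, DT)
    * control: standard medical management — states {MedTx, Death}.
    * intervention: centrifugal-flow pump as permanent support — states
      {PumpStable, PumpComplication, Death}.

Model 2 (bridge to transplant, BTT)
    * control: waiting list on medical treatment, then transplant —
      states {WaitMedTx, WaitMedTxFrac, TransplantSurgery, PostTx, Death}.
    * intervention: pump implant, waiting list with the pump, then
      transplant — the same tail plus the pump complication state.

Conventions
-----------
* Death competes first within a cycle; complication entry applies to
  the survivor mass and is capped at ``1 - p_death``.
* All active complication types are pooled into a single one-cycle
  complication state whose utility and one-time episode cost are the
  incidence-weighted mixtures of the types active that month.  The
  ventricular-arrhythmia entry is a disutility decrement applied to the
  concurrent pump utility rather than an absolute utility.
* Post-transplant complications (constant monthly rates) do not get an
  explicit state: they adjust the post-transplant utility and monthly
  cost by their expected value each cycle.
* Fractional waiting times W are modelled as floor(W) full tunnel
  cycles plus one fractional cycle with occupancy fraction frac(W) and
  death probability ``1 - (1 - p) ** frac(W)``; transplant surgery
  occupies the following cycle.
* Mortality on the control waiting list is the medical-management
  monthly mortality; patients on the urgent list are costed as
  hospitalized medical treatment, pump carriers as outpatient waiting.
"""

from __future__ import annotations

import math

import numpy as np

from .engine import StrategyModel
from .errors import ModelError
from .parameters import CostTable, ParameterSet

__all__ = [
    "build_dt_control",
    "build_dt_intervention",
    "build_btt_control",
    "build_btt_intervention",
    "build_pair",
    "pump_complication_mixture",
    "post_transplant_adjustments",
]

_FRAC_EPS = 1e-9


def pump_complication_mixture(
    params: ParameterSet, costs: CostTable, month: int
) -> tuple[float, float, float]:
    """(total entry rate, mixture utility, mixture episode cost) at a month.

    The mixture utility weighs each active complication's utility by its
    incidence; the arrhythmia disutility contributes the concurrent pump
    utility plus the decrement.  The concurrent pump utility is the
    post-first-month value because the complication state is never
    occupied during the implant month itself.
    """
    total = 0.0
    u_acc = 0.0
    c_acc = 0.0
    base_u = params.u_pump_after.base
    for spec in params.pump_complications:
        r = spec.rate.at(month)
        if r == 0.0:
            continue
        u = base_u + spec.utility.base if spec.utility.disutility else spec.utility.base
        total += r
        u_acc += r * u
        c_acc += r * costs.episode_cost(spec.cost_key)
    if total == 0.0:
        return 0.0, base_u, 0.0
    if total > 1.0:
        raise ModelError(
            f"pump complication rates sum to {total:.4f} > 1 at month {month}"
        )
    return total, u_acc / total, c_acc / total


def post_transplant_adjustments(
    params: ParameterSet, costs: CostTable
) -> tuple[float, float]:
    """Expected-value utility and monthly cost add-on of the post-transplant
    state, folding in the constant monthly transplant-complication rates."""
    u_stable = params.u_stable_ht.base
    total = 0.0
    u_acc = 0.0
    cost_add = 0.0
    for spec in params.ht_complications:
        r = spec.rate.at(1)
        u = u_stable + spec.utility.base if spec.utility.disutility else spec.utility.base
        total += r
        u_acc += r * u
        cost_add += r * costs.episode_cost(spec.cost_key)
    if total > 1.0:
        raise ModelError(f"transplant complication rates sum to {total:.4f} > 1")
    utility = (1.0 - total) * u_stable + u_acc
    monthly_cost = costs.monthly["post_transplant"] + cost_add
    return utility, monthly_cost


def _split_wait(months: float) -> tuple[int, float]:
    """Whole tunnel cycles and the fractional remainder of a waiting time."""
    if months < 0:
        raise ModelError(f"waiting time must be >= 0, got {months}")
    n_full = int(math.floor(months + _FRAC_EPS))
    frac = months - n_full
    if frac < _FRAC_EPS:
        frac = 0.0
    return n_full, frac


# ---------------------------------------------------------------------------
# Model 1 — destination therapy


def build_dt_control(params: ParameterSet, costs: CostTable) -> StrategyModel:
    """Standard medical management: stay in MedTx or die.

    The monthly cost blends inotrope-dependent hospitalization (a fixed
    fraction of surviving time) with outpatient follow-up.
    """
    p = params.p_death_medtx.base
    u = params.u_medtx.base
    hf = params.hosp_fraction_medtx
    monthly = (
        hf * costs.monthly["medtx_hospitalized"]
        + (1.0 - hf) * costs.monthly["medtx_outpatient"]
    )
    states = ("MedTx", "Death")
    mat = np.array([[1.0 - p, p], [0.0, 1.0]])
    return StrategyModel(
        name="medical_management",
        states=states,
        initial=[1.0, 0.0],
        transition=lambda t: mat,
        utility=lambda s, t: u if s == "MedTx" else 0.0,
        running_cost=lambda s, t: monthly if s == "MedTx" else 0.0,
        stationary_from=0,
        metadata={"model": "DT", "mean_age": params.mean_age_dt,
                  "perspective": costs.perspective},
    )


def build_dt_intervention(params: ParameterSet, costs: CostTable) -> StrategyModel:
    """Centrifugal-flow pump as destination therapy.

    Device price and implantation are charged at cycle 0.  Per cycle,
    pump mortality (a step schedule in months since implant) competes
    first; survivors enter the pooled one-cycle complication state with
    the summed incidence of the active complication types, capped at the
    survivor mass.
    """
    mort = params.pump_mortality
    u_first = params.u_pump_first_month.base
    u_after = params.u_pump_after.base
    pump_monthly = costs.monthly["pump_stable"]
    implant_cost = costs.device_price + costs.one_time["pump_implantation"]
    states = ("PumpStable", "PumpComplication", "Death")

    def transition(t: int) -> np.ndarray:
        month = t + 1
        p_d = mort.at(month)
        total, _, _ = pump_complication_mixture(params, costs, month)
        p_c = min(total, 1.0 - p_d)
        return np.array(
            [
                [1.0 - p_d - p_c, p_c, p_d],
                [1.0 - p_d, 0.0, p_d],
                [0.0, 0.0, 1.0],
            ]
        )

    def utility(state: str, t: int) -> float:
        if state == "PumpStable":
            return u_first if t == 0 else u_after
        if state == "PumpComplication":
            # occupied from cycle 1 on; weights follow the incidence of
            # the month the complication occurred (the previous cycle)
            _, u_mix, _ = pump_complication_mixture(params, costs, max(t, 1))
            return u_mix
        return 0.0

    def running_cost(state: str, t: int) -> float:
        return pump_monthly if state != "Death" else 0.0

    def entry_cost(state: str, t: int) -> float:
        if state == "PumpStable" and t == 0:
            return implant_cost
        if state == "PumpComplication":
            _, _, c_mix = pump_complication_mixture(params, costs, max(t, 1))
            return c_mix
        return 0.0

    return StrategyModel(
        name="pump_destination_therapy",
        states=states,
        initial=[1.0, 0.0, 0.0],
        transition=transition,
        utility=utility,
        running_cost=running_cost,
        entry_cost=entry_cost,
        stationary_from=mort.starts[-1] + 12,  # beyond the last tabulated month
        metadata={"model": "DT", "mean_age": params.mean_age_dt,
                  "perspective": costs.perspective},
    )


# ---------------------------------------------------------------------------
# Model 2 — bridge to transplant


def _transplant_tail(params: ParameterSet, costs: CostTable):
    """Shared transplant-surgery and post-transplant pieces."""
    p_periop = params.p_death_ht_periop.base
    p_post = params.p_death_post_ht.base
    u_post, c_post = post_transplant_adjustments(params, costs)
    return p_periop, p_post, u_post, c_post


def build_btt_control(params: ParameterSet, costs: CostTable) -> StrategyModel:
    """Direct transplantation: waiting list on medical treatment, then
    transplant surgery, then the post-transplant state."""
    p_wait = params.p_death_medtx.base
    u_wait = params.u_medtx.base
    wait = params.wait_ht.base
    n_full, frac = _split_wait(wait)
    p_periop, p_post, u_post, c_post = _transplant_tail(params, costs)
    # urgent-list patients are hospitalized inotrope-dependent
    c_wait = costs.monthly["medtx_hospitalized"]
    surgery_cost = costs.one_time["heart_transplant"]

    states = ("WaitMedTx", "WaitMedTxFrac", "TransplantSurgery", "PostTx", "Death")
    i_wait, i_frac, i_surg, i_post, i_death = range(5)
    frac_death = 1.0 - (1.0 - p_wait) ** frac if frac > 0 else 0.0
    surgery_cycle = n_full + (1 if frac > 0 else 0)

    def transition(t: int) -> np.ndarray:
        mat = np.zeros((5, 5))
        mat[i_death, i_death] = 1.0
        # waiting rows: destination depends on where the clock stands
        if frac > 0 and t == n_full - 1:
            wait_dest = i_frac
        elif t >= n_full - 1:
            wait_dest = i_surg
        else:
            wait_dest = i_wait
        mat[i_wait, wait_dest] += 1.0 - p_wait
        mat[i_wait, i_death] += p_wait
        mat[i_frac, i_surg] = 1.0 - frac_death
        mat[i_frac, i_death] = frac_death
        mat[i_surg, i_post] = 1.0 - p_periop
        mat[i_surg, i_death] = p_periop
        mat[i_post, i_post] = 1.0 - p_post
        mat[i_post, i_death] = p_post
        return mat

    utilities = {
        "WaitMedTx": u_wait,
        "WaitMedTxFrac": u_wait,
        "TransplantSurgery": u_wait,
        "PostTx": u_post,
        "Death": 0.0,
    }
    costs_monthly = {
        "WaitMedTx": c_wait,
        "WaitMedTxFrac": c_wait,
        "TransplantSurgery": 0.0,
        "PostTx": c_post,
        "Death": 0.0,
    }

    initial = np.zeros(5)
    if wait == 0:
        initial[i_surg] = 1.0
    elif n_full == 0:
        initial[i_frac] = 1.0
    else:
        initial[i_wait] = 1.0

    return StrategyModel(
        name="direct_transplant",
        states=states,
        initial=initial,
        transition=transition,
        utility=lambda s, t: utilities[s],
        running_cost=lambda s, t: costs_monthly[s],
        entry_cost=lambda s, t: surgery_cost if s == "TransplantSurgery" else 0.0,
        occupancy={"WaitMedTxFrac": frac if frac > 0 else 1.0},
        stationary_from=surgery_cycle + 1,
        metadata={"model": "BTT", "mean_age": params.mean_age_btt,
                  "perspective": costs.perspective},
    )


def build_btt_intervention(params: ParameterSet, costs: CostTable) -> StrategyModel:
    """Centrifugal-flow pump as bridge to transplant.

    The cohort carries the pump while waiting (pump mortality schedule
    and pooled complication state as in destination therapy), then moves
    through transplant surgery into the post-transplant state.  The
    waiting clock keeps running through complication episodes; during
    the final full cycle and the fractional exit cycle only mortality
    competes, so survivors are transplanted on schedule.
    """
    mort = params.pump_mortality
    wait = params.wait_ht_btt.base
    n_full, frac = _split_wait(wait)
    p_periop, p_post, u_post, c_post = _transplant_tail(params, costs)
    u_first = params.u_pump_first_month.base
    u_after = params.u_pump_after.base
    c_wait = costs.monthly["pump_waiting"]
    implant_cost = costs.device_price + costs.one_time["pump_implantation"]
    surgery_cost = costs.one_time["heart_transplant"]

    states = ("PumpWait", "PumpComplication", "PumpWaitFrac",
              "TransplantSurgery", "PostTx", "Death")
    i_wait, i_comp, i_frac, i_surg, i_post, i_death = range(6)
    surgery_cycle = n_full + (1 if frac > 0 else 0)

    def frac_death_at(t: int) -> float:
        month = t + 1
        p = mort.at(month)
        return 1.0 - (1.0 - p) ** frac if frac > 0 else 0.0

    def transition(t: int) -> np.ndarray:
        month = t + 1
        p_d = mort.at(month)
        mat = np.zeros((6, 6))
        mat[i_death, i_death] = 1.0
        if frac > 0 and t == n_full - 1:
            wait_dest, comp_entry = i_frac, False
        elif t >= n_full - 1:
            wait_dest, comp_entry = i_surg, False
        else:
            wait_dest, comp_entry = i_wait, True
        if comp_entry:
            total, _, _ = pump_complication_mixture(params, costs, month)
            p_c = min(total, 1.0 - p_d)
        else:
            p_c = 0.0
        mat[i_wait, wait_dest] += 1.0 - p_d - p_c
        mat[i_wait, i_comp] += p_c
        mat[i_wait, i_death] += p_d
        mat[i_comp, wait_dest] = 1.0 - p_d
        mat[i_comp, i_death] = p_d
        fd = frac_death_at(t)
        mat[i_frac, i_surg] = 1.0 - fd
        mat[i_frac, i_death] = fd
        mat[i_surg, i_post] = 1.0 - p_periop
        mat[i_surg, i_death] = p_periop
        mat[i_post, i_post] = 1.0 - p_post
        mat[i_post, i_death] = p_post
        return mat

    def utility(state: str, t: int) -> float:
        if state == "PumpWait":
            return u_first if t == 0 else u_after
        if state in ("PumpWaitFrac",):
            return u_after
        if state == "PumpComplication":
            _, u_mix, _ = pump_complication_mixture(params, costs, max(t, 1))
            return u_mix
        if state == "TransplantSurgery":
            return params.u_medtx.base
        if state == "PostTx":
            return u_post
        return 0.0

    def running_cost(state: str, t: int) -> float:
        if state in ("PumpWait", "PumpComplication", "PumpWaitFrac"):
            return c_wait
        if state == "PostTx":
            return c_post
        return 0.0

    def entry_cost(state: str, t: int) -> float:
        if t == 0 and state in ("PumpWait", "PumpWaitFrac", "TransplantSurgery"):
            return implant_cost + (surgery_cost if state == "TransplantSurgery" else 0.0)
        if state == "PumpComplication":
            _, _, c_mix = pump_complication_mixture(params, costs, max(t, 1))
            return c_mix
        if state == "TransplantSurgery":
            return surgery_cost
        return 0.0

    initial = np.zeros(6)
    if wait == 0:
        initial[i_surg] = 1.0
    elif n_full == 0:
        initial[i_frac] = 1.0
    else:
        initial[i_wait] = 1.0

    return StrategyModel(
        name="pump_bridge_to_transplant",
        states=states,
        initial=initial,
        transition=transition,
        utility=utility,
        running_cost=running_cost,
        entry_cost=entry_cost,
        occupancy={"PumpWaitFrac": frac if frac > 0 else 1.0},
        stationary_from=surgery_cycle + 1,
        metadata={"model": "BTT", "mean_age": params.mean_age_btt,
                  "perspective": costs.perspective},
    )


_BUILDERS = {
    "DT": (build_dt_control, build_dt_intervention),
    "BTT": (build_btt_control, build_btt_intervention),
}


def build_pair(
    model_id: str, params: ParameterSet, costs: CostTable
) -> tuple[StrategyModel, StrategyModel]:
    """(control, intervention) models for ``model_id`` in {"DT", "BTT"}."""
    try:
        build_control, build_intervention = _BUILDERS[model_id]
    except KeyError:
        raise ModelError(f"unknown model id {model_id!r}; expected 'DT' or 'BTT'") from None
    return build_control(params, costs), build_intervention(params, costs)
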