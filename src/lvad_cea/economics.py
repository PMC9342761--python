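"""Incremental cost-effectiveness results: ICER, NMB, dominance.

Combines two cohort traces (control and intervention run under the same
parameter set and payer perspective) into incremental costs, QALYs and
the incremental cost-effectiveness ratio, with explicit dominance
handling.  Results are reported per patient; the nominal cohort size is
only a reporting convenience.
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import StrategyModel, run_cohort
from .errors import ValidationError
from .parameters import CostTable, ParameterSet
from .strategies import build_pair

__all__ = ["ICERValue", "CEBlock", "CEResult", "icer", "nmb", "evaluate_pair",
           "evaluate_model"]

#: dominance / definedness labels used by :func:`icer`
ICER_RATIO = "icer"
INTERVENTION_DOMINANT = "intervention_dominant"
INTERVENTION_DOMINATED = "intervention_dominated"
ICER_UNDEFINED = "undefined"


@dataclass(frozen=True)
class ICERValue:
    """An ICER or the reason there is none.

    ``value`` is ΔC/ΔE (ARS per QALY) when the ratio is meaningful,
    ``None`` when the intervention dominates / is dominated or when
    ΔE = 0.  ``label`` carries the classification.
    """

    value: float | None
    label: str

    @property
    def is_ratio(self) -> bool:
        return self.label == ICER_RATIO


def icer(delta_cost: float, delta_effect: float) -> ICERValue:
    """Classify and compute the incremental cost-effectiveness ratio.

    Returns a plain ratio when ΔE != 0 and the signs agree (including
    the south-west quadrant, where the ratio reads as savings per QALY
    forgone); a dominance flag when one strategy is both cheaper and
    more effective; and an undefined flag when ΔE = 0.
    """
    if delta_effect == 0.0:
        return ICERValue(None, ICER_UNDEFINED)
    if delta_cost < 0.0 and delta_effect > 0.0:
        return ICERValue(None, INTERVENTION_DOMINANT)
    if delta_cost > 0.0 and delta_effect < 0.0:
        return ICERValue(None, INTERVENTION_DOMINATED)
    return ICERValue(delta_cost / delta_effect, ICER_RATIO)


@dataclass(frozen=True)
class CEBlock:
    """Cost-effectiveness summary for one discounting setting."""

    discount_rate: float
    control_cost: float
    control_qaly: float
    intervention_cost: float
    intervention_qaly: float

    @property
    def delta_cost(self) -> float:
        return self.intervention_cost - self.control_cost

    @property
    def delta_effect(self) -> float:
        return self.intervention_qaly - self.control_qaly

    @property
    def icer(self) -> ICERValue:
        return icer(self.delta_cost, self.delta_effect)


@dataclass(frozen=True)
class CEResult:
    """Base-case result for one strategy pair and payer perspective."""

    model_id: str
    perspective: str
    control_name: str
    intervention_name: str
    discounted: CEBlock
    undiscounted: CEBlock
    cohort_size: int = 1


def nmb(result: CEResult | CEBlock, wtp: float) -> float:
    """Net monetary benefit ``wtp * ΔE - ΔC`` at a willingness-to-pay.

    Accepts a :class:`CEResult` (its discounted block is used) or a
    :class:`CEBlock`.
    """
    if wtp < 0:
        raise ValidationError(f"willingness-to-pay must be >= 0, got {wtp}")
    block = result.discounted if isinstance(result, CEResult) else result
    return wtp * block.delta_effect - block.delta_cost


def evaluate_pair(
    control: StrategyModel,
    intervention: StrategyModel,
    discount_rate: float = 0.05,
    model_id: str = "",
    perspective: str = "",
    cohort_size: int = 1,
    half_cycle: bool = False,
) -> CEResult:
    """Run both cohorts to their lifetime horizons and summarise.

    A single run per arm yields both the discounted and the
    undiscounted accrual streams (Table-2-style reporting).
    """
    tr_c = run_cohort(control, discount_rate=discount_rate, half_cycle=half_cycle)
    tr_i = run_cohort(intervention, discount_rate=discount_rate, half_cycle=half_cycle)
    discounted = CEBlock(
        discount_rate=discount_rate,
        control_cost=tr_c.total_cost_disc,
        control_qaly=tr_c.total_qaly_disc,
        intervention_cost=tr_i.total_cost_disc,
        intervention_qaly=tr_i.total_qaly_disc,
    )
    undiscounted = CEBlock(
        discount_rate=0.0,
        control_cost=tr_c.total_cost_undisc,
        control_qaly=tr_c.total_qaly_undisc,
        intervention_cost=tr_i.total_cost_undisc,
        intervention_qaly=tr_i.total_qaly_undisc,
    )
    return CEResult(
        model_id=model_id or control.metadata.get("model", ""),
        perspective=perspective or control.metadata.get("perspective", ""),
        control_name=control.name,
        intervention_name=intervention.name,
        discounted=discounted,
        undiscounted=undiscounted,
        cohort_size=cohort_size,
    )


def evaluate_model(
    model_id: str,
    params: ParameterSet,
    costs: CostTable,
    discount_rate: float | None = None,
    half_cycle: bool = False,
) -> CEResult:
    """Build and evaluate one strategy pair from inputs.

    ``discount_rate`` defaults to the parameter set's annual rate.
    """
    control, intervention = build_pair(model_id, params, costs)
    rate = params.discount_rate_annual if discount_rate is None else discount_rate
    return evaluate_pair(
        control,
        intervention,
        discount_rate=rate,
        model_id=model_id,
        perspective=costs.perspective,
        cohort_size=params.cohort_size,
        half_cycle=half_cycle,
    )
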