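"""Second-order (parameter-uncertainty) distributions.

Distribution families follow standard health-economic practice:

* probabilities and utilities — beta, method-of-moments from the mean
  and standard error; when only a variability range is available it is
  read as a 95% central interval, SE = (high - low) / 3.92;
* disutility decrements — negated beta on the magnitude;
* costs — gamma with a coefficient of variation of 25% / 1.96
  (one-way cost ranges are +/- 25% of the mean);
* waiting times — uniform over their variability range.

Zero-width inputs (SE = 0 or low = high) reproduce the base value
exactly without consuming random numbers, so fully degenerate
distributions return the base case bit-for-bit.  Moment combinations
implying out-of-range mass are clamped with a logged warning.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .parameters import (
    ComplicationSpec,
    CostTable,
    Estimate,
    ParameterSet,
    PiecewiseRate,
)

__all__ = [
    "COST_CV",
    "range_to_se",
    "draw_beta",
    "draw_estimate",
    "draw_parameter_set",
    "draw_cost_factors",
]

logger = logging.getLogger(__name__)

#: coefficient of variation implied by a +/-25% range read as 95% CI
COST_CV = 0.25 / 1.96

_CLAMP = 0.95  # fraction of the feasible beta SD used when moments are infeasible


def range_to_se(low: float, high: float) -> float:
    """SE implied by reading (low, high) as a 95% central interval."""
    return (high - low) / 3.92


def draw_beta(mean: float, se: float, rng: np.random.Generator) -> float:
    """Beta draw parameterised by mean and SE (method of moments).

    Degenerate inputs (se=0, or mean at 0 or 1) return the mean.  An SE
    implying variance >= mean(1-mean) is clamped to the feasible region
    with a warning.
    """
    if se == 0.0 or mean <= 0.0 or mean >= 1.0:
        return mean
    feasible = mean * (1.0 - mean)
    if se * se >= feasible:
        clamped = _CLAMP * math.sqrt(feasible)
        logger.warning(
            "beta SE %.4g infeasible for mean %.4g; clamped to %.4g", se, mean, clamped
        )
        se = clamped
    nu = feasible / (se * se) - 1.0
    a = mean * nu
    b = (1.0 - mean) * nu
    return float(rng.beta(a, b))


def _se_of(est: Estimate) -> float:
    if est.se is not None:
        return est.se
    if est.has_range:
        return range_to_se(est.low, est.high)
    return 0.0


def draw_estimate(est: Estimate, rng: np.random.Generator,
                  uniform: bool = False) -> Estimate:
    """One draw from an estimate's distribution, keeping its metadata.

    ``uniform=True`` draws uniformly over the variability range (used
    for waiting times).  The drawn value replaces ``base``; low/high are
    widened if the draw falls outside them so the result still
    validates.
    """
    if uniform:
        if not est.has_range or est.low == est.high:
            return est
        value = float(rng.uniform(est.low, est.high))
    elif est.disutility:
        se = est.se or 0.0
        value = -draw_beta(-est.base, se, rng)
    else:
        se = _se_of(est)
        if se == 0.0:
            return est
        value = draw_beta(est.base, se, rng)
    if value == est.base:
        return est
    low = None if est.low is None else min(est.low, value)
    high = None if est.high is None else max(est.high, value)
    return dataclasses.replace(est, base=value, low=low, high=high)


def _draw_piecewise(rate: PiecewiseRate, rng: np.random.Generator) -> PiecewiseRate:
    if rate.lows is None or rate.highs is None:
        return rate
    values = []
    changed = False
    for v, lo, hi in zip(rate.values, rate.lows, rate.highs):
        se = range_to_se(lo, hi)
        if se == 0.0:
            values.append(v)
            continue
        drawn = draw_beta(v, se, rng)
        changed = changed or drawn != v
        values.append(drawn)
    if not changed:
        return rate
    return PiecewiseRate(
        rate.starts,
        tuple(values),
        tuple(min(lo, v) for lo, v in zip(rate.lows, values)),
        tuple(max(hi, v) for hi, v in zip(rate.highs, values)),
    )


def _draw_complication(spec: ComplicationSpec, rng: np.random.Generator,
                       draw_rate: bool = True) -> ComplicationSpec:
    rate = _draw_piecewise(spec.rate, rng) if draw_rate else spec.rate
    utility = draw_estimate(spec.utility, rng)
    if rate is spec.rate and utility is spec.utility:
        return spec
    return dataclasses.replace(spec, rate=rate, utility=utility)


def draw_parameter_set(params: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One joint draw of every uncertain model parameter.

    Parameters are drawn independently.  Transplant-complication rates
    carry no variability range and stay fixed; their utilities are
    drawn.  The discount rate, hospitalization fraction and global
    constants are not second-order uncertain.
    """
    return dataclasses.replace(
        params,
        p_death_medtx=draw_estimate(params.p_death_medtx, rng),
        u_medtx=draw_estimate(params.u_medtx, rng),
        wait_ht=draw_estimate(params.wait_ht, rng, uniform=True),
        wait_ht_btt=draw_estimate(params.wait_ht_btt, rng, uniform=True),
        p_death_ht_periop=draw_estimate(params.p_death_ht_periop, rng),
        p_death_post_ht=draw_estimate(params.p_death_post_ht, rng),
        pump_mortality=_draw_piecewise(params.pump_mortality, rng),
        u_pump_first_month=draw_estimate(params.u_pump_first_month, rng),
        u_pump_after=draw_estimate(params.u_pump_after, rng),
        pump_complications=tuple(
            _draw_complication(c, rng) for c in params.pump_complications
        ),
        u_stable_ht=draw_estimate(params.u_stable_ht, rng),
        ht_complications=tuple(
            _draw_complication(c, rng, draw_rate=False)
            for c in params.ht_complications
        ),
    )


def draw_cost_factors(costs: CostTable, rng: np.random.Generator,
                      cv: float = COST_CV) -> dict[str, float]:
    """Multiplicative gamma factors (mean 1, CV ``cv``) per cost key.

    Drawing *factors* rather than values lets both payer perspectives
    share one set of draws, preserving their cost ordering.  Keys are
    drawn in sorted order for reproducibility.
    """
    if cv == 0.0:
        return {}
    shape = 1.0 / (cv * cv)
    scale = cv * cv
    keys = sorted(costs.monthly) + sorted(costs.one_time) + ["device_price"]
    return {k: float(rng.gamma(shape, scale)) for k in keys}
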