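"""Sensitivity analyses: one-way DSA (tornado), waiting-time scenario,
and second-order Monte-Carlo PSA with CE-plane and CEAC outputs.

The one-way analysis re-evaluates the full strategy pair at the low and
high end of every parameter that carries a variability range (cost
items at +/-25%, the discount rate from 0 to 10%); parameters without a
range are skipped with a logged notice.  The probabilistic analysis
draws every uncertain parameter jointly (independent draws, see
:mod:`lvad_cea.distributions`), rebuilds both strategies per iteration
and records the incremental cost/effect pair per payer perspective.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distributions import draw_cost_factors, draw_parameter_set
from .economics import evaluate_model
from .errors import ValidationError
from .parameters import CostTable, ParameterSet, load_parameters, to_dict

__all__ = [
    "TornadoRow",
    "PSADraws",
    "one_way_dsa",
    "tornado_frame",
    "waiting_time_scenario",
    "psa",
    "ceac",
    "ceac_thresholds",
    "ce_plane",
    "ce_plane_export",
]

logger = logging.getLogger(__name__)

DISCOUNT_DSA_BOUNDS = (0.0, 0.10)
COST_DSA_FACTOR = 0.25


@dataclass(frozen=True)
class TornadoRow:
    """One-way sensitivity result for a single parameter."""

    parameter: str
    low: float
    high: float
    icer_low: float | None
    icer_high: float | None

    @property
    def swing(self) -> float:
        if self.icer_low is None or self.icer_high is None:
            return float("inf")  # dominance at a bound: maximal decision impact
        return abs(self.icer_high - self.icer_low)


@dataclass
class PSADraws:
    """Monte-Carlo (ΔC, ΔE) pairs per payer perspective."""

    model_id: str
    seed: int
    n_iter: int
    delta_cost: dict[str, np.ndarray]
    delta_effect: dict[str, np.ndarray]
    discount_rate: float

    @property
    def perspectives(self) -> tuple[str, ...]:
        return tuple(self.delta_cost)

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for persp in self.perspectives:
            parts.append(
                pd.DataFrame(
                    {
                        "iteration": np.arange(self.n_iter),
                        "perspective": persp,
                        "delta_qaly": self.delta_effect[persp],
                        "delta_cost": self.delta_cost[persp],
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity analysis


def _set_in(tree: dict, path: tuple, value) -> None:
    node = tree
    for key in path[:-1]:
        node = node[key]
    node[path[-1]] = value


def _dsa_items(model_id: str, params: ParameterSet) -> list[tuple[str, tuple, float, float]]:
    """(name, config path, low, high) for every ranged model parameter."""
    items: list[tuple[str, tuple, float, float]] = []

    def add_estimate(name: str, section: tuple, est) -> None:
        if est.has_range and est.low != est.high:
            items.append((name, section + ("base",), est.low, est.high))
        else:
            logger.info("DSA: parameter %s has no variability range; skipped", name)

    if model_id == "DT":
        add_estimate("p_death_medtx", ("model1", "p_death_medtx"), params.p_death_medtx)
    else:
        add_estimate("p_death_medtx (waiting list)", ("model1", "p_death_medtx"),
                     params.p_death_medtx)
        add_estimate("wait_ht", ("model2", "wait_ht"), params.wait_ht)
        add_estimate("wait_ht_btt", ("model2", "wait_ht_btt"), params.wait_ht_btt)
        add_estimate("p_death_ht_periop", ("model2", "p_death_ht_periop"),
                     params.p_death_ht_periop)
        add_estimate("p_death_post_ht", ("model2", "p_death_post_ht"),
                     params.p_death_post_ht)

    mort = params.pump_mortality
    if mort.lows is not None and mort.highs is not None:
        for i, start in enumerate(mort.starts):
            items.append(
                (
                    f"pump_mortality[month {start}+]",
                    ("pump", "mortality", "values", i),
                    mort.lows[i],
                    mort.highs[i],
                )
            )
    for ci, spec in enumerate(params.pump_complications):
        if spec.rate.lows is None or spec.rate.highs is None:
            logger.info("DSA: complication %s has no rate range; skipped", spec.name)
            continue
        for i, start in enumerate(spec.rate.starts):
            items.append(
                (
                    f"{spec.name}[month {start}+]",
                    ("pump", "complications", ci, "rate", "values", i),
                    spec.rate.lows[i],
                    spec.rate.highs[i],
                )
            )
    for spec in params.ht_complications:
        logger.info("DSA: transplant complication %s has no rate range; skipped",
                    spec.name)
    return items


def one_way_dsa(
    model_id: str,
    params: ParameterSet,
    costs: CostTable,
    discount_rate: float | None = None,
) -> list[TornadoRow]:
    """Tornado analysis: two full evaluations per ranged parameter.

    Also varies the annual discount rate over 0–10%, the device price
    and every cost-table entry by +/-25%.  Rows are sorted by
    descending ICER swing.
    """
    rate = params.discount_rate_annual if discount_rate is None else discount_rate
    base_tree = to_dict(params)

    def icer_with(tree: dict | None = None, cost_table: CostTable | None = None,
                  disc: float | None = None) -> float | None:
        p = params if tree is None else load_parameters(tree, merge_defaults=False)
        c = cost_table if cost_table is not None else costs
        r = rate if disc is None else disc
        return evaluate_model(model_id, p, c, discount_rate=r).discounted.icer.value

    rows: list[TornadoRow] = []
    for name, path, low, high in _dsa_items(model_id, params):
        results = []
        for bound in (low, high):
            tree = copy.deepcopy(base_tree)
            _set_in(tree, path, float(bound))
            # a varied base may step outside its own printed range
            _widen_range(tree, path, float(bound))
            results.append(icer_with(tree=tree))
        rows.append(TornadoRow(name, low, high, results[0], results[1]))

    lo, hi = DISCOUNT_DSA_BOUNDS
    rows.append(
        TornadoRow("discount_rate", lo, hi,
                   icer_with(disc=lo), icer_with(disc=hi))
    )
    cost_keys = ["device_price"] + sorted(costs.monthly) + sorted(costs.one_time)
    for key in cost_keys:
        base_value = (
            costs.device_price if key == "device_price"
            else costs.monthly.get(key, costs.one_time.get(key))
        )
        results = []
        for factor in (1.0 - COST_DSA_FACTOR, 1.0 + COST_DSA_FACTOR):
            results.append(icer_with(cost_table=costs.scaled({key: factor})))
        rows.append(
            TornadoRow(f"cost:{key}", base_value * (1 - COST_DSA_FACTOR),
                       base_value * (1 + COST_DSA_FACTOR), results[0], results[1])
        )
    rows.sort(key=lambda r: r.swing, reverse=True)
    return rows


def _widen_range(tree: dict, path: tuple, value: float) -> None:
    """Relax low/high alongside a varied base so validation passes."""
    if path[-1] != "base":
        return
    node = tree
    for key in path[:-1]:
        node = node[key]
    if isinstance(node, dict):
        if node.get("low") is not None:
            node["low"] = min(node["low"], value)
        if node.get("high") is not None:
            node["high"] = max(node["high"], value)


def tornado_frame(rows: Sequence[TornadoRow], base_icer: float | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "parameter": [r.parameter for r in rows],
            "low": [r.low for r in rows],
            "high": [r.high for r in rows],
            "icer_low": [r.icer_low for r in rows],
            "icer_high": [r.icer_high for r in rows],
            "swing": [r.swing for r in rows],
        }
    )
    if base_icer is not None:
        df.attrs["base_icer"] = base_icer
    return df


# ---------------------------------------------------------------------------
# waiting-time scenario analysis


def waiting_time_scenario(
    values: Sequence[float],
    params: ParameterSet,
    costs: Mapping[str, CostTable] | CostTable,
    equal_waits: bool = True,
    discount_rate: float | None = None,
) -> pd.DataFrame:
    """Re-evaluate the bridge-to-transplant pair over waiting times.

    With ``equal_waits`` (the published alternative scenario) both arms
    share each waiting time; otherwise only the direct-transplant arm's
    wait is varied and the pump arm keeps its base value.
    """
    tables = costs if isinstance(costs, Mapping) else {costs.perspective: costs}
    base_tree = to_dict(params)
    records = []
    for w in values:
        if w <= 0:
            raise ValidationError(f"waiting time must be > 0, got {w}")
        tree = copy.deepcopy(base_tree)
        _set_in(tree, ("model2", "wait_ht", "base"), float(w))
        _widen_range(tree, ("model2", "wait_ht", "base"), float(w))
        if equal_waits:
            _set_in(tree, ("model2", "wait_ht_btt", "base"), float(w))
            _widen_range(tree, ("model2", "wait_ht_btt", "base"), float(w))
        p = load_parameters(tree, merge_defaults=False)
        for persp, table in tables.items():
            res = evaluate_model("BTT", p, table, discount_rate=discount_rate)
            block = res.discounted
            records.append(
                {
                    "wait_months": w,
                    "perspective": persp,
                    "delta_cost": block.delta_cost,
                    "delta_qaly": block.delta_effect,
                    "icer": block.icer.value,
                }
            )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


def psa(
    model_id: str,
    params: ParameterSet,
    costs: Mapping[str, CostTable] | CostTable,
    n_iter: int = 1000,
    seed: int = 0,
    discount_rate: float | None = None,
) -> PSADraws:
    """Second-order Monte-Carlo simulation of the strategy pair.

    Each iteration draws one joint parameter set and one set of
    multiplicative cost factors (shared across perspectives, preserving
    the PS >= SS ordering), rebuilds both strategies and records the
    incremental cost and effect.  Reproducible under ``seed``.
    """
    if n_iter < 1:
        raise ValidationError(f"n_iter must be >= 1, got {n_iter}")
    tables = costs if isinstance(costs, Mapping) else {costs.perspective: costs}
    rate = params.discount_rate_annual if discount_rate is None else discount_rate
    rng = np.random.default_rng(seed)
    any_table = next(iter(tables.values()))
    d_cost = {p: np.empty(n_iter) for p in tables}
    d_eff = {p: np.empty(n_iter) for p in tables}
    for i in range(n_iter):
        drawn = draw_parameter_set(params, rng)
        factors = draw_cost_factors(any_table, rng)
        for persp, table in tables.items():
            res = evaluate_model(model_id, drawn, table.scaled(factors),
                                 discount_rate=rate)
            d_cost[persp][i] = res.discounted.delta_cost
            d_eff[persp][i] = res.discounted.delta_effect
    return PSADraws(
        model_id=model_id,
        seed=seed,
        n_iter=n_iter,
        delta_cost=d_cost,
        delta_effect=d_eff,
        discount_rate=rate,
    )


def ceac_thresholds(gdp_per_capita: float, max_multiple: float = 6.0,
                    step: float = 0.1) -> np.ndarray:
    """Willingness-to-pay grid: 0 to ``max_multiple`` GDP in ``step`` GDP
    increments, always including the integer-GDP points."""
    grid = np.arange(0.0, max_multiple + step / 2, step) * gdp_per_capita
    integers = np.arange(1, int(max_multiple) + 1) * gdp_per_capita
    return np.unique(np.round(np.concatenate([grid, integers]), 6))


def ceac(draws: PSADraws, thresholds: Sequence[float]) -> pd.DataFrame:
    """Probability of positive net monetary benefit per threshold.

    Fraction of draws with ``wtp * ΔE - ΔC > 0`` for each
    willingness-to-pay value and perspective.
    """
    if draws.n_iter == 0:
        raise ValidationError("CEAC needs a non-empty draw set")
    records = []
    for persp in draws.perspectives:
        de = draws.delta_effect[persp]
        dc = draws.delta_cost[persp]
        for wtp in thresholds:
            prob = float(np.mean(wtp * de - dc > 0.0))
            records.append(
                {"perspective": persp, "wtp": float(wtp), "probability": prob}
            )
    return pd.DataFrame.from_records(records)


def _quadrant(delta_effect: float, delta_cost: float) -> str:
    ns = "N" if delta_cost >= 0 else "S"
    ew = "E" if delta_effect >= 0 else "W"
    return ns + ew


def ce_plane(draws: PSADraws) -> pd.DataFrame:
    """(ΔE, ΔC) pairs with cost-effectiveness-plane quadrant labels."""
    df = draws.to_frame()
    df["quadrant"] = [
        _quadrant(e, c) for e, c in zip(df["delta_qaly"], df["delta_cost"])
    ]
    return df


def ce_plane_export(draws: PSADraws, path) -> pd.DataFrame:
    """Write the CE-plane scatter as CSV and return the frame."""
    df = ce_plane(draws)
    df.to_csv(path, index=False)
    return df
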