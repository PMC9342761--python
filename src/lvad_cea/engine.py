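"""Generic monthly-cycle cohort state-transition engine.

A :class:`StrategyModel` bundles an ordered state list (with a single
absorbing death state), a cycle-indexed transition schedule, and
per-state per-cycle utility, running-cost and one-time entry-cost
accruals.  :func:`run_cohort` propagates cohort fractions through the
transition matrices and accrues discounted and undiscounted QALYs and
costs per cycle.

Accrual conventions
-------------------
* State membership at the *start* of a cycle accrues that cycle's full
  utility and running cost (no half-cycle correction by default; pass
  ``half_cycle=True`` to average start- and end-of-cycle membership).
* One-time entry costs are charged to the cohort mass entering a state
  at the cycle of the triggering transition, discounted at that cycle.
* Discounting compounds annually at monthly resolution:
  ``(1 + r) ** (-cycle / 12)``.
* "Lifetime" horizons run until the surviving fraction drops below an
  extinction threshold (1e-6) or a hard cap of 1200 cycles (100 years).
* States may occupy only a fraction of a month (tunnel exit cycles);
  their utility/cost accruals are pro-rated by that occupancy fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .errors import ModelError, ValidationError

__all__ = [
    "StrategyModel",
    "CohortTrace",
    "discount_factor",
    "run_cohort",
    "lifetime_horizon",
    "EXTINCTION_THRESHOLD",
    "CYCLE_CAP",
]

EXTINCTION_THRESHOLD = 1e-6
CYCLE_CAP = 1200  # 100 years of monthly cycles

_ROW_SUM_TOL = 1e-12


def discount_factor(annual_rate: float, cycle: int) -> float:
    """Discount multiplier for an accrual at a given monthly cycle.

    Annual compounding applied at monthly resolution:
    ``(1 + annual_rate) ** (-cycle / 12)``.
    """
    if annual_rate < 0:
        raise ValidationError(f"annual discount rate must be >= 0, got {annual_rate}")
    if cycle < 0:
        raise ValidationError(f"cycle must be >= 0, got {cycle}")
    return float((1.0 + annual_rate) ** (-cycle / 12.0))


class StrategyModel:
    """A fully built cohort model for one treatment strategy.

    Parameters
    ----------
    name:
        Strategy label used in reports and error messages.
    states:
        Ordered state names; must contain ``death_state``.
    initial:
        Initial cohort distribution over states (sums to 1).
    transition:
        ``transition(cycle) -> (n, n)`` row-stochastic matrix applied to
        the membership vector at the end of that cycle.
    utility / running_cost / entry_cost:
        ``f(state_name, cycle) -> float``.  ``running_cost`` is a
        per-month state-occupancy cost; ``entry_cost`` is charged once
        per unit mass entering the state at that cycle.
    occupancy:
        Optional map ``state -> fraction of the month occupied`` used to
        pro-rate accruals (default 1 for every state).
    stationary_from:
        Cycle index from which all schedules are constant; enables
        caching of matrices and accrual vectors for long horizons.
    """

    def __init__(
        self,
        name: str,
        states: tuple[str, ...],
        initial,
        transition: Callable[[int], np.ndarray],
        utility: Callable[[str, int], float],
        running_cost: Callable[[str, int], float],
        entry_cost: Callable[[str, int], float] | None = None,
        occupancy: Mapping[str, float] | None = None,
        stationary_from: int = 0,
        death_state: str = "Death",
        metadata: Mapping | None = None,
    ) -> None:
        self.name = name
        self.states = tuple(states)
        if death_state not in self.states:
            raise ModelError(f"{name}: absorbing state {death_state!r} not in states")
        self.death_state = death_state
        self.death_index = self.states.index(death_state)
        self.initial = np.asarray(initial, dtype=float)
        if self.initial.shape != (len(self.states),):
            raise ModelError(f"{name}: initial distribution has wrong length")
        if abs(self.initial.sum() - 1.0) > 1e-10 or (self.initial < 0).any():
            raise ModelError(f"{name}: initial distribution must be a probability vector")
        self._transition = transition
        self._utility = utility
        self._running_cost = running_cost
        self._entry_cost = entry_cost or (lambda state, cycle: 0.0)
        occupancy = occupancy or {}
        self.occupancy = np.array(
            [occupancy.get(s, 1.0) for s in self.states], dtype=float
        )
        if ((self.occupancy < 0) | (self.occupancy > 1)).any():
            raise ModelError(f"{name}: occupancy fractions must lie in [0, 1]")
        self.stationary_from = int(stationary_from)
        self.metadata = dict(metadata or {})
        self._matrix_cache: dict[int, np.ndarray] = {}
        self._vector_cache: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    # -- public accessors (spec surface) ---------------------------------

    def transition(self, cycle: int) -> np.ndarray:
        """Validated row-stochastic transition matrix for a cycle."""
        key = min(cycle, self.stationary_from)
        cached = self._matrix_cache.get(key)
        if cached is not None:
            return cached
        mat = np.asarray(self._transition(key), dtype=float)
        self._validate_matrix(mat, key)
        self._matrix_cache[key] = mat
        return mat

    def utility(self, state: str, cycle: int) -> float:
        return float(self._utility(state, cycle))

    def running_cost(self, state: str, cycle: int) -> float:
        return float(self._running_cost(state, cycle))

    def entry_cost(self, state: str, cycle: int) -> float:
        return float(self._entry_cost(state, cycle))

    def accrual_vectors(self, cycle: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(utility, running cost, entry cost) vectors for a cycle, cached."""
        key = min(cycle, self.stationary_from)
        cached = self._vector_cache.get(key)
        if cached is None:
            u = np.array([self._utility(s, key) for s in self.states], dtype=float)
            if ((u < -1.0) | (u > 1.0)).any():
                raise ModelError(f"{self.name}: utility outside [-1, 1] at cycle {key}")
            c = np.array([self._running_cost(s, key) for s in self.states], dtype=float)
            e = np.array([self._entry_cost(s, key) for s in self.states], dtype=float)
            cached = (u, c, e)
            self._vector_cache[key] = cached
        return cached

    # -- internals --------------------------------------------------------

    def _validate_matrix(self, mat: np.ndarray, cycle: int) -> None:
        n = len(self.states)
        if mat.shape != (n, n):
            raise ModelError(f"{self.name}: transition matrix at cycle {cycle} not {n}x{n}")
        if (mat < -_ROW_SUM_TOL).any():
            raise ModelError(f"{self.name}: negative transition probability at cycle {cycle}")
        sums = mat.sum(axis=1)
        bad = np.abs(sums - 1.0) > _ROW_SUM_TOL
        if bad.any():
            state = self.states[int(np.argmax(bad))]
            raise ModelError(
                f"{self.name}: transition row for state {state!r} at cycle {cycle} "
                f"sums to {sums[bad][0]!r}, not 1"
            )
        death_row = np.zeros(n)
        death_row[self.death_index] = 1.0
        if not np.allclose(mat[self.death_index], death_row, atol=_ROW_SUM_TOL):
            raise ModelError(
                f"{self.name}: death state must be absorbing (cycle {cycle})"
            )


@dataclass
class CohortTrace:
    """State-membership fractions by cycle plus per-cycle accruals.

    ``membership[t]`` is the distribution at the start of cycle ``t``;
    the array has one extra row holding the final post-transition
    distribution.  Accrual arrays have one entry per simulated cycle.
    """

    states: tuple[str, ...]
    membership: np.ndarray
    qaly_disc: np.ndarray
    qaly_undisc: np.ndarray
    cost_disc: np.ndarray
    cost_undisc: np.ndarray
    discount_rate: float
    death_index: int
    cycles: int = field(init=False)

    def __post_init__(self) -> None:
        self.cycles = len(self.qaly_disc)

    @property
    def total_qaly_disc(self) -> float:
        return float(self.qaly_disc.sum())

    @property
    def total_qaly_undisc(self) -> float:
        return float(self.qaly_undisc.sum())

    @property
    def total_cost_disc(self) -> float:
        return float(self.cost_disc.sum())

    @property
    def total_cost_undisc(self) -> float:
        return float(self.cost_undisc.sum())

    def alive(self, cycle: int) -> float:
        return float(1.0 - self.membership[cycle, self.death_index])


def run_cohort(
    model: StrategyModel,
    horizon: int | None = None,
    discount_rate: float = 0.05,
    extinction: float = EXTINCTION_THRESHOLD,
    cap: int = CYCLE_CAP,
    half_cycle: bool = False,
) -> CohortTrace:
    """Propagate the cohort and accrue per-cycle costs and QALYs.

    With ``horizon=None`` the run stops when the surviving fraction
    falls below ``extinction`` or at ``cap`` cycles, whichever is first;
    an explicit ``horizon`` disables the extinction stop.
    """
    if horizon is not None and horizon < 1:
        raise ValidationError(f"horizon must be >= 1, got {horizon}")
    limit = cap if horizon is None else int(horizon)
    n = len(model.states)
    occ = model.occupancy
    monthly_df = (1.0 + discount_rate) ** (-1.0 / 12.0)

    membership = np.empty((limit + 1, n))
    qaly_d = np.zeros(limit)
    qaly_u = np.zeros(limit)
    cost_d = np.zeros(limit)
    cost_u = np.zeros(limit)

    m = model.initial.copy()
    membership[0] = m
    df = 1.0
    ran = 0
    for t in range(limit):
        alive = 1.0 - m[model.death_index]
        if horizon is None and alive < extinction:
            break
        u_vec, c_vec, e_vec = model.accrual_vectors(t)
        mat = model.transition(t)
        m_next = m @ mat
        occupants = 0.5 * (m + m_next) if half_cycle else m
        q = float(occupants @ (u_vec * occ)) / 12.0
        c = float(occupants @ (c_vec * occ))
        if t == 0:
            # initial entries (e.g. device purchase + implantation)
            c += float(m @ e_vec)
        qaly_u[t] += q
        qaly_d[t] += q * df
        cost_u[t] += c
        cost_d[t] += c * df
        m = m_next
        membership[t + 1] = m
        df *= monthly_df  # df now corresponds to cycle t + 1
        ran = t + 1
        # one-time costs for mass entering a state from *other* states,
        # charged and discounted at the arrival cycle; entrants arriving
        # exactly at the horizon cap fall outside the accrued window,
        # mirroring their un-accrued occupancy
        if t + 1 < limit:
            inflow = np.clip(m_next - membership[t] * np.diag(mat), 0.0, None)
            entry_next = float(inflow @ model.accrual_vectors(t + 1)[2])
            if entry_next != 0.0:
                cost_u[t + 1] += entry_next
                cost_d[t + 1] += entry_next * df

    membership = membership[: ran + 1]
    return CohortTrace(
        states=model.states,
        membership=membership,
        qaly_disc=qaly_d[:ran],
        qaly_undisc=qaly_u[:ran],
        cost_disc=cost_d[:ran],
        cost_undisc=cost_u[:ran],
        discount_rate=discount_rate,
        death_index=model.death_index,
    )


def lifetime_horizon(
    model: StrategyModel,
    extinction: float = EXTINCTION_THRESHOLD,
    cap: int = CYCLE_CAP,
) -> int:
    """First cycle at which the surviving fraction drops below the
    extinction threshold, hard-capped at ``cap`` cycles."""
    m = model.initial.copy()
    for t in range(cap):
        if 1.0 - m[model.death_index] < extinction:
            return t
        m = m @ model.transition(t)
    return cap
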