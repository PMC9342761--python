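"""Typed, validated model inputs for the two LVAD decision models.

The package models two monthly-cycle Markov cohort comparisons for
advanced heart failure (NYHA III/IV, INTERMACS profiles 1-4):

* Model 1 (destination therapy, DT): a centrifugal-flow pump versus
  standard medical management in transplant-ineligible patients.
* Model 2 (bridge to transplant, BTT): a centrifugal-flow pump while on
  the heart-transplant waiting list versus direct transplantation.

This module houses every clinical, epidemiological and utility input as
a typed record, loads/serialises the structured-text (YAML) parameter
file, and validates the basic invariants: probabilities and utilities in
[0, 1], disutility decrements in [-1, 0], ``low <= base <= high`` for
every variability range, and contiguous monthly step schedules.

A packaged default parameter file ships under ``data/table1.yaml``; cost
tables are handled by :mod:`lvad_cea.synthetic` because the underlying
micro-costing values are not public.
"""

from __future__ import annotations

import copy
from collections.abc import Mapping
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError, ValidationError

__all__ = [
    "Estimate",
    "PiecewiseRate",
    "ComplicationSpec",
    "ParameterSet",
    "CostTable",
    "MONTHLY_COST_KEYS",
    "BASE_ONE_TIME_KEYS",
    "load_parameters",
    "load_cost_table",
    "serialize",
    "rate_at",
    "default_parameter_path",
]

#: monthly state-occupancy cost categories every cost table must carry
MONTHLY_COST_KEYS = (
    "medtx_outpatient",
    "medtx_hospitalized",
    "pump_stable",
    "pump_waiting",
    "post_transplant",
)

#: one-time event costs every cost table must carry, besides one entry
#: per complication episode (validated against the parameter set).
BASE_ONE_TIME_KEYS = ("pump_implantation", "heart_transplant")

PERSPECTIVES = ("SS", "PS")


# ---------------------------------------------------------------------------
# elementary value types


@dataclass(frozen=True)
class Estimate:
    """A point estimate with an optional variability range and/or SE.

    The range (``low``/``high``) drives the one-way deterministic
    sensitivity analysis; for probabilistic analysis a range with no SE
    is read as a 95% central interval.  ``disutility`` marks decrements
    (values in [-1, 0]) applied on top of a base utility.
    """

    base: float
    low: float | None = None
    high: float | None = None
    se: float | None = None
    disutility: bool = False

    def __post_init__(self) -> None:
        if self.low is not None and self.high is not None:
            if not (self.low <= self.base <= self.high):
                raise ValidationError(
                    f"range must satisfy low <= base <= high, got "
                    f"({self.low}, {self.base}, {self.high})"
                )
        if self.se is not None and self.se < 0:
            raise ValidationError(f"standard error must be >= 0, got {self.se}")

    @property
    def has_range(self) -> bool:
        return self.low is not None and self.high is not None

    def require_probability(self, name: str) -> None:
        lo = self.low if self.low is not None else self.base
        hi = self.high if self.high is not None else self.base
        if not (0.0 <= lo and hi <= 1.0):
            raise ValidationError(f"{name!r} must lie in [0, 1], got {self.base}")

    def require_disutility(self, name: str) -> None:
        lo = self.low if self.low is not None else self.base
        hi = self.high if self.high is not None else self.base
        if not (-1.0 <= lo and hi <= 0.0):
            raise ValidationError(
                f"disutility {name!r} must lie in [-1, 0], got {self.base}"
            )


@dataclass(frozen=True)
class PiecewiseRate:
    """Monthly probability as a step function of months since model entry.

    ``starts`` are 1-based first months of each interval (strictly
    increasing, beginning at month 1), ``values`` the per-cycle
    probabilities.  Months beyond the last tabulated interval carry the
    last value forward, which is how the lifetime horizon extrapolates
    registry schedules that end at month 60.  Optional ``lows``/``highs``
    carry the per-interval variability ranges.
    """

    starts: tuple[int, ...]
    values: tuple[float, ...]
    lows: tuple[float, ...] | None = None
    highs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.starts) == 0 or len(self.starts) != len(self.values):
            raise ValidationError("piecewise schedule needs matching starts/values")
        if self.starts[0] != 1:
            raise ValidationError("piecewise schedule must start at month 1")
        if any(b <= a for a, b in zip(self.starts, self.starts[1:])):
            raise ValidationError("piecewise interval starts must strictly increase")
        for bounds in (self.lows, self.highs):
            if bounds is not None and len(bounds) != len(self.values):
                raise ValidationError("range bounds must match schedule length")
        for i, v in enumerate(self.values):
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"monthly probability out of [0,1]: {v}")
            if self.lows is not None and self.highs is not None:
                if not (self.lows[i] <= v <= self.highs[i]):
                    raise ValidationError(
                        f"interval {i}: low <= base <= high violated "
                        f"({self.lows[i]}, {v}, {self.highs[i]})"
                    )

    def at(self, month: int) -> float:
        """Value of the step function at a (1-based) month."""
        if month < 1:
            raise ValidationError(f"month must be >= 1, got {month}")
        idx = 0
        for i, start in enumerate(self.starts):
            if month >= start:
                idx = i
            else:
                break
        return self.values[idx]

    def with_values(self, values: tuple[float, ...]) -> "PiecewiseRate":
        return PiecewiseRate(self.starts, tuple(values), None, None)

    @property
    def n_intervals(self) -> int:
        return len(self.starts)


def rate_at(schedule: PiecewiseRate, month: int) -> float:
    """Monthly probability of a step schedule at ``month`` (>= 1).

    Months beyond the last tabulated interval return the last interval's
    value (carry-forward extrapolation).
    """
    return schedule.at(month)


@dataclass(frozen=True)
class ComplicationSpec:
    """One adverse-event type: incidence schedule, utility, episode cost key.

    ``utility`` is either an absolute health-state utility for the month
    spent in the complication state or, when flagged as a disutility, a
    decrement applied to the concurrent pump utility (used for
    ventricular arrhythmia).  ``cost_key`` indexes the one-time episode
    cost in the cost table.
    """

    name: str
    rate: PiecewiseRate
    utility: Estimate
    cost_key: str

    def __post_init__(self) -> None:
        if self.utility.disutility:
            self.utility.require_disutility(self.name)
        else:
            self.utility.require_probability(f"utility of {self.name}")


# ---------------------------------------------------------------------------
# the full parameter set


@dataclass(frozen=True)
class ParameterSet:
    """All inputs of both decision models plus global constants.

    Mean ages are descriptive cohort metadata only: no age-specific
    background mortality enters the transitions.
    """

    # globals
    discount_rate_annual: float
    gdp_per_capita: float
    wtp_multipliers: tuple[int, ...]
    device_price: float
    cohort_size: int
    exchange_rate_ars_per_usd: float

    # model 1 (destination therapy)
    mean_age_dt: float
    p_death_medtx: Estimate
    u_medtx: Estimate
    hosp_fraction_medtx: float

    # model 2 (bridge to transplant)
    mean_age_btt: float
    wait_ht: Estimate                 # months on the direct-transplant list
    wait_ht_btt: Estimate             # months on the list with a pump
    p_death_ht_periop: Estimate       # per-event perioperative mortality
    p_death_post_ht: Estimate         # monthly post-transplant mortality

    # centrifugal-flow pump
    pump_mortality: PiecewiseRate
    u_pump_first_month: Estimate
    u_pump_after: Estimate
    pump_complications: tuple[ComplicationSpec, ...]

    # heart transplant
    u_stable_ht: Estimate
    ht_complications: tuple[ComplicationSpec, ...]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.discount_rate_annual < 0:
            raise ValidationError("discount rate must be >= 0")
        if not 0.0 <= self.hosp_fraction_medtx <= 1.0:
            raise ValidationError("hosp_fraction_medtx must lie in [0, 1]")
        if self.device_price < 0 or self.gdp_per_capita <= 0:
            raise ValidationError("device price and GDP per capita must be positive")
        if self.cohort_size < 1:
            raise ValidationError("cohort_size must be >= 1")
        for name in ("p_death_medtx", "p_death_ht_periop", "p_death_post_ht"):
            getattr(self, name).require_probability(name)
        for name in ("u_medtx", "u_pump_first_month", "u_pump_after", "u_stable_ht"):
            getattr(self, name).require_probability(name)
        for w in ("wait_ht", "wait_ht_btt"):
            if getattr(self, w).base < 0:
                raise ValidationError(f"{w} must be >= 0 months")
        # ComplicationSpec / PiecewiseRate validate themselves on construction

    def complication(self, name: str) -> ComplicationSpec:
        for spec in self.pump_complications + self.ht_complications:
            if spec.name == name:
                return spec
        raise KeyError(name)


# ---------------------------------------------------------------------------
# cost tables


@dataclass(frozen=True)
class CostTable:
    """Direct medical costs for one payer perspective, ARS (Dec 2019).

    ``monthly`` maps model states to state-occupancy costs per cycle;
    ``one_time`` maps events (implantation, transplant surgery, each
    complication episode) to per-event costs.  ``device_price`` is the
    pump purchase price charged once at implantation.
    """

    perspective: str
    monthly: Mapping[str, float]
    one_time: Mapping[str, float]
    device_price: float

    def __post_init__(self) -> None:
        if self.perspective not in PERSPECTIVES:
            raise ValidationError(
                f"perspective must be one of {PERSPECTIVES}, got {self.perspective!r}"
            )
        for key in MONTHLY_COST_KEYS:
            if key not in self.monthly:
                raise ConfigurationError(f"cost table missing monthly cost {key!r}")
        for key in BASE_ONE_TIME_KEYS:
            if key not in self.one_time:
                raise ConfigurationError(f"cost table missing one-time cost {key!r}")
        for group in (self.monthly, self.one_time):
            for key, value in group.items():
                if value < 0:
                    raise ValidationError(f"cost {key!r} must be >= 0, got {value}")
        if self.device_price < 0:
            raise ValidationError("device_price must be >= 0")

    def episode_cost(self, key: str) -> float:
        try:
            return self.one_time[key]
        except KeyError:
            raise ConfigurationError(
                f"cost table has no one-time cost for complication {key!r}"
            ) from None

    def scaled(self, factors: Mapping[str, float]) -> "CostTable":
        """Return a copy with multiplicative factors applied by key.

        Recognised keys: every monthly/one-time key and ``device_price``.
        Missing keys default to a factor of 1.
        """
        return CostTable(
            perspective=self.perspective,
            monthly={k: v * factors.get(k, 1.0) for k, v in self.monthly.items()},
            one_time={k: v * factors.get(k, 1.0) for k, v in self.one_time.items()},
            device_price=self.device_price * factors.get("device_price", 1.0),
        )


# ---------------------------------------------------------------------------
# loading / serialising


def default_parameter_path() -> Path:
    """Path of the packaged default parameter file."""
    return Path(resources.files("lvad_cea").joinpath("data/table1.yaml"))


def _require(mapping: Mapping, path: tuple[str, ...]):
    node = mapping
    for i, key in enumerate(path):
        if not isinstance(node, Mapping) or key not in node:
            raise ConfigurationError(
                "missing required configuration key: " + ".".join(map(str, path[: i + 1]))
            )
        node = node[key]
    return node


def _estimate(node, name: str, disutility: bool = False) -> Estimate:
    if isinstance(node, (int, float)):
        return Estimate(base=float(node), disutility=disutility)
    if not isinstance(node, Mapping) or "base" not in node:
        raise ConfigurationError(f"parameter {name!r} must be a number or have a 'base'")
    try:
        return Estimate(
            base=float(node["base"]),
            low=None if node.get("low") is None else float(node["low"]),
            high=None if node.get("high") is None else float(node["high"]),
            se=None if node.get("se") is None else float(node["se"]),
            disutility=bool(node.get("disutility", disutility)),
        )
    except ValidationError as exc:
        raise ValidationError(f"{name}: {exc}") from None


def _piecewise(node, name: str) -> PiecewiseRate:
    starts = tuple(int(s) for s in _require({name: node}, (name, "starts")))
    values = tuple(float(v) for v in _require({name: node}, (name, "values")))
    lows = node.get("lows")
    highs = node.get("highs")
    try:
        return PiecewiseRate(
            starts,
            values,
            None if lows is None else tuple(float(v) for v in lows),
            None if highs is None else tuple(float(v) for v in highs),
        )
    except ValidationError as exc:
        raise ValidationError(f"{name}: {exc}") from None


def _complications(nodes, section: str) -> tuple[ComplicationSpec, ...]:
    specs = []
    for i, node in enumerate(nodes):
        name = _require(node, ("name",))
        disutility = bool(node.get("disutility", False))
        specs.append(
            ComplicationSpec(
                name=name,
                rate=_piecewise(_require(node, ("rate",)), f"{section}.{name}.rate"),
                utility=_estimate(
                    _require(node, ("utility",)), f"{section}.{name}.utility", disutility
                ),
                cost_key=node.get("cost_key", name),
            )
        )
    return tuple(specs)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def _read_yaml(source) -> dict:
    text = Path(source).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"configuration in {source} is not a mapping")
    return data


def load_parameters(source=None, merge_defaults: bool = True) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a config source.

    ``source`` may be ``None`` (packaged defaults), a path to a YAML
    file, or an already-parsed mapping.  With ``merge_defaults`` (the
    default) keys absent from the source fall back to the packaged
    default values; with ``merge_defaults=False`` every key is required
    and a missing one raises :class:`ConfigurationError` naming it.
    """
    if source is None:
        data = _read_yaml(default_parameter_path())
    elif isinstance(source, Mapping):
        data = dict(source)
    else:
        data = _read_yaml(source)

    if merge_defaults and source is not None:
        data = _deep_merge(_read_yaml(default_parameter_path()), data)

    return ParameterSet(
        discount_rate_annual=float(_require(data, ("globals", "discount_rate_annual"))),
        gdp_per_capita=float(_require(data, ("globals", "gdp_per_capita"))),
        wtp_multipliers=tuple(
            int(k) for k in _require(data, ("globals", "wtp_multipliers"))
        ),
        device_price=float(_require(data, ("globals", "device_price"))),
        cohort_size=int(_require(data, ("globals", "cohort_size"))),
        exchange_rate_ars_per_usd=float(
            _require(data, ("globals", "exchange_rate_ars_per_usd"))
        ),
        mean_age_dt=float(_require(data, ("model1", "mean_age"))),
        p_death_medtx=_estimate(
            _require(data, ("model1", "p_death_medtx")), "p_death_medtx"
        ),
        u_medtx=_estimate(_require(data, ("model1", "u_medtx")), "u_medtx"),
        hosp_fraction_medtx=float(_require(data, ("model1", "hosp_fraction_medtx"))),
        mean_age_btt=float(_require(data, ("model2", "mean_age"))),
        wait_ht=_estimate(_require(data, ("model2", "wait_ht")), "wait_ht"),
        wait_ht_btt=_estimate(_require(data, ("model2", "wait_ht_btt")), "wait_ht_btt"),
        p_death_ht_periop=_estimate(
            _require(data, ("model2", "p_death_ht_periop")), "p_death_ht_periop"
        ),
        p_death_post_ht=_estimate(
            _require(data, ("model2", "p_death_post_ht")), "p_death_post_ht"
        ),
        pump_mortality=_piecewise(
            _require(data, ("pump", "mortality")), "pump.mortality"
        ),
        u_pump_first_month=_estimate(
            _require(data, ("pump", "u_first_month")), "pump.u_first_month"
        ),
        u_pump_after=_estimate(_require(data, ("pump", "u_after")), "pump.u_after"),
        pump_complications=_complications(
            _require(data, ("pump", "complications")), "pump.complications"
        ),
        u_stable_ht=_estimate(
            _require(data, ("transplant", "u_stable")), "transplant.u_stable"
        ),
        ht_complications=_complications(
            _require(data, ("transplant", "complications")), "transplant.complications"
        ),
    )


def _estimate_dict(e: Estimate) -> dict | float:
    if e.low is None and e.high is None and e.se is None and not e.disutility:
        return e.base
    out: dict = {"base": e.base}
    if e.low is not None:
        out["low"] = e.low
    if e.high is not None:
        out["high"] = e.high
    if e.se is not None:
        out["se"] = e.se
    if e.disutility:
        out["disutility"] = True
    return out


def _piecewise_dict(p: PiecewiseRate) -> dict:
    out: dict = {"starts": list(p.starts), "values": list(p.values)}
    if p.lows is not None:
        out["lows"] = list(p.lows)
    if p.highs is not None:
        out["highs"] = list(p.highs)
    return out


def _complication_dict(c: ComplicationSpec) -> dict:
    out: dict = {"name": c.name, "rate": _piecewise_dict(c.rate)}
    if c.utility.disutility:
        out["disutility"] = True
        out["utility"] = {"base": c.utility.base}
        if c.utility.se is not None:
            out["utility"]["se"] = c.utility.se
    else:
        out["utility"] = _estimate_dict(c.utility)
    if c.cost_key != c.name:
        out["cost_key"] = c.cost_key
    return out


def to_dict(params: ParameterSet) -> dict:
    """Plain-dict form of a parameter set (the YAML schema)."""
    return {
        "globals": {
            "discount_rate_annual": params.discount_rate_annual,
            "gdp_per_capita": params.gdp_per_capita,
            "wtp_multipliers": list(params.wtp_multipliers),
            "device_price": params.device_price,
            "cohort_size": params.cohort_size,
            "exchange_rate_ars_per_usd": params.exchange_rate_ars_per_usd,
        },
        "model1": {
            "mean_age": params.mean_age_dt,
            "p_death_medtx": _estimate_dict(params.p_death_medtx),
            "u_medtx": _estimate_dict(params.u_medtx),
            "hosp_fraction_medtx": params.hosp_fraction_medtx,
        },
        "model2": {
            "mean_age": params.mean_age_btt,
            "wait_ht": _estimate_dict(params.wait_ht),
            "wait_ht_btt": _estimate_dict(params.wait_ht_btt),
            "p_death_ht_periop": _estimate_dict(params.p_death_ht_periop),
            "p_death_post_ht": _estimate_dict(params.p_death_post_ht),
        },
        "pump": {
            "mortality": _piecewise_dict(params.pump_mortality),
            "u_first_month": _estimate_dict(params.u_pump_first_month),
            "u_after": _estimate_dict(params.u_pump_after),
            "complications": [
                _complication_dict(c) for c in params.pump_complications
            ],
        },
        "transplant": {
            "u_stable": _estimate_dict(params.u_stable_ht),
            "complications": [_complication_dict(c) for c in params.ht_complications],
        },
    }


def serialize(params: ParameterSet) -> str:
    """Canonical YAML serialisation; round-trips through ``load_parameters``."""
    return yaml.safe_dump(to_dict(params), sort_keys=False, default_flow_style=False)


def load_cost_table(source, perspective: str | None = None) -> CostTable:
    """Load one perspective's :class:`CostTable` from a YAML file or mapping.

    The file either describes a single perspective (keys ``perspective``,
    ``monthly``, ``one_time``, ``device_price``) or both, nested under
    ``SS``/``PS`` with a shared top-level ``device_price``; in the latter
    case ``perspective`` selects which one to return.
    """
    data = source if isinstance(source, Mapping) else _read_yaml(source)
    if "monthly" not in data and any(p in data for p in PERSPECTIVES):
        if perspective is None:
            raise ConfigurationError(
                "cost file holds both perspectives; specify which one to load"
            )
        section = _require(data, (perspective,))
        return CostTable(
            perspective=perspective,
            monthly={k: float(v) for k, v in _require(section, ("monthly",)).items()},
            one_time={k: float(v) for k, v in _require(section, ("one_time",)).items()},
            device_price=float(
                section.get("device_price", _require(data, ("device_price",)))
            ),
        )
    persp = perspective or _require(data, ("perspective",))
    return CostTable(
        perspective=persp,
        monthly={k: float(v) for k, v in _require(data, ("monthly",)).items()},
        one_time={k: float(v) for k, v in _require(data, ("one_time",)).items()},
        device_price=float(_require(data, ("device_price",))),
    )
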