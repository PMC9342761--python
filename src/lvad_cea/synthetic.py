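"""Synthetic cost tables and perturbed parameter sets.

The micro-costing inputs behind the published analysis (state-occupancy
monthly costs and one-time event costs per payer perspective) are not
public; only the device purchase price is printed.  This module
generates cost tables with the same *structure* and a realistic
magnitude ordering so every pipeline stage runs end to end without any
external data:

* the device price is fixed at the printed ARS 7,104,276;
* hospitalized medical-treatment months cost more than outpatient ones;
* pump implantation > transplant surgery > any complication episode;
* Private Sector (PS) entries are the Social Security (SS) entries
  times an uplift drawn in [1.05, 1.40].

Magnitudes are centred so that the destination-therapy incremental cost
lands in the neighbourhood of the published ARS 8.06M when combined
with the fixed device price — a realistic operating regime, not a
reconstruction of the confidential values.  A slot is provided for the
real supplementary cost file when a user can supply it.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import yaml

from .distributions import draw_parameter_set
from .errors import SupplementaryDataMissing
from .parameters import (
    CostTable,
    ParameterSet,
    load_cost_table,
)

__all__ = [
    "generate_cost_table",
    "generate_cost_tables",
    "write_cost_file",
    "calibration_target_costs",
    "perturb_parameters",
    "DEVICE_PRICE_ARS",
]

#: manufacturer purchase price of the pump, ARS (Dec 2019)
DEVICE_PRICE_ARS = 7_104_276.0

# central magnitudes (SS perspective, ARS/month or ARS/event) used by the
# generator; each is jittered log-uniformly within [0.8, 1.25] of centre
_MONTHLY_CENTERS = {
    "medtx_outpatient": 27_000.0,
    "medtx_hospitalized": 550_000.0,
    "pump_stable": 8_000.0,
    "pump_waiting": 8_000.0,
    "post_transplant": 36_000.0,
}
_ONE_TIME_CENTERS = {
    "pump_implantation": 1_400_000.0,
    "heart_transplant": 950_000.0,
    "gi_bleeding": 250_000.0,
    "pump_failure": 450_000.0,
    "disabling_stroke": 400_000.0,
    "nondisabling_stroke": 200_000.0,
    "driveline_infection": 180_000.0,
    "right_heart_failure": 300_000.0,
    "sepsis": 350_000.0,
    "ventricular_arrhythmia": 150_000.0,
    "transplant_rejection": 300_000.0,
    "allograft_vasculopathy": 350_000.0,
    "skin_malignancy": 60_000.0,
    "lymphoma": 450_000.0,
    "renal_dysfunction_dialysis": 400_000.0,
    "ht_sepsis": 350_000.0,
}
# jitter bounds chosen so the implantation > transplant > episode ordering
# cannot be violated by the draws themselves
_JITTER_LOW, _JITTER_HIGH = 0.8, 1.25
_UPLIFT_LOW, _UPLIFT_HIGH = 1.05, 1.40


def _loguniform(rng: np.random.Generator, center: float) -> float:
    lo, hi = math.log(center * _JITTER_LOW), math.log(center * _JITTER_HIGH)
    return float(math.exp(rng.uniform(lo, hi)))


def generate_cost_table(seed: int, perspective: str = "SS") -> CostTable:
    """Deterministic synthetic cost table for one payer perspective.

    The SS table is drawn first from the seeded stream; the PS table
    applies per-key uplift factors drawn from the continuation of the
    same stream, so both perspectives of one seed are consistent and
    every PS entry is at least its SS counterpart.
    """
    rng = np.random.default_rng(seed)
    monthly = {k: _loguniform(rng, c) for k, c in _MONTHLY_CENTERS.items()}
    one_time = {k: _loguniform(rng, c) for k, c in _ONE_TIME_CENTERS.items()}
    if perspective == "PS":
        monthly = {k: v * rng.uniform(_UPLIFT_LOW, _UPLIFT_HIGH)
                   for k, v in monthly.items()}
        one_time = {k: v * rng.uniform(_UPLIFT_LOW, _UPLIFT_HIGH)
                    for k, v in one_time.items()}
    return CostTable(
        perspective=perspective,
        monthly=monthly,
        one_time=one_time,
        device_price=DEVICE_PRICE_ARS,
    )


def generate_cost_tables(seed: int) -> dict[str, CostTable]:
    """Both perspectives for one seed, keyed ``SS``/``PS``."""
    return {p: generate_cost_table(seed, p) for p in ("SS", "PS")}


def write_cost_file(tables: dict[str, CostTable], path) -> None:
    """Write a two-perspective cost file in the supplementary-table layout."""
    payload = {"device_price": float(next(iter(tables.values())).device_price)}
    for persp, table in tables.items():
        payload[persp] = {
            "monthly": {k: float(v) for k, v in table.monthly.items()},
            "one_time": {k: float(v) for k, v in table.one_time.items()},
        }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def calibration_target_costs(path="s2_cost_inputs.yaml") -> dict[str, CostTable]:
    """Load the user-supplied supplementary cost file (both perspectives).

    The confidential cost values are not distributed with the package;
    reproducing the published cost-side results requires the user to
    provide them in the documented YAML layout.  A missing file raises
    :class:`SupplementaryDataMissing` — there is no silent fallback.
    """
    p = Path(path)
    if not p.exists():
        raise SupplementaryDataMissing(
            f"supplementary cost values not provided (no file at {p}); "
            "supply the cost table to reproduce cost-side results"
        )
    return {persp: load_cost_table(p, persp) for persp in ("SS", "PS")}


def perturb_parameters(params: ParameterSet, seed: int) -> ParameterSet:
    """One seeded joint draw of every uncertain parameter.

    Deterministic under ``seed``; degenerate (zero-width) distributions
    reproduce ``params`` unchanged.
    """
    return draw_parameter_set(params, np.random.default_rng(seed))
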