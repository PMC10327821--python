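"""Convert branch cohort traces into discounted costs, life-years and QALYs.

Recurring flows are valued on half-cycle-corrected occupancy and discounted
at cycle midpoints; one-off flows are discounted at their event time (cycle
start for entry costs, cycle midpoint for incidence-triggered costs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .cohort_engine import AML, CHF, DR, RF, CohortTrace, half_cycle_occupancy
from .conversions import discount_factor
from .decision_tree import Branch
from .parameters import ModelConfig

__all__ = [
    "COST_CATEGORIES",
    "TABLE_ROW_NAMES",
    "StrategyOutcome",
    "value_costs",
    "value_qalys",
    "value_branch",
]

COST_CATEGORIES = (
    "test",
    "adjuvant",
    "transportation",
    "sick_leave",
    "recurrence_free",
    "distant_recurrence",
    "aml",
    "chf",
    "end_of_life",
)

#: Human-readable report labels for the cost breakdown.
TABLE_ROW_NAMES = {
    "test": "Test",
    "adjuvant": "Adjuvant treatments",
    "transportation": "Transportation",
    "sick_leave": "Sick leave due to CT",
    "recurrence_free": "Recurrence-free",
    "distant_recurrence": "Distant recurrence",
    "aml": "AML",
    "chf": "CHF",
    "end_of_life": "End of life",
}


@dataclass
class StrategyOutcome:
    """Discounted per-patient outcomes at branch, stratum or population level."""

    costs_by_category: Dict[str, float]
    ly: float
    qaly: float
    ct_proportion: float
    aml_proportion: float
    chf_proportion: float

    @property
    def total_cost(self) -> float:
        return float(sum(self.costs_by_category.values()))

    def validate(self) -> "StrategyOutcome":
        if self.qaly > self.ly + 1e-9:
            raise AssertionError(f"QALY {self.qaly} exceeds LY {self.ly}")
        for name in ("ct_proportion", "aml_proportion", "chf_proportion"):
            v = getattr(self, name)
            if not (-1e-9 <= v <= 1.0 + 1e-9):
                raise AssertionError(f"{name} outside [0, 1]: {v}")
        return self


def _grids(trace: CohortTrace, config: ModelConfig):
    dt = trace.cycle_length_years
    K = trace.n_cycles
    k = np.arange(K)
    d_mid = discount_factor((k + 0.5) * dt, config.discount)
    d_start = discount_factor(k * dt, config.discount)
    return dt, K, d_mid, d_start


def value_costs(trace: CohortTrace, branch: Branch, config: ModelConfig) -> Dict[str, float]:
    """Discounted cost per patient of this branch, by reporting category."""
    spec = config.stratum(branch.stratum_id)
    costs = config.costs
    dt, K, d_mid, d_start = _grids(trace, config)
    hc = half_cycle_occupancy(trace)
    out = {c: 0.0 for c in COST_CATEGORIES}
    n_first = max(int(round(1.0 / dt)), 1)
    ct = branch.receives_ct

    # Test cost: strategy-level cycle-0 one-off (the test precedes the
    # treatment decision, so every test-arm branch carries the full amount).
    if branch.strategy == "ODX":
        out["test"] = costs.test_cost

    # Adjuvant: CT add-on (cycle 0) + ET drug cost while recurrence-free,
    # for the configured ET duration.
    adjuvant = spec.ct_addon_cost if ct else 0.0
    et_cycles = np.arange(K) * dt < config.et_duration_years
    adjuvant += float(np.sum(spec.et_annual_cost * dt * hc[:, RF] * d_mid * et_cycles))
    out["adjuvant"] = adjuvant

    # Transportation: CT transport at cycle 0; ET transport spread over the
    # first-year cycles, charged at cycle start on recurrence-free occupancy.
    transport = spec.transport_ct_cost if ct else 0.0
    first_year = np.arange(K) < n_first
    transport += float(
        np.sum(
            (spec.transport_et_cost / n_first)
            * trace.occupancy[:-1, RF]
            * d_start
            * first_year
        )
    )
    out["transportation"] = transport

    out["sick_leave"] = spec.sick_leave_cost if ct else 0.0

    # Recurrence-free state: first-year stratum cost replaces the generic
    # recurring cost in the first-year cycles.
    rf_percycle = np.where(
        first_year,
        spec.rf_year1_cost / n_first,
        costs.per_cycle("rf_recurring", costs.rf_recurring_cost, dt),
    )
    out["recurrence_free"] = float(np.sum(rf_percycle * hc[:, RF] * d_mid))

    dr_percycle = costs.per_cycle("dr_cdk46", costs.dr_cdk46_cost, dt) + costs.per_cycle(
        "dr_management", costs.dr_management_cost, dt
    )
    out["distant_recurrence"] = float(np.sum(dr_percycle * hc[:, DR] * d_mid))

    out["aml"] = float(
        np.sum(costs.aml_oneoff_cost * trace.incidence[:, 1] * d_mid)
        + np.sum(
            costs.per_cycle("aml_recurring", costs.aml_recurring_cost, dt)
            * hc[:, AML]
            * d_mid
        )
    )
    out["chf"] = float(
        np.sum(costs.chf_oneoff_cost * trace.incidence[:, 2] * d_mid)
        + np.sum(
            costs.per_cycle("chf_recurring", costs.chf_recurring_cost, dt)
            * hc[:, CHF]
            * d_mid
        )
    )
    out["end_of_life"] = float(np.sum(costs.terminal_cost * trace.incidence[:, 3] * d_mid))
    return out


def value_qalys(trace: CohortTrace, branch: Branch, config: ModelConfig):
    """Discounted (life-years, QALYs) per patient of this branch."""
    u = config.utilities
    dt, K, d_mid, _ = _grids(trace, config)
    hc = half_cycle_occupancy(trace)
    alive = hc[:, [RF, DR, AML, CHF]].sum(axis=1)
    ly = float(np.sum(alive * d_mid) * dt)

    adj = u.france_adjustment if u.apply_france_adjustment else 1.0
    base = np.array(
        [min(u.u_rf * adj, 1.0), min(u.u_dr * adj, 1.0), min(u.u_aml * adj, 1.0),
         min(u.u_chf * adj, 1.0)]
    )
    spec = config.stratum(branch.stratum_id)
    curve = config.age_utility_curve
    mult = curve.lookup_array(trace.ages[:-1]) / curve.lookup(spec.start_age)

    weights = np.clip(base[None, :] * mult[:, None], 0.0, 1.0)  # (K, 4)
    qaly = float(np.sum(hc[:, [RF, DR, AML, CHF]] * weights * d_mid[:, None]) * dt)

    if branch.receives_ct and u.ct_decrement > 0.0 and u.ct_decrement_cycles > 0:
        dec = np.arange(K) < u.ct_decrement_cycles
        qaly -= float(np.sum(u.ct_decrement * np.minimum(mult, 1.0) * alive * d_mid * dec) * dt)
    return ly, qaly


def value_branch(trace: CohortTrace, branch: Branch, config: ModelConfig) -> StrategyOutcome:
    """Full valuation of one branch trace."""
    ly, qaly = value_qalys(trace, branch, config)
    return StrategyOutcome(
        costs_by_category=value_costs(trace, branch, config),
        ly=ly,
        qaly=qaly,
        ct_proportion=1.0 if branch.receives_ct else 0.0,
        aml_proportion=float(trace.incidence[:, 1].sum()),
        chf_proportion=float(trace.incidence[:, 2].sum()),
    ).validate()
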