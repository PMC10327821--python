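"""Markov cohort engine.

Propagates each decision-tree branch through a five-state model
(recurrence-free, distant recurrence, AML, CHF, death) on the model's cycle
grid with half-cycle correction. CHF is internally split by tenure so the
first-year excess mortality applies by time-in-state, not calendar time.

Competing risks within a cycle are combined on the rate scale: marginal
per-cycle probabilities are converted to rates, summed, and the total exit
probability ``1 - exp(-sum r_i)`` is allocated proportionally to the rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
import pandas as pd

from . import conversions as cv
from .decision_tree import Branch
from .parameters import ModelConfig

__all__ = [
    "STATES",
    "CohortTrace",
    "marginal_probs",
    "build_transition_matrix",
    "build_cycle_matrices",
    "run_branch",
    "half_cycle_occupancy",
    "write_trace_csv",
]

#: Collapsed reporting states, in order.
STATES = ("RF", "DR", "AML", "CHF", "DEAD")
RF, DR, AML, CHF, DEAD = range(5)

_CLIP = 1.0 - 1e-12
_RECURRENCE_HORIZON_YEARS = 10.0  # recurrence inputs are ten-year probabilities
_AML_SURVIVAL_HORIZON_YEARS = 5.0  # AML death input is a five-year probability


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and incidence streams for one branch.

    ``occupancy`` has ``n_cycles + 1`` rows over the five collapsed states;
    row 0 is (1, 0, 0, 0, 0). ``incidence`` holds per-cycle inflow of new
    distant recurrences, AML cases, CHF cases, and deaths.
    """

    branch: Branch
    occupancy: np.ndarray  # (K+1, 5)
    incidence: np.ndarray  # (K, 4): new DR, AML, CHF, deaths
    ages: np.ndarray  # (K+1,) age at cycle start
    cycle_length_years: float
    occupancy_internal: np.ndarray = field(repr=False, default=None)

    @property
    def n_cycles(self) -> int:
        return self.incidence.shape[0]

    def alive(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, DEAD]


def _n_first_year_cycles(cycle_length_years: float) -> int:
    return max(int(round(1.0 / cycle_length_years)), 1)


def _rescale_cycle_prob(p: float, from_years: float, to_years: float) -> float:
    """Re-express a probability defined over *from_years* on a *to_years* grid."""
    if from_years == to_years:
        return p
    return 1.0 - (1.0 - p) ** (to_years / from_years)


def marginal_probs(branch: Branch, cycle_index: int, config: ModelConfig) -> Dict[str, float]:
    """Per-cycle marginal transition probabilities before competing-risk
    adjustment, for one branch at one cycle."""
    spec = config.stratum(branch.stratum_id)
    dt = config.cycle_length_years
    age = spec.start_age + cycle_index * dt
    ct = branch.receives_ct
    cl = config.clinical

    p_bg = cv.annual_to_cycle_prob(config.life_table.lookup(age), dt)
    p_rf_dr = cv.cycle_prob_from_survival(
        spec.recurrence.prob(branch.rs_context, branch.treatment),
        _RECURRENCE_HORIZON_YEARS,
        dt,
    )
    in_window = (
        cl.aml_risk_window_years is None or cycle_index * dt < cl.aml_risk_window_years
    )
    p_aml = _rescale_cycle_prob(cl.aml_cycle_prob, 0.5, dt) if (ct and in_window) else 0.0
    p_chf = cv.annual_to_cycle_prob(config.chf_incidence_curve.lookup(age), dt)
    if ct:
        p_chf = cv.rescale_prob_hr(p_chf, cl.chf_rr_ct)
    p_dr_death = max(p_bg, cv.cycle_prob_from_median(cl.dr_median_os_months, dt))
    if cl.aml_5yr_death_prob >= 1.0:
        p_aml_death = 1.0
    else:
        p_aml_death = max(
            p_bg,
            cv.cycle_prob_from_survival(
                1.0 - cl.aml_5yr_death_prob, _AML_SURVIVAL_HORIZON_YEARS, dt
            ),
        )
    return {
        "rf_dr": p_rf_dr,
        "rf_aml": p_aml,
        "rf_chf": p_chf,
        "rf_death": p_bg,
        "dr_aml": p_aml if cl.dr_toxicity else 0.0,
        "dr_chf": p_chf if cl.dr_toxicity else 0.0,
        "dr_death": p_dr_death,
        "aml_death": p_aml_death,
        "chf_death_first_year": cv.rescale_prob_hr(min(p_bg, _CLIP), cl.chf_excess_hr_year1),
        "chf_death_later": cv.rescale_prob_hr(min(p_bg, _CLIP), cl.chf_excess_hr_later),
    }


def _compete(marginals: np.ndarray) -> np.ndarray:
    """Allocate the joint exit probability across competing events.

    ``marginals`` has shape (..., m); returns the same shape with each
    column holding the adjusted transition probability.
    """
    p = np.clip(marginals, 0.0, _CLIP)
    rates = -np.log1p(-p)
    total_rate = rates.sum(axis=-1, keepdims=True)
    p_total = -np.expm1(-total_rate)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total_rate > 0.0, p_total * rates / total_rate, 0.0)
    return out


def build_cycle_matrices(branch: Branch, config: ModelConfig) -> np.ndarray:
    """Internal per-cycle transition matrices, shape (K, S, S).

    Internal state order: RF, DR, AML, CHF tenure substates (one per cycle of
    the first year in CHF, then a terminal "later" substate), DEAD.
    """
    spec = config.stratum(branch.stratum_id)
    dt = config.cycle_length_years
    K = config.n_cycles(spec)
    cl = config.clinical
    ct = branch.receives_ct

    ages = spec.start_age + dt * np.arange(K)
    p_bg = cv.annual_to_cycle_prob(config.life_table.lookup_array(ages), dt)
    p_rf_dr = np.full(
        K,
        cv.cycle_prob_from_survival(
            spec.recurrence.prob(branch.rs_context, branch.treatment),
            _RECURRENCE_HORIZON_YEARS,
            dt,
        ),
    )
    if ct:
        in_window = (
            np.ones(K, dtype=bool)
            if cl.aml_risk_window_years is None
            else (dt * np.arange(K) < cl.aml_risk_window_years)
        )
        p_aml = np.where(in_window, _rescale_cycle_prob(cl.aml_cycle_prob, 0.5, dt), 0.0)
    else:
        p_aml = np.zeros(K)
    p_chf = cv.annual_to_cycle_prob(config.chf_incidence_curve.lookup_array(ages), dt)
    if ct:
        p_chf = cv.rescale_prob_hr(p_chf, cl.chf_rr_ct)
    p_dr_death = np.maximum(p_bg, cv.cycle_prob_from_median(cl.dr_median_os_months, dt))
    if cl.aml_5yr_death_prob >= 1.0:
        p_aml_death = np.ones(K)
    else:
        p_aml_death = np.maximum(
            p_bg,
            cv.cycle_prob_from_survival(
                1.0 - cl.aml_5yr_death_prob, _AML_SURVIVAL_HORIZON_YEARS, dt
            ),
        )
    p_bg_c = np.minimum(p_bg, _CLIP)
    p_chf_death_y1 = cv.rescale_prob_hr(p_bg_c, cl.chf_excess_hr_year1)
    p_chf_death_late = cv.rescale_prob_hr(p_bg_c, cl.chf_excess_hr_later)

    n_first = _n_first_year_cycles(dt)
    n_chf = n_first + 1  # tenure substates: entry cycle .. last first-year cycle, then "later"
    S = 3 + n_chf + 1
    i_rf, i_dr, i_aml = 0, 1, 2
    i_chf0 = 3
    i_late = 3 + n_chf - 1
    i_dead = S - 1

    M = np.zeros((K, S, S))

    # RF row: competing DR / AML / CHF / death
    rf = _compete(np.stack([p_rf_dr, p_aml, p_chf, p_bg], axis=-1))
    M[:, i_rf, i_dr] = rf[:, 0]
    M[:, i_rf, i_aml] = rf[:, 1]
    M[:, i_rf, i_chf0] = rf[:, 2]
    M[:, i_rf, i_dead] = rf[:, 3]
    M[:, i_rf, i_rf] = 1.0 - rf.sum(axis=-1)

    # DR row: competing AML / CHF / death (toxicity transitions togglable)
    dr_aml = p_aml if cl.dr_toxicity else np.zeros(K)
    dr_chf = p_chf if cl.dr_toxicity else np.zeros(K)
    dr = _compete(np.stack([dr_aml, dr_chf, p_dr_death], axis=-1))
    M[:, i_dr, i_aml] = dr[:, 0]
    M[:, i_dr, i_chf0] = dr[:, 1]
    M[:, i_dr, i_dead] = dr[:, 2]
    M[:, i_dr, i_dr] = 1.0 - dr.sum(axis=-1)

    # AML row: absorbing except death
    M[:, i_aml, i_dead] = p_aml_death
    M[:, i_aml, i_aml] = 1.0 - p_aml_death

    # CHF tenure chain
    for j in range(n_chf):
        s = i_chf0 + j
        q = p_chf_death_y1 if j < n_first else p_chf_death_late
        nxt = min(s + 1, i_late)
        M[:, s, i_dead] = q
        M[:, s, nxt] += 1.0 - q

    M[:, i_dead, i_dead] = 1.0

    return M


def _collapse(occ_internal: np.ndarray, n_chf: int) -> np.ndarray:
    """Collapse internal occupancy (…, S) to the five reporting states."""
    out = np.empty(occ_internal.shape[:-1] + (5,))
    out[..., RF] = occ_internal[..., 0]
    out[..., DR] = occ_internal[..., 1]
    out[..., AML] = occ_internal[..., 2]
    out[..., CHF] = occ_internal[..., 3 : 3 + n_chf].sum(axis=-1)
    out[..., DEAD] = occ_internal[..., -1]
    return out


def build_transition_matrix(
    branch: Branch,
    cycle_index: int,
    config: ModelConfig,
    chf_tenure: str = "later",
) -> np.ndarray:
    """Collapsed 5×5 transition matrix for one cycle.

    Because CHF mortality depends on tenure, the CHF row needs a tenure
    assumption: ``chf_tenure`` is ``"first_year"`` or ``"later"``.
    """
    if chf_tenure not in ("first_year", "later"):
        raise ValueError("chf_tenure must be 'first_year' or 'later'")
    Mi = build_cycle_matrices(branch, config)[cycle_index]
    dt = config.cycle_length_years
    n_chf = _n_first_year_cycles(dt) + 1
    i_chf0, i_late, i_dead = 3, 3 + n_chf - 1, Mi.shape[0] - 1
    chf_row_src = i_chf0 if chf_tenure == "first_year" else i_late

    M = np.zeros((5, 5))
    col_map = [0, 1, 2] + [3] * n_chf + [4]
    for i_int, i_col in ((0, RF), (1, DR), (2, AML), (chf_row_src, CHF), (i_dead, DEAD)):
        for j_int in range(Mi.shape[0]):
            M[i_col, col_map[j_int]] += Mi[i_int, j_int]

    rows = M.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-12):
        raise AssertionError(f"transition-matrix rows do not sum to 1: {rows}")
    if np.any(M < -1e-15) or np.any(M > 1.0 + 1e-12):
        raise AssertionError("transition-matrix entries outside [0, 1]")
    return M


def run_branch(branch: Branch, config: ModelConfig) -> CohortTrace:
    """Cohort-trace recursion for one branch over its full horizon."""
    spec = config.stratum(branch.stratum_id)
    dt = config.cycle_length_years
    K = config.n_cycles(spec)
    M = build_cycle_matrices(branch, config)
    S = M.shape[1]
    n_chf = _n_first_year_cycles(dt) + 1
    i_chf0, i_dead = 3, S - 1

    occ = np.zeros((K + 1, S))
    occ[0, 0] = 1.0
    incidence = np.zeros((K, 4))
    for k in range(K):
        row = occ[k]
        nxt = row @ M[k]
        occ[k + 1] = nxt
        Mk = M[k]
        incidence[k, 0] = row[0] * Mk[0, 1]  # new DR
        incidence[k, 1] = row[0] * Mk[0, 2] + row[1] * Mk[1, 2]  # new AML
        incidence[k, 2] = row[0] * Mk[0, i_chf0] + row[1] * Mk[1, i_chf0]  # new CHF
        incidence[k, 3] = nxt[i_dead] - row[i_dead]  # deaths

    ages = spec.start_age + dt * np.arange(K + 1)
    return CohortTrace(
        branch=branch,
        occupancy=_collapse(occ, n_chf),
        incidence=incidence,
        ages=ages,
        cycle_length_years=dt,
        occupancy_internal=occ,
    )


def half_cycle_occupancy(trace: CohortTrace) -> np.ndarray:
    """Effective per-cycle occupancy: mean of cycle-start and cycle-end rows."""
    return 0.5 * (trace.occupancy[:-1] + trace.occupancy[1:])


def write_trace_csv(trace: CohortTrace, path) -> None:
    """One row per cycle boundary with occupancy; incidence columns refer to
    the cycle that starts at that row's age (empty on the final row)."""
    K = trace.n_cycles
    df = pd.DataFrame(trace.occupancy, columns=[f"occ_{s.lower()}" for s in STATES])
    df.insert(0, "age", trace.ages)
    df.insert(0, "cycle", np.arange(K + 1))
    for j, name in enumerate(("new_dr", "new_aml", "new_chf", "new_death")):
        col = np.full(K + 1, np.nan)
        col[:K] = trace.incidence[:, j]
        df[name] = col
    df.to_csv(path, index=False)
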