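"""Probability/rate arithmetic shared by all model stages.

All manipulations happen on the hazard (log-survival) scale so that
probabilities never leave [0, 1] regardless of the magnitudes involved.
Every function accepts scalars or numpy arrays and broadcasts.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "cycle_prob_from_survival",
    "cycle_prob_from_median",
    "rescale_prob_hr",
    "annual_to_cycle_prob",
    "prob_to_rate",
    "rate_to_prob",
    "discount_factor",
]


def prob_to_rate(p, period_years: float = 1.0):
    """Instantaneous event rate implied by probability *p* over *period_years*."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probability must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        r = -np.log1p(-p) / period_years
    return r if r.ndim else float(r)


def rate_to_prob(rate, period_years: float = 1.0):
    """Event probability over *period_years* under constant rate *rate*."""
    rate = np.asarray(rate, dtype=float)
    p = -np.expm1(-rate * period_years)
    return p if p.ndim else float(p)


def cycle_prob_from_survival(surv_prob, at_years: float, cycle_years: float):
    """Per-cycle event probability under a constant hazard.

    The hazard is calibrated so that the event-free probability at
    ``at_years`` equals ``surv_prob``; the per-cycle probability is then
    ``1 - surv_prob ** (cycle_years / at_years)``.
    """
    if at_years <= 0 or cycle_years <= 0:
        raise ValueError("at_years and cycle_years must be positive")
    s = np.asarray(surv_prob, dtype=float)
    if np.any(s <= 0):
        raise ValueError("survival probability must be > 0 (infinite hazard otherwise)")
    if np.any(s > 1):
        raise ValueError("survival probability must be <= 1")
    p = 1.0 - s ** (cycle_years / at_years)
    return p if p.ndim else float(p)


def cycle_prob_from_median(median_months: float, cycle_years: float) -> float:
    """Per-cycle death probability from an exponential with the given median."""
    if median_months <= 0:
        raise ValueError("median must be positive")
    return float(1.0 - 0.5 ** (12.0 * cycle_years / median_months))


def rescale_prob_hr(p, hr: float):
    """Rescale a probability by a hazard ratio: ``1 - (1 - p) ** hr``."""
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probability must lie in [0, 1]")
    out = 1.0 - (1.0 - p) ** hr
    return out if out.ndim else float(out)


def annual_to_cycle_prob(p_annual, cycle_years: float):
    """Place an annual probability on the model's cycle grid."""
    if cycle_years <= 0:
        raise ValueError("cycle length must be positive")
    p = np.asarray(p_annual, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probability must lie in [0, 1]")
    out = 1.0 - (1.0 - p) ** cycle_years
    return out if out.ndim else float(out)


def discount_factor(t_years, spec):
    """Two-tier discount factor at time *t_years*.

    Flows up to ``spec.switch_year`` are discounted at ``spec.rate_early``;
    beyond that, at ``spec.rate_late`` (compounding on the early-phase factor,
    so the function is continuous at the switch).
    """
    t = np.asarray(t_years, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    sw = spec.switch_year
    early = (1.0 + spec.rate_early) ** (-np.minimum(t, sw))
    late = (1.0 + spec.rate_late) ** (-np.maximum(t - sw, 0.0))
    out = early * late
    return out if out.ndim else float(out)
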