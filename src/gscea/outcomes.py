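"""Aggregation of branch outcomes, strategy comparison, and the deterministic
end-to-end pipeline (decision tree → cohort engine → valuation → comparison).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

from .cohort_engine import CohortTrace, run_branch
from .decision_tree import Branch, branch_weights
from .parameters import ModelConfig, SubPopulationSpec
from .valuation import COST_CATEGORIES, StrategyOutcome, value_branch

__all__ = [
    "ComparisonResult",
    "ModelResult",
    "aggregate",
    "compare",
    "avoided_fraction",
    "run_strategy_stratum",
    "run_strategy",
    "run_model",
]

Status = Literal["dominant", "dominated", "icer"]


@dataclass
class ComparisonResult:
    """Incremental outcomes of the test-guided strategy against standard of care."""

    delta_cost: float
    delta_qaly: float
    delta_ly: float
    status: Status
    nmb: float
    wtp: float
    icer_value: Optional[float] = None
    ct_avoided: float = 0.0
    aml_avoided: float = 0.0
    chf_avoided: float = 0.0

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "delta_ly": self.delta_ly,
            "status": self.status,
            "icer": self.icer_value,
            "nmb": self.nmb,
            "wtp": self.wtp,
            "ct_avoided": self.ct_avoided,
            "aml_avoided": self.aml_avoided,
            "chf_avoided": self.chf_avoided,
        }


def aggregate(
    outcomes: Sequence[StrategyOutcome], weights: Sequence[float]
) -> StrategyOutcome:
    """Weight-average outcomes (branch → stratum, or stratum → population)."""
    if len(outcomes) != len(weights):
        raise ValueError("outcomes and weights must have the same length")
    total = sum(weights)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"aggregation weights must sum to 1, got {total:.8f}")
    costs = {
        c: sum(w * o.costs_by_category[c] for o, w in zip(outcomes, weights))
        for c in COST_CATEGORIES
    }
    return StrategyOutcome(
        costs_by_category=costs,
        ly=sum(w * o.ly for o, w in zip(outcomes, weights)),
        qaly=sum(w * o.qaly for o, w in zip(outcomes, weights)),
        ct_proportion=sum(w * o.ct_proportion for o, w in zip(outcomes, weights)),
        aml_proportion=sum(w * o.aml_proportion for o, w in zip(outcomes, weights)),
        chf_proportion=sum(w * o.chf_proportion for o, w in zip(outcomes, weights)),
    )


def avoided_fraction(soc_rate: float, odx_rate: float) -> float:
    """Relative reduction ``1 - odx/soc``; 0 when the reference rate is 0."""
    if not (0.0 <= soc_rate <= 1.0 and 0.0 <= odx_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    if soc_rate == 0.0:
        return 0.0
    return 1.0 - odx_rate / soc_rate


def compare(odx: StrategyOutcome, soc: StrategyOutcome, wtp: float) -> ComparisonResult:
    """Incremental comparison (test-guided minus standard of care).

    ICER values are reported only when one strategy is more effective and
    more costly (or less of both); otherwise the result is classified as
    dominant/dominated and no ICER is computed.
    """
    dc = odx.total_cost - soc.total_cost
    dq = odx.qaly - soc.qaly
    dl = odx.ly - soc.ly
    nmb = wtp * dq - dc
    if dc < 0 and dq > 0:
        status: Status = "dominant"
        icer = None
    elif dc > 0 and dq < 0:
        status = "dominated"
        icer = None
    else:
        status = "icer"
        if dq == 0.0:
            icer = 0.0 if dc == 0.0 else math.copysign(math.inf, dc)
        else:
            icer = dc / dq
    return ComparisonResult(
        delta_cost=dc,
        delta_qaly=dq,
        delta_ly=dl,
        status=status,
        nmb=nmb,
        wtp=wtp,
        icer_value=icer,
        ct_avoided=avoided_fraction(soc.ct_proportion, odx.ct_proportion),
        aml_avoided=avoided_fraction(soc.aml_proportion, odx.aml_proportion),
        chf_avoided=avoided_fraction(soc.chf_proportion, odx.chf_proportion),
    )


# ---------------------------------------------------------------------------
# Deterministic pipeline
# ---------------------------------------------------------------------------


def run_strategy_stratum(
    spec: SubPopulationSpec,
    strategy: str,
    config: ModelConfig,
    collect_traces: bool = False,
) -> Tuple[StrategyOutcome, List[Tuple[Branch, CohortTrace]]]:
    """Run and weight-average all branches of one stratum under one strategy."""
    branches = branch_weights(spec, strategy)
    traces = []
    outs = []
    for b in branches:
        trace = run_branch(b, config)
        outs.append(value_branch(trace, b, config))
        if collect_traces:
            traces.append((b, trace))
    return aggregate(outs, [b.weight for b in branches]), traces


@dataclass
class ModelResult:
    """Full deterministic model run: outcomes and comparisons at both levels."""

    config: ModelConfig = field(repr=False)
    stratum_outcomes: Dict[str, Dict[str, StrategyOutcome]]  # id -> strategy -> outcome
    population_outcomes: Dict[str, StrategyOutcome]  # strategy -> outcome
    stratum_comparisons: Dict[str, ComparisonResult]
    population_comparison: ComparisonResult
    traces: Optional[Dict[str, List[Tuple[Branch, CohortTrace]]]] = None

    def summary_dict(self) -> dict:
        def outcome_dict(o: StrategyOutcome) -> dict:
            return {
                "costs_by_category": dict(o.costs_by_category),
                "total_cost": o.total_cost,
                "ly": o.ly,
                "qaly": o.qaly,
                "ct_proportion": o.ct_proportion,
                "aml_proportion": o.aml_proportion,
                "chf_proportion": o.chf_proportion,
            }

        return {
            "population": {
                "outcomes": {s: outcome_dict(o) for s, o in self.population_outcomes.items()},
                "comparison": self.population_comparison.to_dict(),
            },
            "strata": {
                sid: {
                    "outcomes": {s: outcome_dict(o) for s, o in per.items()},
                    "comparison": self.stratum_comparisons[sid].to_dict(),
                }
                for sid, per in self.stratum_outcomes.items()
            },
        }


def run_strategy(
    config: ModelConfig, strategy: str, collect_traces: bool = False
) -> Tuple[StrategyOutcome, Dict[str, StrategyOutcome], Dict]:
    """Run one strategy over every stratum; returns population and per-stratum
    outcomes (plus traces when requested)."""
    per_stratum: Dict[str, StrategyOutcome] = {}
    traces: Dict[str, List] = {}
    for sp in config.subpopulations:
        out, tr = run_strategy_stratum(sp, strategy, config, collect_traces=collect_traces)
        per_stratum[sp.id] = out
        if collect_traces:
            traces[sp.id] = tr
    pop = aggregate(
        [per_stratum[sp.id] for sp in config.subpopulations],
        [sp.weight for sp in config.subpopulations],
    )
    return pop, per_stratum, traces


def run_model(config: ModelConfig, collect_traces: bool = False) -> ModelResult:
    """Full deterministic base run: both strategies, both aggregation levels."""
    pop_odx, strata_odx, traces_odx = run_strategy(config, "ODX", collect_traces)
    pop_soc, strata_soc, traces_soc = run_strategy(config, "SOC", collect_traces)
    stratum_outcomes = {
        sp.id: {"ODX": strata_odx[sp.id], "SOC": strata_soc[sp.id]}
        for sp in config.subpopulations
    }
    traces = None
    if collect_traces:
        traces = {
            f"{sid}_{strategy}": trs
            for strategy, all_traces in (("ODX", traces_odx), ("SOC", traces_soc))
            for sid, trs in all_traces.items()
        }
    return ModelResult(
        config=config,
        stratum_outcomes=stratum_outcomes,
        population_outcomes={"ODX": pop_odx, "SOC": pop_soc},
        stratum_comparisons={
            sid: compare(per["ODX"], per["SOC"], config.wtp)
            for sid, per in stratum_outcomes.items()
        },
        population_comparison=compare(pop_odx, pop_soc, config.wtp),
        traces=traces,
    )
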