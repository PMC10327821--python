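"""Treatment-allocation stage: split each stratum, under each strategy, into
weighted (RS category × treatment) branches.

Each branch is carried through the Markov stage as its own homogeneous
cohort and results are weight-averaged afterwards.
"""

from __future__ import annotations

from typing import List, Literal

from pydantic import BaseModel, ConfigDict, Field

from .parameters import ModelConfig, RSShares, SubPopulationSpec

__all__ = ["Branch", "effective_rs_shares", "branch_weights", "ct_probability", "STRATEGIES"]

STRATEGIES = ("ODX", "SOC")

Strategy = Literal["ODX", "SOC"]
RsContext = Literal["rs_lt16", "rs_mid", "rs_gt25", "soc"]
Treatment = Literal["ET", "ET_CT"]

_WEIGHT_EPS = 1e-12


class Branch(BaseModel):
    """An atomic modelled cohort within a (stratum, strategy) pair."""

    model_config = ConfigDict(frozen=True)

    stratum_id: str
    strategy: Strategy
    rs_context: RsContext
    treatment: Treatment
    weight: float = Field(gt=0.0, le=1.0)

    @property
    def receives_ct(self) -> bool:
        return self.treatment == "ET_CT"


def effective_rs_shares(spec: SubPopulationSpec) -> RSShares:
    """Normalized RS-category shares for a stratum.

    The middle share is always derived as the complement of the <16 and >25
    shares: this resolves the premenopausal table inconsistency (the printed
    middle figure there is a cumulative value) and is a no-op for strata
    whose printed shares already sum to 1.
    """
    lt16, gt25 = spec.rs_shares.lt16, spec.rs_shares.gt25
    mid = 1.0 - lt16 - gt25
    if mid < -1e-9:
        raise ValueError(f"{spec.id}: rs shares normalize to a negative middle share")
    return RSShares(lt16=lt16, mid=max(mid, 0.0), gt25=gt25)


def branch_weights(spec: SubPopulationSpec, strategy: Strategy) -> List[Branch]:
    """All non-zero-weight branches of a stratum under one strategy.

    Under the test-guided strategy each RS category with share ``s`` and CT
    probability ``q`` yields an ET+CT branch of weight ``s*q`` and an ET
    branch of weight ``s*(1-q)``. Under standard of care the stratum splits
    only by its overall CT probability.
    """
    branches: List[Branch] = []
    if strategy == "SOC":
        q = spec.soc_ct_prob
        for treatment, w in (("ET_CT", q), ("ET", 1.0 - q)):
            if w > _WEIGHT_EPS:
                branches.append(
                    Branch(
                        stratum_id=spec.id,
                        strategy="SOC",
                        rs_context="soc",
                        treatment=treatment,
                        weight=w,
                    )
                )
        return branches

    shares = effective_rs_shares(spec)
    for context, share in (
        ("rs_lt16", shares.lt16),
        ("rs_mid", shares.mid),
        ("rs_gt25", shares.gt25),
    ):
        if share <= _WEIGHT_EPS:
            continue
        q = spec.ct_prob_by_rs.get(context, 0.0)
        for treatment, w in (("ET_CT", share * q), ("ET", share * (1.0 - q))):
            if w > _WEIGHT_EPS:
                branches.append(
                    Branch(
                        stratum_id=spec.id,
                        strategy="ODX",
                        rs_context=context,
                        treatment=treatment,
                        weight=w,
                    )
                )
    return branches


def ct_probability(spec: SubPopulationSpec, strategy: Strategy) -> float:
    """Proportion of the stratum receiving chemotherapy under a strategy."""
    return sum(b.weight for b in branch_weights(spec, strategy) if b.receives_ct)


def population_ct_probability(config: ModelConfig, strategy: Strategy) -> float:
    """Stratum-weight-averaged CT probability for the whole target population."""
    return sum(sp.weight * ct_probability(sp, strategy) for sp in config.subpopulations)
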