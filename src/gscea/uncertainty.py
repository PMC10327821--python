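"""Sensitivity and scenario analysis.

One-way deterministic sensitivity analysis over a scalar-parameter registry,
probabilistic sensitivity analysis with seeded, per-parameter child RNG
streams, acceptability-curve computation, and a deep-merge scenario runner.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel

from .outcomes import ComparisonResult, run_model
from .parameters import ModelConfig, load_config, config_to_dict
from .synthetic_inputs import PsaSpec, default_psa_spec

logger = logging.getLogger("gscea")

__all__ = [
    "RegistryEntry",
    "parameter_registry",
    "get_param",
    "set_param",
    "DsaResult",
    "PsaResult",
    "CeacCurve",
    "run_dsa",
    "run_psa",
    "ceac",
    "apply_overrides",
    "run_scenario",
]


# ---------------------------------------------------------------------------
# Dotted-path access into a ModelConfig
# ---------------------------------------------------------------------------


def _walk(config: ModelConfig, tokens: Sequence[str]):
    node = config
    for tok in tokens:
        if isinstance(node, list):
            match = [x for x in node if getattr(x, "id", None) == tok]
            if not match:
                raise KeyError(f"no list element with id {tok!r}")
            node = match[0]
        elif isinstance(node, dict):
            node = node[tok]
        else:
            node = getattr(node, tok)
    return node


def get_param(config: ModelConfig, path: str) -> float:
    """Read a scalar parameter by dotted path (list elements matched by id)."""
    return _walk(config, path.split("."))


def set_param(config: ModelConfig, path: str, value: float) -> None:
    """Set a scalar parameter by dotted path, in place."""
    *head, leaf = path.split(".")
    parent = _walk(config, head)
    if isinstance(parent, dict):
        if leaf not in parent:
            raise KeyError(f"{path}: no key {leaf!r}")
        parent[leaf] = value
    else:
        if not hasattr(parent, leaf):
            raise KeyError(f"{path}: no field {leaf!r}")
        object.__setattr__(parent, leaf, value)


@dataclass(frozen=True)
class RegistryEntry:
    """One scalar model parameter addressable in DSA/PSA."""

    path: str
    kind: str  # probability | utility | cost | ratio | scale

    def get(self, config: ModelConfig) -> float:
        return get_param(config, self.path)

    def set(self, config: ModelConfig, value: float) -> None:
        set_param(config, self.path, value)


_CLINICAL = [
    ("clinical.aml_cycle_prob", "probability"),
    ("clinical.chf_rr_ct", "ratio"),
    ("clinical.dr_median_os_months", "scale"),
    ("clinical.aml_5yr_death_prob", "probability"),
    ("clinical.chf_excess_hr_year1", "ratio"),
    ("clinical.chf_excess_hr_later", "ratio"),
]
_UTILITIES = [
    ("utilities.u_rf", "utility"),
    ("utilities.u_dr", "utility"),
    ("utilities.u_aml", "utility"),
    ("utilities.u_chf", "utility"),
    ("utilities.france_adjustment", "ratio"),
    ("utilities.ct_decrement", "utility"),
]
_COSTS = [
    ("costs.test_cost", "cost"),
    ("costs.rf_recurring_cost", "cost"),
    ("costs.dr_cdk46_cost", "cost"),
    ("costs.dr_management_cost", "cost"),
    ("costs.aml_oneoff_cost", "cost"),
    ("costs.aml_recurring_cost", "cost"),
    ("costs.chf_oneoff_cost", "cost"),
    ("costs.chf_recurring_cost", "cost"),
    ("costs.terminal_cost", "cost"),
]
_STRATUM_COSTS = [
    "rf_year1_cost",
    "ct_addon_cost",
    "sick_leave_cost",
    "transport_ct_cost",
    "transport_et_cost",
    "et_annual_cost",
]


def parameter_registry(config: ModelConfig) -> List[RegistryEntry]:
    """Deterministically ordered registry of all scalar model parameters."""
    entries = [RegistryEntry(p, k) for p, k in _CLINICAL + _UTILITIES + _COSTS]
    for sp in config.subpopulations:
        base = f"subpopulations.{sp.id}"
        entries.append(RegistryEntry(f"{base}.soc_ct_prob", "probability"))
        for cat in sorted(sp.ct_prob_by_rs):
            entries.append(RegistryEntry(f"{base}.ct_prob_by_rs.{cat}", "probability"))
        for ctx in sorted(sp.recurrence.ten_year_rf_prob):
            for tx in sorted(sp.recurrence.ten_year_rf_prob[ctx]):
                entries.append(
                    RegistryEntry(
                        f"{base}.recurrence.ten_year_rf_prob.{ctx}.{tx}", "survival"
                    )
                )
        for cost in _STRATUM_COSTS:
            entries.append(RegistryEntry(f"{base}.{cost}", "cost"))
    return entries


# ---------------------------------------------------------------------------
# Deterministic (one-way) sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class DsaRow:
    param: str
    low: float
    high: float
    delta_cost_low: float
    delta_cost_high: float
    delta_qaly_low: float
    delta_qaly_high: float

    @property
    def swing_cost(self) -> float:
        return abs(self.delta_cost_high - self.delta_cost_low)

    @property
    def swing_qaly(self) -> float:
        return abs(self.delta_qaly_high - self.delta_qaly_low)


@dataclass
class DsaResult:
    base_delta_cost: float
    base_delta_qaly: float
    rows: List[DsaRow]

    def to_frame(self, sort_by: str = "swing_cost") -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "param": r.param,
                    "low": r.low,
                    "high": r.high,
                    "delta_cost_low": r.delta_cost_low,
                    "delta_cost_high": r.delta_cost_high,
                    "delta_qaly_low": r.delta_qaly_low,
                    "delta_qaly_high": r.delta_qaly_high,
                    "swing_cost": r.swing_cost,
                    "swing_qaly": r.swing_qaly,
                }
                for r in self.rows
            ]
        )
        return df.sort_values(sort_by, ascending=False).reset_index(drop=True)


def _clamp_bound(value: float, kind: str, path: str) -> float:
    if kind in ("probability", "utility") and value > 1.0:
        logger.warning("DSA: %s bound %.4f clamped to 1", path, value)
        return 1.0
    if value < 0.0:
        logger.warning("DSA: %s bound %.4f clamped to 0", path, value)
        return 0.0
    return value


def run_dsa(
    config: ModelConfig,
    ranges: Optional[Dict[str, Tuple[float, float]]] = None,
    params: Optional[Sequence[str]] = None,
    range_frac: float = 0.20,
) -> DsaResult:
    """One-way DSA: re-run the deterministic pipeline at each parameter's low
    and high bound (default ±``range_frac`` around base, clamped to domain)."""
    ranges = ranges or {}
    base_result = run_model(config).population_comparison
    registry = parameter_registry(config)
    if params is not None:
        wanted = set(params)
        registry = [e for e in registry if e.path in wanted]
        missing = wanted - {e.path for e in registry}
        if missing:
            raise KeyError(f"unknown DSA parameters: {sorted(missing)}")

    rows: List[DsaRow] = []
    for entry in registry:
        base = entry.get(config)
        if entry.path in ranges:
            lo, hi = ranges[entry.path]
            if not (lo <= base <= hi):
                raise ValueError(f"DSA range for {entry.path} does not bracket base {base}")
        elif entry.kind == "survival":
            # Survival-type inputs are varied ±range_frac on the implied
            # constant event hazard, keeping bounds inside (0, 1): a
            # probability-scale ±20% would clamp to 1 (zero recurrence).
            lo, hi = base ** (1.0 + range_frac), base ** (1.0 - range_frac)
        else:
            if base == 0.0:
                continue  # ±20% of zero is a zero-width range
            lo, hi = base * (1.0 - range_frac), base * (1.0 + range_frac)
        lo = _clamp_bound(lo, entry.kind, entry.path)
        hi = _clamp_bound(hi, entry.kind, entry.path)
        results = []
        for bound in (lo, hi):
            cfg = config.copy_deep()
            entry.set(cfg, bound)
            results.append(run_model(cfg).population_comparison)
        rows.append(
            DsaRow(
                param=entry.path,
                low=lo,
                high=hi,
                delta_cost_low=results[0].delta_cost,
                delta_cost_high=results[1].delta_cost,
                delta_qaly_low=results[0].delta_qaly,
                delta_qaly_high=results[1].delta_qaly,
            )
        )
    return DsaResult(
        base_delta_cost=base_result.delta_cost,
        base_delta_qaly=base_result.delta_qaly,
        rows=rows,
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

_DOMAIN = {
    "probability": (0.0, 1.0),
    "survival": (0.0, 1.0),
    "utility": (0.0, 1.0),
    "cost": (0.0, float("inf")),
    "ratio": (0.0, float("inf")),
    "scale": (0.0, float("inf")),
}


@dataclass
class PsaResult:
    """Incremental (cost, QALY, NMB) per PSA draw plus run metadata."""

    draws: np.ndarray  # (n, 3): delta_cost, delta_qaly, nmb
    seed: int
    wtp: float
    n_resampled: int = 0

    @property
    def n(self) -> int:
        return self.draws.shape[0]

    @property
    def delta_cost(self) -> np.ndarray:
        return self.draws[:, 0]

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.draws[:, 1]

    @property
    def nmb(self) -> np.ndarray:
        return self.draws[:, 2]

    def summary(self) -> dict:
        mean_dc = float(self.delta_cost.mean())
        mean_dq = float(self.delta_qaly.mean())
        if mean_dc < 0 and mean_dq > 0:
            prob_icer: Optional[float] = None
            status = "dominant"
        elif mean_dc > 0 and mean_dq < 0:
            prob_icer = None
            status = "dominated"
        else:
            prob_icer = mean_dc / mean_dq if mean_dq != 0.0 else None
            status = "icer"
        return {
            "n": self.n,
            "seed": self.seed,
            "wtp": self.wtp,
            "mean_delta_cost": mean_dc,
            "mean_delta_qaly": mean_dq,
            "status": status,
            "probabilistic_icer": prob_icer,
            "fraction_dominant": float(
                np.mean((self.delta_cost < 0) & (self.delta_qaly > 0))
            ),
            "fraction_cost_effective_at_wtp": float(np.mean(self.nmb > 0)),
            "n_resampled": self.n_resampled,
        }

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=["delta_cost", "delta_qaly", "nmb"])
        df.insert(0, "draw", np.arange(self.n))
        return df


def _sample_all(
    spec: PsaSpec, n: int, seed: int, kind_by_path: Dict[str, str]
) -> Tuple[Dict[str, np.ndarray], int]:
    """Sample every distribution; out-of-domain scalar draws are resampled
    from deterministic follow-up streams (counted)."""
    samples: Dict[str, np.ndarray] = {}
    n_resampled = 0
    for dist in spec.dists:
        x = dist.sample(n, seed)
        if dist.family in ("beta", "gamma", "lognormal"):
            kind = kind_by_path.get(dist.targets[0])
            if kind is not None:
                lo, hi = _DOMAIN[kind]
                for round_ in range(1, 51):
                    bad = (x < lo) | (x > hi)
                    if not bad.any():
                        break
                    n_resampled += int(bad.sum())
                    logger.info(
                        "PSA: resampling %d out-of-domain draws of %s", bad.sum(), dist.name
                    )
                    redraw = dist.sample(n, seed + round_)
                    x = np.where(bad, redraw, x)
                else:
                    raise RuntimeError(f"PSA: cannot sample {dist.name} within domain")
        samples[dist.name] = x
    return samples, n_resampled


def run_psa(
    config: ModelConfig,
    spec: Optional[PsaSpec] = None,
    n: int = 5000,
    seed: int = 0,
) -> PsaResult:
    """Joint-sampling PSA: each draw re-runs the full deterministic pipeline.

    Per-parameter RNG streams are derived from (seed, hash(parameter name)),
    so adding or removing a parameter does not perturb the others' draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or default_psa_spec(config)
    kind_by_path = {e.path: e.kind for e in parameter_registry(config)}
    samples, n_resampled = _sample_all(spec, n, seed, kind_by_path)

    draws = np.empty((n, 3))
    for i in range(n):
        cfg = config.copy_deep()
        for dist in spec.dists:
            x = samples[dist.name]
            if dist.family == "dirichlet":
                for j, target in enumerate(dist.targets):
                    set_param(cfg, target, float(x[i, j]))
            else:
                set_param(cfg, dist.targets[0], float(x[i]))
        comp = run_model(cfg).population_comparison
        draws[i] = (comp.delta_cost, comp.delta_qaly, comp.nmb)
    return PsaResult(draws=draws, seed=seed, wtp=config.wtp, n_resampled=n_resampled)


class CeacCurve(BaseModel):
    """Probability of positive net benefit over a willingness-to-pay grid."""

    wtp: List[float]
    probability: List[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})


def ceac(result: PsaResult, wtp_grid: Sequence[float]) -> CeacCurve:
    """Cost-effectiveness acceptability curve from PSA draws."""
    if result.n == 0:
        raise ValueError("PSA result has no draws")
    grid = list(wtp_grid)
    probs = [
        float(np.mean(lam * result.delta_qaly - result.delta_cost > 0.0)) for lam in grid
    ]
    return CeacCurve(wtp=grid, probability=probs)


# ---------------------------------------------------------------------------
# Scenario runner
# ---------------------------------------------------------------------------


def _deep_merge(base: dict, overrides: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in overrides.items():
        if key == "population" and isinstance(val, dict):
            # {stratum_id: partial-spec} merges into the matching list entry
            for sid, partial in val.items():
                matched = False
                for i, entry in enumerate(out["population"]):
                    if entry["id"] == sid:
                        out["population"][i] = _deep_merge(entry, partial)
                        matched = True
                if not matched:
                    raise KeyError(f"scenario overrides unknown stratum {sid!r}")
        elif isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def apply_overrides(base: ModelConfig, overrides: dict) -> ModelConfig:
    """Deep-merge a partial configuration document onto a base config."""
    doc = config_to_dict(base, inline_curves=True)
    return load_config(_deep_merge(doc, overrides))


def run_scenario(base: ModelConfig, overrides: dict) -> ComparisonResult:
    """Re-run the deterministic pipeline under a scenario's overrides."""
    return run_model(apply_overrides(base, overrides)).population_comparison
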