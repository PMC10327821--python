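"""Synthetic stand-ins for external model inputs that ship with no dataset.

Provides a Gompertz–Makeham female life table, an age-declining utility
multiplier curve, an age-increasing chronic-heart-failure incidence curve,
and default parameter-uncertainty distributions for probabilistic
sensitivity analysis. All are configurable and replaceable by user CSVs.
"""

from __future__ import annotations

import hashlib
import math
from pathlib import Path
from typing import TYPE_CHECKING, Dict, List, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import ModelConfig

__all__ = [
    "LifeTable",
    "AgeCurve",
    "ParamDist",
    "PsaSpec",
    "make_life_table",
    "make_age_utility_multiplier",
    "make_chf_incidence",
    "default_psa_spec",
    "life_expectancy",
    "calibrate_life_table",
]

# Calibrated so that female life expectancy at birth is ~85 years
# (France-like); see calibrate_life_table.
DEFAULT_MAKEHAM_A = 5e-5
DEFAULT_GOMPERTZ_B = 5.57e-6
DEFAULT_GOMPERTZ_C = 0.11


class LifeTable(BaseModel):
    """Annual death probabilities by single year of age.

    The table closes: the probability at the final age is 1.
    """

    entries: Dict[int, float]

    @model_validator(mode="after")
    def _check(self) -> "LifeTable":
        if not self.entries:
            raise ValueError("life table must have at least one entry")
        ages = sorted(self.entries)
        for a in ages:
            q = self.entries[a]
            if not (0.0 < q <= 1.0):
                raise ValueError(f"death probability at age {a} must be in (0, 1], got {q}")
        if self.entries[ages[-1]] != 1.0:
            raise ValueError("life table must close with probability 1 at the final age")
        return self

    @property
    def max_age(self) -> int:
        return max(self.entries)

    @property
    def min_age(self) -> int:
        return min(self.entries)

    def lookup(self, age: float) -> float:
        """Annual death probability applying to [age, age+1); clamped to range."""
        a = int(math.floor(age))
        a = min(max(a, self.min_age), self.max_age)
        return self.entries[a]

    def lookup_array(self, ages: np.ndarray) -> np.ndarray:
        amin, amax = self.min_age, self.max_age
        table = np.array([self.entries[a] for a in range(amin, amax + 1)])
        idx = np.clip(np.floor(ages).astype(int), amin, amax) - amin
        return table[idx]

    def to_frame(self) -> pd.DataFrame:
        ages = sorted(self.entries)
        return pd.DataFrame(
            {"age": ages, "annual_death_prob": [self.entries[a] for a in ages]}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(entries=dict(zip(df["age"].astype(int), df["annual_death_prob"])))


class AgeCurve(BaseModel):
    """Step function of age: the value at integer age x applies on [x, x+1)."""

    entries: Dict[int, float]

    @model_validator(mode="after")
    def _check(self) -> "AgeCurve":
        if not self.entries:
            raise ValueError("age curve must have at least one entry")
        if any(v <= 0 for v in self.entries.values()):
            raise ValueError("age-curve values must be positive")
        return self

    @property
    def max_age(self) -> int:
        return max(self.entries)

    @property
    def min_age(self) -> int:
        return min(self.entries)

    def lookup(self, age: float) -> float:
        a = int(math.floor(age))
        a = min(max(a, self.min_age), self.max_age)
        return self.entries[a]

    def lookup_array(self, ages: np.ndarray) -> np.ndarray:
        amin, amax = self.min_age, self.max_age
        table = np.array([self.entries[a] for a in range(amin, amax + 1)])
        idx = np.clip(np.floor(ages).astype(int), amin, amax) - amin
        return table[idx]

    def to_frame(self, value_column: str = "value") -> pd.DataFrame:
        ages = sorted(self.entries)
        return pd.DataFrame({"age": ages, value_column: [self.entries[a] for a in ages]})

    def write_csv(self, path, value_column: str = "value") -> None:
        self.to_frame(value_column).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, value_column: Optional[str] = None) -> "AgeCurve":
        df = pd.read_csv(path, float_precision="round_trip")
        col = value_column or df.columns[1]
        return cls(entries=dict(zip(df["age"].astype(int), df[col])))


def make_life_table(
    makeham_a: float = DEFAULT_MAKEHAM_A,
    gompertz_b: float = DEFAULT_GOMPERTZ_B,
    gompertz_c: float = DEFAULT_GOMPERTZ_C,
    max_age: int = 110,
) -> LifeTable:
    """Gompertz–Makeham life table: hazard(x) = a + b * exp(c * x).

    The annual death probability at age x is ``1 - exp(-(a + b e^{cx}))``
    and the final-age probability is forced to 1 so the table closes.
    """
    if makeham_a < 0:
        raise ValueError("makeham_a must be non-negative")
    if gompertz_b <= 0 or gompertz_c <= 0:
        raise ValueError("gompertz_b and gompertz_c must be positive")
    ages = np.arange(max_age + 1)
    hazard = makeham_a + gompertz_b * np.exp(gompertz_c * ages)
    q = 1.0 - np.exp(-hazard)
    q[-1] = 1.0
    return LifeTable(entries={int(a): float(p) for a, p in zip(ages, q)})


def life_expectancy(table: LifeTable, from_age: int = 0) -> float:
    """Life expectancy by standard life-table summation (trapezoidal l_x)."""
    ages = range(max(from_age, table.min_age), table.max_age + 1)
    survivors = 1.0
    total = 0.0
    for a in ages:
        nxt = survivors * (1.0 - table.entries[a])
        total += 0.5 * (survivors + nxt)
        survivors = nxt
    return total


def calibrate_life_table(
    target_le: float,
    makeham_a: float = DEFAULT_MAKEHAM_A,
    gompertz_c: float = DEFAULT_GOMPERTZ_C,
    max_age: int = 110,
    tol: float = 1e-3,
) -> LifeTable:
    """Find gompertz_b by bisection so life expectancy at birth hits *target_le*."""
    lo, hi = 1e-9, 1e-2
    if not (
        life_expectancy(make_life_table(makeham_a, hi, gompertz_c, max_age))
        < target_le
        < life_expectancy(make_life_table(makeham_a, lo, gompertz_c, max_age))
    ):
        raise ValueError(f"target life expectancy {target_le} not bracketed")
    for _ in range(100):
        mid = math.sqrt(lo * hi)
        table = make_life_table(makeham_a, mid, gompertz_c, max_age)
        le = life_expectancy(table)
        if abs(le - target_le) < tol:
            return table
        if le > target_le:
            lo = mid
        else:
            hi = mid
    return table


def make_age_utility_multiplier(
    anchor_age: int = 43,
    slope_per_year: float = 0.003,
    max_age: int = 110,
    floor: float = 0.5,
) -> AgeCurve:
    """Linear age-related utility decline, normalized to 1 at *anchor_age*.

    Values below the anchor are held at 1 (the model only looks up ages at or
    above each cohort's entry age after re-anchoring).
    """
    if slope_per_year < 0:
        raise ValueError("slope must be non-negative")
    entries = {}
    for age in range(0, max_age + 1):
        v = 1.0 - slope_per_year * max(age - anchor_age, 0)
        entries[age] = max(v, floor)
    return AgeCurve(entries=entries)


def make_chf_incidence(
    base_annual_prob: float = 0.001,
    doubling_years: float = 10.0,
    anchor_age: int = 50,
    max_age: int = 110,
    cap: float = 0.2,
) -> AgeCurve:
    """Exponentially age-increasing annual CHF incidence, capped.

    Annual probability at age x is ``base * 2 ** ((x - anchor) / doubling)``.
    """
    if base_annual_prob <= 0:
        raise ValueError("base probability must be positive")
    if doubling_years <= 0:
        raise ValueError("doubling time must be positive")
    entries = {}
    for age in range(0, max_age + 1):
        v = base_annual_prob * 2.0 ** ((age - anchor_age) / doubling_years)
        entries[age] = min(v, cap)
    return AgeCurve(entries=entries)


# ---------------------------------------------------------------------------
# PSA distribution specification
# ---------------------------------------------------------------------------

Family = Literal["beta", "gamma", "lognormal", "dirichlet", "fixed"]


class ParamDist(BaseModel):
    """Sampling distribution for one parameter (or one dirichlet group).

    ``targets`` holds dotted config paths (see :mod:`gscea.uncertainty`); a
    scalar family has one target, a dirichlet group one per share.
    """

    name: str
    family: Family
    targets: List[str]
    mean: Optional[float] = None
    se: Optional[float] = None
    shares: Optional[List[float]] = None  # dirichlet only
    concentration: float = 400.0  # dirichlet only

    @model_validator(mode="after")
    def _check(self) -> "ParamDist":
        if self.family == "dirichlet":
            if self.shares is None or len(self.shares) != len(self.targets):
                raise ValueError(f"{self.name}: dirichlet needs one share per target")
        elif self.family != "fixed":
            if self.mean is None or self.se is None:
                raise ValueError(f"{self.name}: mean and se required")
            if self.family == "beta":
                m, v = self.mean, self.se**2
                if v >= m * (1 - m):
                    raise ValueError(f"{self.name}: beta variance too large for mean {m}")
        return self

    def _rng(self, seed: int) -> np.random.Generator:
        digest = hashlib.sha256(self.name.encode()).digest()
        child = int.from_bytes(digest[:8], "big")
        return np.random.default_rng([seed, child])

    def sample(self, n: int, seed: int) -> np.ndarray:
        """Draw *n* samples; shape (n,) for scalars, (n, k) for dirichlet groups."""
        rng = self._rng(seed)
        if self.family == "fixed":
            return np.full(n, self.mean if self.mean is not None else 0.0)
        if self.family == "beta":
            m, v = self.mean, self.se**2
            k = m * (1 - m) / v - 1.0
            return rng.beta(m * k, (1 - m) * k, size=n)
        if self.family == "gamma":
            shape = (self.mean / self.se) ** 2
            scale = self.se**2 / self.mean
            return rng.gamma(shape, scale, size=n)
        if self.family == "lognormal":
            sigma2 = math.log(1.0 + (self.se / self.mean) ** 2)
            mu = math.log(self.mean) - sigma2 / 2.0
            return rng.lognormal(mu, math.sqrt(sigma2), size=n)
        # dirichlet
        alpha = np.asarray(self.shares) * self.concentration
        return rng.dirichlet(alpha, size=n)


class PsaSpec(BaseModel):
    """Full PSA specification: one ParamDist per sampled parameter/group."""

    dists: List[ParamDist]

    def names(self) -> List[str]:
        return [d.name for d in self.dists]

    def get(self, name: str) -> ParamDist:
        for d in self.dists:
            if d.name == name:
                return d
        raise KeyError(name)


_DEGENERATE_EPS = 1e-12


def default_psa_spec(
    config: "ModelConfig",
    prob_se_frac: float = 0.10,
    cost_se_frac: float = 0.20,
    ratio_se_frac: float = 0.10,
    concentration: float = 400.0,
) -> PsaSpec:
    """Conventional default distributions for every scalar model parameter.

    Probabilities and utilities get beta distributions (mean = base value,
    SE = 10% of the mean, method of moments); costs get gamma (SE = 20%);
    ratios and positive scales get lognormal (SE = 10%); category-share
    groups get dirichlet with concentration 400. Parameters whose base value
    is 0 or 1 are held fixed.
    """
    from .uncertainty import parameter_registry  # deferred: avoids import cycle

    dists: List[ParamDist] = []
    for entry in parameter_registry(config):
        base = entry.get(config)
        if entry.kind == "survival":
            # Uncertainty lives in the event risk: SE is a fraction of the
            # complement, keeping the implied hazard within plausible range.
            se = prob_se_frac * (1.0 - base)
            if se <= _DEGENERATE_EPS:
                dists.append(
                    ParamDist(name=entry.path, family="fixed", targets=[entry.path], mean=base)
                )
            else:
                dists.append(
                    ParamDist(
                        name=entry.path, family="beta", targets=[entry.path], mean=base, se=se
                    )
                )
        elif entry.kind in ("probability", "utility"):
            if base <= _DEGENERATE_EPS or base >= 1.0 - _DEGENERATE_EPS:
                dists.append(
                    ParamDist(name=entry.path, family="fixed", targets=[entry.path], mean=base)
                )
            else:
                dists.append(
                    ParamDist(
                        name=entry.path,
                        family="beta",
                        targets=[entry.path],
                        mean=base,
                        se=prob_se_frac * base,
                    )
                )
        elif entry.kind == "cost":
            if base <= _DEGENERATE_EPS:
                dists.append(
                    ParamDist(name=entry.path, family="fixed", targets=[entry.path], mean=base)
                )
            else:
                dists.append(
                    ParamDist(
                        name=entry.path,
                        family="gamma",
                        targets=[entry.path],
                        mean=base,
                        se=cost_se_frac * base,
                    )
                )
        elif entry.kind in ("ratio", "scale"):
            dists.append(
                ParamDist(
                    name=entry.path,
                    family="lognormal",
                    targets=[entry.path],
                    mean=base,
                    se=ratio_se_frac * base,
                )
            )
    # dirichlet groups: stratum weights and per-stratum RS shares
    from .decision_tree import effective_rs_shares

    dists.append(
        ParamDist(
            name="population.weights",
            family="dirichlet",
            targets=[f"subpopulations.{sp.id}.weight" for sp in config.subpopulations],
            shares=[sp.weight for sp in config.subpopulations],
            concentration=concentration,
        )
    )
    for sp in config.subpopulations:
        shares = effective_rs_shares(sp)
        names, vals = [], []
        for cat, v in (("lt16", shares.lt16), ("mid", shares.mid), ("gt25", shares.gt25)):
            if v > _DEGENERATE_EPS:
                names.append(f"subpopulations.{sp.id}.rs_shares.{cat}")
                vals.append(v)
        if len(names) >= 2:
            dists.append(
                ParamDist(
                    name=f"subpopulations.{sp.id}.rs_shares",
                    family="dirichlet",
                    targets=names,
                    shares=vals,
                    concentration=concentration,
                )
            )
    return PsaSpec(dists=dists)


def write_synthetic_inputs(
    output_dir,
    life_table: Optional[LifeTable] = None,
    utility_curve: Optional[AgeCurve] = None,
    chf_curve: Optional[AgeCurve] = None,
) -> Dict[str, Path]:
    """Emit the three synthetic curves as CSVs; returns the written paths."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    life_table = life_table or make_life_table()
    utility_curve = utility_curve or make_age_utility_multiplier()
    chf_curve = chf_curve or make_chf_incidence()
    paths = {
        "life_table": out / "life_table.csv",
        "age_utility_curve": out / "age_utility_curve.csv",
        "chf_incidence_curve": out / "chf_incidence_curve.csv",
    }
    life_table.write_csv(paths["life_table"])
    utility_curve.write_csv(paths["age_utility_curve"], value_column="multiplier")
    chf_curve.write_csv(paths["chf_incidence_curve"], value_column="annual_prob")
    return paths
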