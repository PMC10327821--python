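"""Model parameter types, configuration loading/validation, and the embedded
base-case configuration.

A configuration document (YAML or JSON) has six sections — ``population``,
``clinical``, ``utilities``, ``costs``, ``discount``, ``settings`` — plus
optional external curves (life table, age-utility multiplier, CHF incidence)
given either as CSV paths or inline age→value mappings. Missing curves fall
back to the synthetic generators with a logged notice.
"""

from __future__ import annotations

import copy
import hashlib
import io
import json
import logging
from pathlib import Path
from typing import Dict, List, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .synthetic_inputs import (
    AgeCurve,
    LifeTable,
    make_age_utility_multiplier,
    make_chf_incidence,
    make_life_table,
)

logger = logging.getLogger("gscea")

__all__ = [
    "RSShares",
    "RecurrenceInputs",
    "SubPopulationSpec",
    "ClinicalParams",
    "UtilityParams",
    "CostParams",
    "DiscountSpec",
    "ModelConfig",
    "ConfigurationError",
    "load_config",
    "base_case_config",
    "config_to_dict",
    "config_digest",
    "STRATA_IDS",
    "RS_CONTEXTS",
    "TREATMENTS",
]

STRATA_IDS = ("N0_lt50", "N0_ge50", "N1_ge50")
RS_CONTEXTS = ("rs_lt16", "rs_mid", "rs_gt25", "soc")
TREATMENTS = ("ET", "ET_CT")

StratumId = Literal["N0_lt50", "N0_ge50", "N1_ge50"]


class ConfigurationError(Exception):
    """A configuration document is structurally unusable (e.g. missing section)."""


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RSShares(_Base):
    """Recurrence-score category shares within a stratum.

    ``mid`` may be stored as a printed cumulative figure; normalization
    (``mid = 1 - lt16 - gt25``) happens in the decision-tree stage, so the
    only hard requirement here is that ``lt16 + gt25 <= 1``.
    """

    lt16: float = Field(ge=0.0, le=1.0)
    mid: float = Field(ge=0.0, le=1.0)
    gt25: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "RSShares":
        if self.lt16 + self.gt25 > 1.0 + 1e-9:
            raise ValueError("rs_shares: lt16 + gt25 must not exceed 1")
        return self


class RecurrenceInputs(_Base):
    """Ten-year recurrence-free probabilities by (RS context, treatment)."""

    ten_year_rf_prob: Dict[str, Dict[str, float]]

    @model_validator(mode="after")
    def _check(self) -> "RecurrenceInputs":
        for ctx, by_tx in self.ten_year_rf_prob.items():
            if ctx not in RS_CONTEXTS:
                raise ValueError(f"recurrence: unknown context {ctx!r}")
            for tx, p in by_tx.items():
                if tx not in TREATMENTS:
                    raise ValueError(f"recurrence[{ctx}]: unknown treatment {tx!r}")
                if not (0.0 < p <= 1.0):
                    raise ValueError(
                        f"recurrence[{ctx}][{tx}]: probability must be in (0, 1], got {p}"
                    )
        if "soc" not in self.ten_year_rf_prob:
            raise ValueError("recurrence: 'soc' context is required")
        return self

    def prob(self, context: str, treatment: str) -> float:
        try:
            return self.ten_year_rf_prob[context][treatment]
        except KeyError as exc:
            raise KeyError(f"no recurrence input for ({context}, {treatment})") from exc


class SubPopulationSpec(_Base):
    """One population stratum with its decision-tree inputs and costs."""

    id: StratumId
    weight: float = Field(gt=0.0, le=1.0)
    start_age: int = Field(gt=0, lt=100)
    soc_ct_prob: float = Field(ge=0.0, le=1.0)
    rs_shares: RSShares
    ct_prob_by_rs: Dict[str, float]
    recurrence: RecurrenceInputs
    rf_year1_cost: float = Field(ge=0.0)
    ct_addon_cost: float = Field(ge=0.0)
    sick_leave_cost: float = Field(ge=0.0)
    transport_ct_cost: float = Field(ge=0.0)
    transport_et_cost: float = Field(ge=0.0)
    et_annual_cost: float = Field(ge=0.0)

    @model_validator(mode="after")
    def _check(self) -> "SubPopulationSpec":
        for cat, p in self.ct_prob_by_rs.items():
            if cat not in ("rs_lt16", "rs_mid", "rs_gt25"):
                raise ValueError(f"ct_prob_by_rs: unknown category {cat!r}")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"ct_prob_by_rs[{cat}]: must be in [0, 1], got {p}")
        return self


class ClinicalParams(_Base):
    aml_cycle_prob: float = Field(ge=0.0, le=1.0)
    chf_rr_ct: float = Field(gt=0.0)
    dr_median_os_months: float = Field(gt=0.0)
    aml_5yr_death_prob: float = Field(ge=0.0, le=1.0)
    chf_excess_hr_year1: float = Field(default=5.0, gt=0.0)
    chf_excess_hr_later: float = Field(default=2.0, gt=0.0)
    # None means the AML hazard applies to every cycle spent recurrence-free
    # by CT-treated patients (unbounded risk window).
    aml_risk_window_years: Optional[float] = Field(default=None, gt=0.0)
    dr_toxicity: bool = True


class UtilityParams(_Base):
    u_rf: float = Field(ge=0.0, le=1.0)
    u_dr: float = Field(ge=0.0, le=1.0)
    u_aml: float = Field(ge=0.0, le=1.0)
    u_chf: float = Field(ge=0.0, le=1.0)
    france_adjustment: float = Field(default=1.0, gt=0.0)
    ct_decrement: float = Field(ge=0.0)
    ct_decrement_cycles: int = Field(default=1, ge=0)
    apply_france_adjustment: bool = True


RECURRING_ITEMS = ("rf_recurring", "dr_cdk46", "dr_management", "aml_recurring", "chf_recurring")


class CostParams(_Base):
    test_cost: float = Field(ge=0.0)
    rf_recurring_cost: float = Field(ge=0.0)
    dr_cdk46_cost: float = Field(ge=0.0)
    dr_management_cost: float = Field(ge=0.0)
    aml_oneoff_cost: float = Field(ge=0.0)
    aml_recurring_cost: float = Field(ge=0.0)
    chf_oneoff_cost: float = Field(ge=0.0)
    chf_recurring_cost: float = Field(ge=0.0)
    terminal_cost: float = Field(ge=0.0)
    recurring_cost_period: Dict[str, Literal["cycle", "year"]] = Field(
        default_factory=lambda: {
            "rf_recurring": "cycle",
            "dr_cdk46": "year",
            "dr_management": "cycle",
            "aml_recurring": "cycle",
            "chf_recurring": "cycle",
        }
    )

    @model_validator(mode="after")
    def _check(self) -> "CostParams":
        missing = [k for k in RECURRING_ITEMS if k not in self.recurring_cost_period]
        if missing:
            raise ValueError(f"recurring_cost_period missing items: {missing}")
        unknown = [k for k in self.recurring_cost_period if k not in RECURRING_ITEMS]
        if unknown:
            raise ValueError(f"recurring_cost_period has unknown items: {unknown}")
        return self

    def per_cycle(self, item: str, amount: float, cycle_length_years: float) -> float:
        """Amount charged per model cycle given the item's declared period."""
        if self.recurring_cost_period[item] == "year":
            return amount * cycle_length_years
        return amount


class DiscountSpec(_Base):
    rate_early: float = Field(default=0.025, ge=0.0, lt=1.0)
    rate_late: float = Field(default=0.015, ge=0.0, lt=1.0)
    switch_year: float = Field(default=30.0, gt=0.0)


class ModelConfig(_Base):
    subpopulations: List[SubPopulationSpec]
    clinical: ClinicalParams
    utilities: UtilityParams
    costs: CostParams
    discount: DiscountSpec
    wtp: float = Field(default=20_000.0, gt=0.0)
    cycle_length_years: float = Field(default=0.5, gt=0.0)
    max_age: int = Field(default=100, gt=0)
    et_duration_years: float = Field(default=5.0, ge=0.0)
    life_table: LifeTable
    age_utility_curve: AgeCurve
    chf_incidence_curve: AgeCurve

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        if not self.subpopulations:
            raise ValueError("at least one subpopulation is required")
        ids = [sp.id for sp in self.subpopulations]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate subpopulation ids: {ids}")
        total = sum(sp.weight for sp in self.subpopulations)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"subpopulation weights must sum to 1, got {total:.8f}")
        for sp in self.subpopulations:
            horizon = self.max_age - sp.start_age
            if horizon <= 0:
                raise ValueError(f"{sp.id}: start_age must be below max_age")
            n = horizon / self.cycle_length_years
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"{sp.id}: horizon {horizon}y is not a whole number of "
                    f"{self.cycle_length_years}y cycles"
                )
        return self

    def stratum(self, stratum_id: str) -> SubPopulationSpec:
        for sp in self.subpopulations:
            if sp.id == stratum_id:
                return sp
        raise KeyError(stratum_id)

    def n_cycles(self, spec: SubPopulationSpec) -> int:
        return int(round((self.max_age - spec.start_age) / self.cycle_length_years))

    def copy_deep(self) -> "ModelConfig":
        return self.model_copy(deep=True)


# ---------------------------------------------------------------------------
# Embedded base-case document
# ---------------------------------------------------------------------------

BASE_CASE_DOCUMENT: dict = {
    "population": [
        {
            "id": "N0_lt50",
            "weight": 0.412,
            "start_age": 43,
            "soc_ct_prob": 0.608,
            "rs_shares": {"lt16": 0.337, "mid": 0.739, "gt25": 0.271},
            "ct_prob_by_rs": {"rs_lt16": 0.0, "rs_mid": 0.311, "rs_gt25": 1.0},
            "recurrence": {
                "ten_year_rf_prob": {
                    "rs_lt16": {"ET": 0.970, "ET_CT": 0.978},
                    "rs_mid": {"ET": 0.827, "ET_CT": 0.917},
                    "rs_gt25": {"ET": 0.711, "ET_CT": 0.833},
                    "soc": {"ET": 0.844, "ET_CT": 0.915},
                }
            },
            "rf_year1_cost": 3777.0,
            "ct_addon_cost": 2063.0,
            "sick_leave_cost": 6316.0,
            "transport_ct_cost": 2906.0,
            "transport_et_cost": 255.0,
            "et_annual_cost": 91.0,
        },
        {
            "id": "N0_ge50",
            "weight": 0.167,
            "start_age": 64,
            "soc_ct_prob": 0.294,
            "rs_shares": {"lt16": 0.0, "mid": 0.718, "gt25": 0.282},
            "ct_prob_by_rs": {"rs_lt16": 0.0, "rs_mid": 0.0, "rs_gt25": 1.0},
            "recurrence": {
                "ten_year_rf_prob": {
                    "rs_mid": {"ET": 0.904, "ET_CT": 0.908},
                    "rs_gt25": {"ET": 0.702, "ET_CT": 0.783},
                    "soc": {"ET": 0.847, "ET_CT": 0.873},
                }
            },
            "rf_year1_cost": 2973.0,
            "ct_addon_cost": 4479.0,
            "sick_leave_cost": 5235.0,
            "transport_ct_cost": 1738.0,
            "transport_et_cost": 925.0,
            "et_annual_cost": 223.0,
        },
        {
            "id": "N1_ge50",
            "weight": 0.421,
            "start_age": 61,
            "soc_ct_prob": 0.776,
            "rs_shares": {"lt16": 0.0, "mid": 0.829, "gt25": 0.171},
            "ct_prob_by_rs": {"rs_lt16": 0.0, "rs_mid": 0.0, "rs_gt25": 1.0},
            "recurrence": {
                "ten_year_rf_prob": {
                    "rs_mid": {"ET": 0.912, "ET_CT": 0.906},
                    "rs_gt25": {"ET": 0.620, "ET_CT": 0.754},
                    "soc": {"ET": 0.862, "ET_CT": 0.880},
                }
            },
            "rf_year1_cost": 3444.0,
            "ct_addon_cost": 3619.0,
            "sick_leave_cost": 10609.0,
            "transport_ct_cost": 1200.0,
            "transport_et_cost": 337.0,
            "et_annual_cost": 223.0,
        },
    ],
    "clinical": {
        "aml_cycle_prob": 0.0062,
        "chf_rr_ct": 1.61,
        "dr_median_os_months": 63.9,
        "aml_5yr_death_prob": 0.76,
        "chf_excess_hr_year1": 5.0,
        "chf_excess_hr_later": 2.0,
        "aml_risk_window_years": None,
        "dr_toxicity": True,
    },
    "utilities": {
        "u_rf": 0.860,
        "u_dr": 0.715,
        "u_aml": 0.271,
        "u_chf": 0.551,
        "france_adjustment": 1.043,
        "ct_decrement": 0.040,
        "ct_decrement_cycles": 1,
        "apply_france_adjustment": True,
    },
    "costs": {
        "test_cost": 1850.0,
        "rf_recurring_cost": 604.0,
        "dr_cdk46_cost": 14395.0,
        "dr_management_cost": 6516.0,
        "aml_oneoff_cost": 23970.0,
        "aml_recurring_cost": 5806.0,
        "chf_oneoff_cost": 1888.0,
        "chf_recurring_cost": 1148.0,
        "terminal_cost": 4606.0,
    },
    "discount": {"rate_early": 0.025, "rate_late": 0.015, "switch_year": 30.0},
    "settings": {
        "wtp": 20_000.0,
        "cycle_length_years": 0.5,
        "max_age": 100,
        "et_duration_years": 5.0,
    },
}

_REQUIRED_SECTIONS = ("population", "clinical", "utilities", "costs", "discount", "settings")

_CURVE_DEFAULTS = {
    "life_table": (make_life_table, LifeTable, None),
    "age_utility_curve": (make_age_utility_multiplier, AgeCurve, "multiplier"),
    "chf_incidence_curve": (make_chf_incidence, AgeCurve, "annual_prob"),
}


def _resolve_curve(name: str, value, base_dir: Optional[Path]):
    factory, cls, column = _CURVE_DEFAULTS[name]
    if value is None:
        logger.info("config: %s not supplied; using synthetic default", name)
        return factory()
    if isinstance(value, cls):
        return value
    if isinstance(value, dict):
        if "entries" in value:
            value = value["entries"]
        return cls(entries={int(k): float(v) for k, v in value.items()})
    if isinstance(value, (str, Path)):
        path = Path(value)
        if base_dir is not None and not path.is_absolute():
            path = base_dir / path
        if not path.exists():
            raise ConfigurationError(f"{name}: curve file not found: {path}")
        if cls is LifeTable:
            return LifeTable.read_csv(path)
        return AgeCurve.read_csv(path, value_column=column)
    raise ConfigurationError(f"{name}: expected path or age->value mapping, got {type(value)!r}")


def load_config(source) -> ModelConfig:
    """Load and validate a model configuration.

    ``source`` may be a path to a YAML/JSON file, a file-like object, a raw
    YAML/JSON string, or an already-parsed document dict.
    """
    base_dir: Optional[Path] = None
    if isinstance(source, ModelConfig):
        return source
    if isinstance(source, dict):
        doc = copy.deepcopy(source)
    else:
        if isinstance(source, (str, Path)) and (
            isinstance(source, Path) or "\n" not in str(source)
        ):
            path = Path(source)
            if not path.exists():
                raise ConfigurationError(f"config file not found: {path}")
            base_dir = path.parent
            text = path.read_text()
        elif isinstance(source, io.IOBase) or hasattr(source, "read"):
            text = source.read()
        else:
            text = str(source)
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigurationError("configuration document must be a mapping")

    missing = [s for s in _REQUIRED_SECTIONS if s not in doc]
    if missing:
        raise ConfigurationError(f"missing configuration section(s): {', '.join(missing)}")

    settings = dict(doc["settings"])
    curves = {
        name: _resolve_curve(name, settings.pop(name, None), base_dir)
        for name in _CURVE_DEFAULTS
    }
    return ModelConfig(
        subpopulations=doc["population"],
        clinical=doc["clinical"],
        utilities=doc["utilities"],
        costs=doc["costs"],
        discount=doc["discount"],
        **settings,
        **curves,
    )


def base_case_config() -> ModelConfig:
    """The embedded base-case configuration (synthetic curves substituted)."""
    return load_config(BASE_CASE_DOCUMENT)


def config_to_dict(config: ModelConfig, inline_curves: bool = True) -> dict:
    """Serialize a ModelConfig back to the sectioned document form."""
    doc = {
        "population": [sp.model_dump() for sp in config.subpopulations],
        "clinical": config.clinical.model_dump(),
        "utilities": config.utilities.model_dump(),
        "costs": config.costs.model_dump(),
        "discount": config.discount.model_dump(),
        "settings": {
            "wtp": config.wtp,
            "cycle_length_years": config.cycle_length_years,
            "max_age": config.max_age,
            "et_duration_years": config.et_duration_years,
        },
    }
    if inline_curves:
        doc["settings"]["life_table"] = dict(sorted(config.life_table.entries.items()))
        doc["settings"]["age_utility_curve"] = dict(
            sorted(config.age_utility_curve.entries.items())
        )
        doc["settings"]["chf_incidence_curve"] = dict(
            sorted(config.chf_incidence_curve.entries.items())
        )
    return doc


def config_digest(config: ModelConfig) -> str:
    """Stable SHA-256 digest of the fully-resolved configuration."""
    doc = config_to_dict(config, inline_curves=True)
    blob = json.dumps(doc, sort_keys=True, separators=(",", ":")).encode()
    return hashlib.sha256(blob).hexdigest()
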