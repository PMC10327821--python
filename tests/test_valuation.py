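import numpy as np
import pytest

from gscea.cohort_engine import run_branch
from gscea.conversions import discount_factor
from gscea.decision_tree import Branch, branch_weights
from gscea.parameters import base_case_config, config_to_dict, load_config
from gscea.valuation import COST_CATEGORIES, value_branch, value_costs, value_qalys

TINY = 1e-12


def make_branch(stratum_id="N1_ge50", strategy="SOC", rs_context="soc", treatment="ET"):
    return Branch(
        stratum_id=stratum_id,
        strategy=strategy,
        rs_context=rs_context,
        treatment=treatment,
        weight=1.0,
    )


def modified_config(mutate):
    doc = config_to_dict(base_case_config())
    mutate(doc)
    return load_config(doc)


def null_hazard_doc(doc):
    doc["settings"]["life_table"] = {
        **{age: TINY for age in range(0, 110)},
        110: 1.0,
    }
    doc["settings"]["chf_incidence_curve"] = {age: TINY for age in range(0, 111)}
    doc["clinical"]["aml_cycle_prob"] = 0.0
    for sp in doc["population"]:
        for ctx in sp["recurrence"]["ten_year_rf_prob"]:
            for tx in sp["recurrence"]["ten_year_rf_prob"][ctx]:
                sp["recurrence"]["ten_year_rf_prob"][ctx][tx] = 1.0


def neutral_utility_doc(doc):
    doc["utilities"].update(
        u_rf=1.0, u_dr=1.0, u_aml=1.0, u_chf=1.0, ct_decrement=0.0, france_adjustment=1.0
    )
    doc["settings"]["age_utility_curve"] = {age: 1.0 for age in range(0, 111)}


def no_discount_doc(doc):
    doc["discount"].update(rate_early=0.0, rate_late=0.0)


class TestValueQalys:
    def test_qaly_equals_ly_with_unit_utilities(self, base_config):
        cfg = modified_config(neutral_utility_doc)
        for sp in cfg.subpopulations:
            for strategy in ("ODX", "SOC"):
                for b in branch_weights(sp, strategy):
                    trace = run_branch(b, cfg)
                    ly, qaly = value_qalys(trace, b, cfg)
                    assert qaly == pytest.approx(ly, abs=1e-9)

    def test_rf_effective_utility_value(self):
        # all-RF cohort, flat age curve, no discounting: QALY/LY = 0.860 x 1.043
        def mutate(doc):
            null_hazard_doc(doc)
            no_discount_doc(doc)
            doc["settings"]["age_utility_curve"] = {age: 1.0 for age in range(0, 111)}

        cfg = modified_config(mutate)
        branch = make_branch()
        trace = run_branch(branch, cfg)
        ly, qaly = value_qalys(trace, branch, cfg)
        assert qaly / ly == pytest.approx(0.860 * 1.043, abs=1e-9)  # 0.89698

    def test_aml_effective_utility_value(self, base_config):
        u = base_config.utilities
        assert u.u_aml * u.france_adjustment == pytest.approx(0.28266, abs=1e-5)

    def test_france_cap_binds(self):
        def mutate(doc):
            null_hazard_doc(doc)
            no_discount_doc(doc)
            doc["utilities"]["u_rf"] = 0.99  # 0.99 * 1.043 > 1 -> capped
            doc["settings"]["age_utility_curve"] = {age: 1.0 for age in range(0, 111)}

        cfg = modified_config(mutate)
        branch = make_branch()
        trace = run_branch(branch, cfg)
        ly, qaly = value_qalys(trace, branch, cfg)
        assert qaly == pytest.approx(ly, abs=1e-9)

    def test_ct_decrement_lowers_qaly_only_for_ct(self, base_config):
        b_et = make_branch(treatment="ET")
        b_ct = make_branch(treatment="ET_CT")
        t_et = run_branch(b_et, base_config)
        t_ct = run_branch(b_ct, base_config)
        _, q_ct = value_qalys(t_ct, b_ct, base_config)
        # same trace valued as if no CT: decrement removed
        cfg2 = base_config.copy_deep()
        object.__setattr__(cfg2.utilities, "ct_decrement", 0.0)
        _, q_ct_nodec = value_qalys(t_ct, b_ct, cfg2)
        # one cycle of 0.040 decrement on ~full occupancy, discounted midpoint
        expected = 0.040 * 0.5 * discount_factor(0.25, base_config.discount)
        assert q_ct_nodec - q_ct == pytest.approx(expected, rel=0.02)
        _, q_et = value_qalys(t_et, b_et, base_config)
        assert q_et > q_ct

    def test_age_multiplier_anchored_at_entry(self, base_config):
        # multiplier is 1 on entry, so a flat-curve run gives strictly larger
        # QALYs than the declining default only after the first cycles
        branch = make_branch()
        trace = run_branch(branch, base_config)
        _, q_decline = value_qalys(trace, branch, base_config)
        cfg_flat = modified_config(
            lambda doc: doc["settings"].__setitem__(
                "age_utility_curve", {age: 1.0 for age in range(0, 111)}
            )
        )
        _, q_flat = value_qalys(trace, branch, cfg_flat)
        assert q_flat > q_decline

    def test_qaly_never_exceeds_ly(self, base_config):
        for sp in base_config.subpopulations:
            for b in branch_weights(sp, "ODX"):
                trace = run_branch(b, base_config)
                ly, qaly = value_qalys(trace, b, base_config)
                assert qaly <= ly + 1e-9

    def test_zero_discount_bounds_ly_by_horizon(self):
        cfg = modified_config(no_discount_doc)
        branch = make_branch()
        trace = run_branch(branch, cfg)
        ly, _ = value_qalys(trace, branch, cfg)
        assert ly <= cfg.max_age - cfg.stratum("N1_ge50").start_age


class TestValueCosts:
    def test_test_cost_exactly_once_undiscounted(self, base_config):
        b_odx = make_branch(strategy="ODX", rs_context="rs_mid", treatment="ET")
        b_soc = make_branch(strategy="SOC")
        c_odx = value_costs(run_branch(b_odx, base_config), b_odx, base_config)
        c_soc = value_costs(run_branch(b_soc, base_config), b_soc, base_config)
        assert c_odx["test"] == 1850.0
        assert c_soc["test"] == 0.0

    def test_all_categories_present(self, base_config):
        b = make_branch()
        costs = value_costs(run_branch(b, base_config), b, base_config)
        assert set(costs) == set(COST_CATEGORIES)

    def test_ct_oneoffs_only_for_ct_branches(self, base_config):
        b_et = make_branch(treatment="ET")
        b_ct = make_branch(treatment="ET_CT")
        c_et = value_costs(run_branch(b_et, base_config), b_et, base_config)
        c_ct = value_costs(run_branch(b_ct, base_config), b_ct, base_config)
        assert c_et["sick_leave"] == 0.0
        assert c_ct["sick_leave"] == 10609.0
        spec = base_config.stratum("N1_ge50")
        # CT branch carries the add-on plus (slightly mortality-reduced) ET drug cost
        assert c_ct["adjuvant"] > spec.ct_addon_cost
        assert c_ct["transportation"] > spec.transport_ct_cost
        assert c_et["adjuvant"] < spec.ct_addon_cost

    def test_everyone_dies_first_cycle_terminal_cost(self):
        def mutate(doc):
            null_hazard_doc(doc)  # no competing transitions
            doc["settings"]["life_table"] = {age: 1.0 for age in range(0, 111)}

        cfg = modified_config(mutate)
        branch = make_branch()
        trace = run_branch(branch, cfg)
        costs = value_costs(trace, branch, cfg)
        expected = 4606.0 * discount_factor(0.25, cfg.discount)
        assert costs["end_of_life"] == pytest.approx(expected, rel=1e-6)

    def test_undiscounted_terminal_equals_deaths_times_cost(self):
        cfg = modified_config(no_discount_doc)
        branch = make_branch(strategy="SOC", treatment="ET_CT")
        trace = run_branch(branch, cfg)
        costs = value_costs(trace, branch, cfg)
        assert costs["end_of_life"] == pytest.approx(
            4606.0 * trace.occupancy[-1, -1], rel=1e-9
        )

    def test_cost_linearity(self, base_config):
        branch = make_branch(strategy="ODX", rs_context="rs_gt25", treatment="ET_CT")
        trace = run_branch(branch, base_config)
        base_costs = value_costs(trace, branch, base_config)

        def double_costs(doc):
            for key, val in doc["costs"].items():
                if key != "recurring_cost_period":
                    doc["costs"][key] = 2 * val
            for sp in doc["population"]:
                for key in (
                    "rf_year1_cost",
                    "ct_addon_cost",
                    "sick_leave_cost",
                    "transport_ct_cost",
                    "transport_et_cost",
                    "et_annual_cost",
                ):
                    sp[key] = 2 * sp[key]

        cfg2 = modified_config(double_costs)
        doubled = value_costs(run_branch(branch, cfg2), branch, cfg2)
        for cat in COST_CATEGORIES:
            assert doubled[cat] == pytest.approx(2 * base_costs[cat], rel=1e-12), cat

    def test_null_single_cycle_assembly(self):
        # one ET branch, no hazards, no discounting, one-year horizon:
        # cost = ET transport + first-year RF cost + ET drug year
        def mutate(doc):
            null_hazard_doc(doc)
            no_discount_doc(doc)
            doc["population"] = [sp for sp in doc["population"] if sp["id"] == "N1_ge50"]
            doc["population"][0]["weight"] = 1.0
            doc["settings"]["max_age"] = 62  # one year horizon for N1 (61)

        cfg = modified_config(mutate)
        branch = make_branch()
        trace = run_branch(branch, cfg)
        costs = value_costs(trace, branch, cfg)
        spec = cfg.stratum("N1_ge50")
        assert costs["transportation"] == pytest.approx(spec.transport_et_cost, rel=1e-6)
        assert costs["recurrence_free"] == pytest.approx(spec.rf_year1_cost, rel=1e-6)
        assert costs["adjuvant"] == pytest.approx(spec.et_annual_cost, rel=1e-6)
        assert costs["test"] == costs["sick_leave"] == 0.0

    def test_rf_recurring_after_first_year(self):
        # two-year horizon, cycles 2-3 charge the generic per-cycle RF cost
        def mutate(doc):
            null_hazard_doc(doc)
            no_discount_doc(doc)
            doc["population"] = [sp for sp in doc["population"] if sp["id"] == "N1_ge50"]
            doc["population"][0]["weight"] = 1.0
            doc["settings"]["max_age"] = 63

        cfg = modified_config(mutate)
        branch = make_branch()
        trace = run_branch(branch, cfg)
        costs = value_costs(trace, branch, cfg)
        spec = cfg.stratum("N1_ge50")
        assert costs["recurrence_free"] == pytest.approx(
            spec.rf_year1_cost + 2 * 604.0, rel=1e-6
        )


class TestValueBranch:
    def test_outcome_validates(self, base_config):
        branch = make_branch(strategy="ODX", rs_context="rs_gt25", treatment="ET_CT")
        out = value_branch(run_branch(branch, base_config), branch, base_config)
        assert out.total_cost == pytest.approx(sum(out.costs_by_category.values()))
        assert out.ct_proportion == 1.0
        assert 0.0 < out.aml_proportion < 1.0
        assert 0.0 < out.chf_proportion < 1.0
        assert out.qaly < out.ly
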