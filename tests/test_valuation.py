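"""Discounting and lifetime valuation of QALYs and costs."""

import dataclasses

import numpy as np
import pytest

from crswnp_cea import ARM_BSC, ARM_DUPILUMAB, HealthState, discount_factor, run_markov, run_tree
from crswnp_cea.markov import CohortTrace, N_STATES
from crswnp_cea.params import PERSPECTIVE_SOCIETAL
from crswnp_cea.valuation import (
    lifetime_costs,
    lifetime_qalys,
    state_utility_vector,
    value_arm,
)
from .conftest import make_flat_lifetable


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "rate, t, expected",
        [(0.03, 0, 1.0), (0.03, 10, 0.744094), (0.0, 7, 1.0)],
    )
    def test_examples(self, rate, t, expected):
        assert discount_factor(rate, t) == pytest.approx(expected, abs=1e-6)


def one_state_trace(state, n_cycles, start_age=51.39):
    occ = np.zeros((n_cycles + 1, N_STATES))
    occ[:, state] = 1.0
    return CohortTrace(start_age, occ, np.zeros(n_cycles + 1))


class TestLifetimeQalys:
    def test_full_health_zero_discount_counts_years(self, cfg):
        cfg.econ.discount_rate_effects = 0.0
        for f in ("u_controlled", "u_inadequate", "u_surgery", "u_postop_controlled",
                  "u_postop_uncontrolled"):
            setattr(cfg.markov_utilities, f, 1.0)
        cfg.tree_utilities.u_baseline = 1.0
        cfg.tree_utilities.u_wk12_24_dup = 1.0
        cfg.tree_utilities.u_wk24plus_responder = 1.0
        cfg.tree_utilities.u_wk24plus_nonresponder = 1.0
        tree = run_tree(cfg, ARM_DUPILUMAB)
        trace = one_state_trace(HealthState.CONTROLLED, 10)
        q = lifetime_qalys(tree, trace, cfg.markov_utilities, cfg.econ)
        assert q == pytest.approx(1 + 10)

    def test_geometric_series_closed_form(self, no_mortality_cfg):
        cfg = no_mortality_cfg
        cfg.sustained.annual_p_sustain = 1.0
        tree = run_tree(cfg, ARM_DUPILUMAB)
        tree.entry_distribution[:] = 0
        tree.entry_distribution[HealthState.CONTROLLED] = 1.0
        trace = run_markov(tree.entry_distribution, cfg)
        K = trace.n_cycles
        expected = tree.qaly + 0.913 * (1.03**-1) * (1 - 1.03**-K) / (1 - 1.03**-1)
        got = lifetime_qalys(tree, trace, cfg.markov_utilities, cfg.econ)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_discounting_never_increases_qalys(self, cfg):
        tree = run_tree(cfg, ARM_DUPILUMAB)
        trace = run_markov(tree.entry_distribution, cfg)
        low = lifetime_qalys(tree, trace, cfg.markov_utilities, cfg.econ)
        cfg.econ.discount_rate_effects = 0.06
        high_rate = lifetime_qalys(tree, trace, cfg.markov_utilities, cfg.econ)
        assert high_rate <= low

    def test_state_utilities_map_inadequate_substates_together(self, cfg):
        u = state_utility_vector(cfg.markov_utilities)
        assert u[HealthState.INADEQ_ELIG] == u[HealthState.INADEQ_INELIG] == 0.776
        assert u[HealthState.DEATH] == 0.0


class TestLifetimeCosts:
    def test_surgery_episode_cost(self, cfg):
        """A unit surgery-entry flow in one undiscounted cycle adds the CT +
        procedure tariff (104 + 2009 = 2113) to disease management."""
        cfg.econ.discount_rate_costs = 0.0
        tree = run_tree(cfg, ARM_BSC)
        trace = one_state_trace(HealthState.SURGERY, 1)
        base_flow = lifetime_costs(tree, trace, cfg, ARM_BSC).disease_management
        trace.surgery_entries[1] = 1.0
        with_flow = lifetime_costs(tree, trace, cfg, ARM_BSC).disease_management
        assert with_flow - base_flow == pytest.approx(2113.0)

    def test_postop_controlled_year_costs_management_plus_followup(self, cfg):
        cfg.econ.discount_rate_costs = 0.0
        tree = run_tree(cfg, ARM_BSC)
        trace0 = one_state_trace(HealthState.DEATH, 1)
        trace1 = one_state_trace(HealthState.POSTOP_CONTROLLED, 1)
        c0 = lifetime_costs(tree, trace0, cfg, ARM_BSC).disease_management
        c1 = lifetime_costs(tree, trace1, cfg, ARM_BSC).disease_management
        assert c1 - c0 == pytest.approx(8937 + 103)

    def test_followup_switch_removes_the_extra_103(self, cfg):
        cfg.econ.discount_rate_costs = 0.0
        cfg.switches.postop_followup_separate = False
        tree = run_tree(cfg, ARM_BSC)
        trace0 = one_state_trace(HealthState.DEATH, 1)
        trace1 = one_state_trace(HealthState.POSTOP_CONTROLLED, 1)
        delta = (
            lifetime_costs(tree, trace1, cfg, ARM_BSC).disease_management
            - lifetime_costs(tree, trace0, cfg, ARM_BSC).disease_management
        )
        assert delta == pytest.approx(8937)

    def test_nhs_perspective_has_zero_indirect(self, cfg):
        tree = run_tree(cfg, ARM_BSC)
        trace = run_markov(tree.entry_distribution, cfg)
        assert lifetime_costs(tree, trace, cfg, ARM_BSC).indirect == 0.0

    def test_societal_indirect_uses_hourly_rate(self, cfg):
        """One workday lost per year in one undiscounted post-op cycle costs
        8 h x 29.80 EUR = 238.40 EUR."""
        cfg.econ.perspective = PERSPECTIVE_SOCIETAL
        cfg.econ.discount_rate_costs = 0.0
        cfg.indirect.workdays_lost_per_year_by_state = {"postop_controlled": 1.0}
        tree = run_tree(cfg, ARM_BSC)
        trace = one_state_trace(HealthState.POSTOP_CONTROLLED, 1)
        assert lifetime_costs(tree, trace, cfg, ARM_BSC).indirect == pytest.approx(238.40)

    def test_total_equals_component_sum(self, cfg):
        for arm in (ARM_DUPILUMAB, ARM_BSC):
            tree = run_tree(cfg, arm)
            trace = run_markov(tree.entry_distribution, cfg)
            cb = lifetime_costs(tree, trace, cfg, arm)
            assert cb.total == pytest.approx(
                cb.drug_acquisition + cb.disease_management + cb.adverse_events + cb.indirect,
                abs=1e-6,
            )

    def test_zero_unit_costs_zero_total(self, cfg):
        for path_obj, fields in (
            (cfg.tree_costs, [f.name for f in dataclasses.fields(cfg.tree_costs)]),
            (cfg.markov_state_costs, ["controlled", "inadequate", "postop_controlled",
                                      "postop_uncontrolled", "death"]),
        ):
            for f in fields:
                setattr(path_obj, f, 0.0)
        cfg.drug.price_per_administration = 0.0
        cfg.surgery_costs.ct_scan = 0.0
        cfg.surgery_costs.procedure = 0.0
        cfg.surgery_costs.annual_followup = 0.0
        cfg.surgery_costs.visit_tariff = 0.0
        for item in cfg.ae_items:
            item.unit_cost = 0.0
        tree = run_tree(cfg, ARM_DUPILUMAB)
        trace = run_markov(tree.entry_distribution, cfg)
        assert lifetime_costs(tree, trace, cfg, ARM_DUPILUMAB).total == 0.0

    def test_compliance_scales_only_drug_costs(self, cfg):
        tree = run_tree(cfg, ARM_DUPILUMAB)
        trace = run_markov(tree.entry_distribution, cfg)
        base = lifetime_costs(tree, trace, cfg, ARM_DUPILUMAB)
        cfg2 = cfg.copy()
        cfg2.drug.compliance = 0.5
        tree2 = run_tree(cfg2, ARM_DUPILUMAB)
        trace2 = run_markov(tree2.entry_distribution, cfg2)
        half = lifetime_costs(tree2, trace2, cfg2, ARM_DUPILUMAB)
        assert half.drug_acquisition == pytest.approx(0.5 * base.drug_acquisition)
        assert half.disease_management == pytest.approx(base.disease_management)
        assert half.adverse_events == pytest.approx(base.adverse_events)

    def test_discounting_lowers_costs(self, cfg):
        tree = run_tree(cfg, ARM_BSC)
        trace = run_markov(tree.entry_distribution, cfg)
        discounted = lifetime_costs(tree, trace, cfg, ARM_BSC).total
        cfg.econ.discount_rate_costs = 0.0
        undiscounted = lifetime_costs(tree, trace, cfg, ARM_BSC).total
        assert undiscounted > discounted


class TestValueArm:
    def test_qalys_bounded_by_life_years(self, cfg):
        for arm in (ARM_DUPILUMAB, ARM_BSC):
            tree = run_tree(cfg, arm)
            trace = run_markov(tree.entry_distribution, cfg)
            res = value_arm(cfg, arm, tree, trace)
            assert res.qalys <= res.life_years
            assert np.isfinite(res.qalys) and np.isfinite(res.costs.total)

    def test_half_cycle_correction_changes_valuation_smoothly(self, cfg):
        tree = run_tree(cfg, ARM_BSC)
        trace = run_markov(tree.entry_distribution, cfg)
        plain = value_arm(cfg, ARM_BSC, tree, trace)
        cfg.switches.half_cycle_correction = True
        corrected = value_arm(cfg, ARM_BSC, tree, trace)
        assert corrected.qalys != plain.qalys
        assert abs(corrected.qalys - plain.qalys) < 0.5
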