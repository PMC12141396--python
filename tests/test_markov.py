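"""Markov cohort engine: transition structure, accrual, ICER logic."""

import copy
import math

import numpy as np
import pytest

from racea.errors import ConfigurationError, DomainError
from racea.markov import (ArmConfig, ArmResult, ModelConfig, UtilityMap,
                          build_states, haq_to_utility, icer,
                          iterate_occupancy, run_cea, run_cohort,
                          summarize_trace)


def _arm(name="tof", response=None, **kw):
    defaults = dict(
        drug_cost_per_cycle=1000.0,
        response=response or {"ACR70": 0.3, "ACR50": 0.2, "ACR20": 0.2, "NONE": 0.3},
        delta_haq={"ACR70": 0.6, "ACR50": 0.5, "ACR20": 0.2},
        baseline_haq=1.0,
        haq_progression_per_year=0.05,
        withdrawal_per_cycle=0.05,
        palliative_drug_cost_per_cycle=300.0,
        state_cost_base_per_cycle=500.0,
        state_cost_per_haq_per_cycle=1000.0,
        utility=UtilityMap(0.862, 0.327, 0.1),
        nonmedical_cost_per_cycle=100.0,
        indirect_cost_per_cycle=20.0,
    )
    defaults.update(kw)
    return ArmConfig(name=name, **defaults)


def _config(arm_kw=None, **kw):
    arm_kw = arm_kw or {}
    arms = {"tof": _arm("tof", **arm_kw), "ada": _arm("ada", **arm_kw)}
    defaults = dict(cycle_length=0.5, horizon=27.0, start_age=51.0, end_age=78.0,
                    mortality_per_cycle=0.01)
    defaults.update(kw)
    return ModelConfig(arms=arms, **defaults)


class TestHaqToUtility:
    def test_zero_slope_is_constant(self):
        m = UtilityMap(0.8, 0.0, 0.0)
        assert haq_to_utility(0.0, m) == haq_to_utility(3.0, m) == 0.8

    def test_linear_value(self):
        assert haq_to_utility(2.0, UtilityMap(0.9, 0.25, -1)) == pytest.approx(0.40)

    def test_floor_clamp(self):
        assert haq_to_utility(3.0, UtilityMap(0.9, 0.5, -0.1)) == pytest.approx(-0.1)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            haq_to_utility(3.5, UtilityMap())


class TestBuildStates:
    def test_all_nonresponders_go_palliative(self):
        arm = _arm(response={"ACR70": 0, "ACR50": 0, "ACR20": 0, "NONE": 1.0})
        labels, init, tr = build_states(arm, [0.0] * 4)
        occ = iterate_occupancy(init, tr, 4)
        pall = labels.index("palliative")
        assert occ[1:, pall] == pytest.approx(np.ones(4))

    def test_full_response_no_attrition_is_absorbing(self):
        arm = _arm(response={"ACR70": 1.0, "ACR50": 0, "ACR20": 0, "NONE": 0},
                   withdrawal_per_cycle=0.0)
        labels, init, tr = build_states(arm, [0.0] * 10)
        occ = iterate_occupancy(init, tr, 10)
        assert occ[1:, labels.index("acr70")] == pytest.approx(np.ones(10))

    def test_first_cycle_multinomial_split(self):
        arm = _arm(withdrawal_per_cycle=0.0)
        labels, init, tr = build_states(arm, [0.0] * 2)
        occ = iterate_occupancy(init, tr, 1)
        assert occ[1, 1:] == pytest.approx([0.3, 0.2, 0.2, 0.3, 0.0])

    def test_invalid_response_probs_rejected(self):
        arm = _arm(response={"ACR70": 0.5, "ACR50": 0.5, "ACR20": 0.5, "NONE": 0.0})
        with pytest.raises(ConfigurationError):
            build_states(arm, [0.0])


class TestRunCohort:
    def test_conservation_and_horizon(self):
        cfg = _config(arm_kw=dict(utility=UtilityMap(1.0, 0.0, 0.0),
                                  drug_cost_per_cycle=0.0,
                                  palliative_drug_cost_per_cycle=0.0,
                                  state_cost_base_per_cycle=0.0,
                                  state_cost_per_haq_per_cycle=0.0,
                                  nonmedical_cost_per_cycle=0.0,
                                  indirect_cost_per_cycle=0.0),
                      mortality_per_cycle=0.0,
                      discount_rate_costs=0.0, discount_rate_qalys=0.0)
        trace = run_cohort(cfg, "tof")
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
        assert trace.qalys_discounted.sum() == pytest.approx(27.0, abs=1e-10)
        assert summarize_trace(trace).total_cost == 0.0

    def test_hand_recursion_undiscounted(self):
        # single effective alive state: everyone responds at ACR70, never
        # withdraws, utility 1; per-cycle death 0.1 over 3 cycles
        cfg = _config(
            arm_kw=dict(
                response={"ACR70": 1.0, "ACR50": 0, "ACR20": 0, "NONE": 0},
                withdrawal_per_cycle=0.0, utility=UtilityMap(1.0, 0.0, 0.0)),
            horizon=1.5, end_age=None, mortality_per_cycle=0.1,
            discount_rate_costs=0.0, discount_rate_qalys=0.0)
        trace = run_cohort(cfg, "tof")
        assert trace.qalys_discounted.sum() == pytest.approx(
            0.5 * (1 + 0.9 + 0.81), abs=1e-12)

    def test_hand_recursion_discounted(self):
        cfg = _config(
            arm_kw=dict(
                response={"ACR70": 1.0, "ACR50": 0, "ACR20": 0, "NONE": 0},
                withdrawal_per_cycle=0.0, utility=UtilityMap(1.0, 0.0, 0.0)),
            horizon=1.5, end_age=None, mortality_per_cycle=0.1,
            discount_rate_costs=0.05, discount_rate_qalys=0.05)
        trace = run_cohort(cfg, "tof")
        expected = 0.5 * (1 + 0.9 * 1.05 ** -0.5 + 0.81 * 1.05 ** -1)
        assert trace.qalys_discounted.sum() == pytest.approx(expected, abs=5e-4)

    def test_closed_form_constant_survival(self):
        q = 0.07
        cfg = _config(
            arm_kw=dict(
                response={"ACR70": 1.0, "ACR50": 0, "ACR20": 0, "NONE": 0},
                withdrawal_per_cycle=0.0, utility=UtilityMap(1.0, 0.0, 0.0)),
            mortality_per_cycle=q,
            discount_rate_costs=0.0, discount_rate_qalys=0.0)
        trace = run_cohort(cfg, "tof")
        n = cfg.n_cycles
        s = 1 - q
        expected = cfg.cycle_length * (1 - s**n) / (1 - s)
        assert trace.qalys_discounted.sum() == pytest.approx(expected, abs=1e-10)

    def test_non_integer_cycle_count_rejected(self):
        with pytest.raises(ConfigurationError):
            _config(horizon=27.25, end_age=None).n_cycles

    def test_zero_discount_reproduces_undiscounted(self):
        cfg0 = _config(discount_rate_costs=0.0, discount_rate_qalys=0.0)
        trace = run_cohort(cfg0, "tof")
        for cat in trace.costs:
            assert np.array_equal(trace.costs[cat], trace.costs_discounted[cat])
        assert np.array_equal(trace.qalys, trace.qalys_discounted)

    def test_cost_and_utility_monotonicity(self):
        base = _config()
        res0 = summarize_trace(run_cohort(base, "tof"))

        dearer = _config(arm_kw=dict(state_cost_per_haq_per_cycle=2000.0))
        assert summarize_trace(run_cohort(dearer, "tof")).total_cost > res0.total_cost

        happier = _config(arm_kw=dict(utility=UtilityMap(0.95, 0.327, 0.1)))
        assert summarize_trace(run_cohort(happier, "tof")).qalys > res0.qalys

    def test_oracle_path_enumeration(self, rng):
        """Engine equals exact path-sum on random ≤4-state, ≤5-cycle chains."""
        for _ in range(200):
            n_states = int(rng.integers(2, 5))
            n_cycles = int(rng.integers(1, 6))
            mats = []
            for _ in range(n_cycles):
                m = rng.random((n_states, n_states))
                m /= m.sum(axis=1, keepdims=True)
                mats.append(m)
            init = rng.random(n_states)
            init /= init.sum()
            occ = iterate_occupancy(init, lambda k: mats[k], n_cycles)

            # brute force: sum over all state paths of product probabilities
            final = np.zeros(n_states)
            paths = [[s] for s in range(n_states)]
            for k in range(n_cycles):
                paths = [p + [s] for p in paths for s in range(n_states)]
            for p in paths:
                prob = init[p[0]]
                for k in range(n_cycles):
                    prob *= mats[k][p[k], p[k + 1]]
                final[p[-1]] += prob
            assert np.allclose(occ[-1], final, atol=1e-10)


class TestIcer:
    @staticmethod
    def _result(arm, total, qalys):
        # decompose an intended total into the cost categories
        return ArmResult(arm=arm, medication_cost=total * 0.4,
                         state_cost=total * 0.4, nonmedical_cost=total * 0.15,
                         indirect_cost=total * 0.05, qalys=qalys, sae_qalys=0.0)

    def test_published_totals_are_dominant(self):
        inc = icer(self._result("tof", 144_558, 10.08),
                   self._result("ada", 317_747, 9.86))
        assert round(inc.delta_cost) == -173_189
        assert inc.delta_qalys == pytest.approx(0.22, abs=1e-9)
        assert inc.label == "dominant"
        assert inc.icer is None

    def test_identical_arms(self):
        a = self._result("tof", 1000.0, 5.0)
        b = self._result("ada", 1000.0, 5.0)
        inc = icer(a, b)
        assert (inc.delta_cost, inc.delta_qalys, inc.icer) == (0.0, 0.0, None)

    def test_plain_ratio(self):
        inc = icer(self._result("tof", 11_000, 5.5), self._result("ada", 1_000, 5.0))
        assert inc.icer == pytest.approx(20_000.0)
        assert inc.label == "ICER"

    def test_cost_difference_only(self):
        inc = icer(self._result("tof", 2_000, 5.0), self._result("ada", 1_000, 5.0))
        assert inc.icer is None
        assert inc.label == "cost difference only"

    def test_dominated(self):
        inc = icer(self._result("tof", 2_000, 4.0), self._result("ada", 1_000, 5.0))
        assert inc.label == "dominated"


class TestAccountingIdentities:
    def test_cost_decomposition(self, model_config):
        res = run_cea(model_config)
        for r in res.arm_results.values():
            assert r.total_cost == pytest.approx(
                r.direct_medical_cost + r.nonmedical_cost + r.indirect_cost,
                rel=1e-12)
            assert r.direct_medical_cost == pytest.approx(
                r.medication_cost + r.state_cost, rel=1e-12)

    def test_packaged_base_case_is_dominant(self, model_config):
        res = run_cea(model_config)
        assert res.incremental.label == "dominant"
        assert res.incremental.delta_cost < 0
        assert res.incremental.delta_qalys > 0

    def test_summary_frame_row_set(self, model_config):
        frame = run_cea(model_config).summary_frame()
        assert len(frame) == 11
        assert frame.attrs["icer_label"] == "dominant"
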