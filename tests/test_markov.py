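"""Markov engine: hazard conversions, cycle quantities, transition matrices,
and lifetime-cohort invariants."""

import math

import numpy as np
import pytest

from csfcea.markov import (GROUPS, HealthState, ScenarioFlags,
                           annual_hazard_to_cycle_prob, baseline_annual_cost,
                           build_cycle_transition_matrix, cycle_cost,
                           cycle_death_prob, cycle_utility,
                           other_cause_mortality_rate, run_all_groups, run_cohort)
from csfcea.parameters import default_parameters

DEAD = HealthState("dead")


class TestHazardConversion:
    def test_discontinuation_rate_reproduces_published_annual_probability(self):
        # 28,768 per 100,000/yr was derived from a 25% annual probability
        assert annual_hazard_to_cycle_prob(28_768, 12) == pytest.approx(0.25, abs=5e-5)
        assert annual_hazard_to_cycle_prob(62_362, 12) == pytest.approx(0.464, abs=5e-4)

    def test_zero_hazard(self):
        assert annual_hazard_to_cycle_prob(0.0, 1) == 0.0

    def test_monthly_closed_form(self):
        assert annual_hazard_to_cycle_prob(27_710, 1) == \
            pytest.approx(1 - math.exp(-0.2771 / 12), abs=1e-12)
        assert annual_hazard_to_cycle_prob(27_710, 1) == pytest.approx(0.02283, abs=5e-6)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            annual_hazard_to_cycle_prob(-1.0)


class TestMortality:
    def test_exponential_fit_values(self):
        assert other_cause_mortality_rate(0) == pytest.approx(3.53)
        assert other_cause_mortality_rate(65) == pytest.approx(
            3.53 * math.exp(0.0909 * 65), rel=1e-12)
        assert 1290 < other_cause_mortality_rate(65) < 1310

    def test_monotone_in_age(self):
        ages = np.linspace(0, 110, 23)
        rates = [other_cause_mortality_rate(a) for a in ages]
        assert all(b > a for a, b in zip(rates, rates[1:]))

    def test_severe_hr_applies(self, ps):
        severe = HealthState("AD", "severe", "community", False)
        p = cycle_death_prob(65, severe, ps, 1)
        hazard = other_cause_mortality_rate(65) * 9.52
        assert p == pytest.approx(1 - math.exp(-hazard / 1e5 / 12), rel=1e-12)

    def test_nonad_mortality_equals_mild_ad(self, ps):
        # "assumed the same as mild AD" applies to non-AD mortality as well
        nonad = HealthState("nonAD", None, "community", False)
        mild = HealthState("AD", "mild", "community", False)
        for age in (55, 65, 75, 85, 95):
            assert cycle_death_prob(age, nonad, ps) == \
                pytest.approx(cycle_death_prob(age, mild, ps), rel=1e-12)

    def test_treatment_does_not_affect_mortality(self, ps):
        for age in (55, 70, 90):
            off = HealthState("AD", "moderate", "community", False)
            on = HealthState("AD", "moderate", "community", True)
            assert cycle_death_prob(age, off, ps) == cycle_death_prob(age, on, ps)

    def test_dead_state_rejected(self, ps):
        with pytest.raises(ValueError):
            cycle_death_prob(65, DEAD, ps)


class TestBaselineCost:
    def test_age_65_matches_published_band(self, ps):
        # exponential fit at 65 lands on the printed 65-84 band value
        got = baseline_annual_cost(65, ps)
        assert got == pytest.approx(893 * math.exp(0.0404 * 65), rel=1e-12)
        assert 12_300 < got < 12_380

    def test_cap_from_age_90(self, ps):
        assert baseline_annual_cost(90, ps) == 33_870
        assert baseline_annual_cost(95, ps) == 33_870
        # below 90 the raw curve applies even where it is close to the cap
        assert baseline_annual_cost(89.9, ps) == pytest.approx(
            893 * math.exp(0.0404 * 89.9), rel=1e-12)

    def test_monotone_below_cap(self, ps):
        ages = np.linspace(40, 89, 20)
        costs = [baseline_annual_cost(a, ps) for a in ages]
        assert all(b > a for a, b in zip(costs, costs[1:]))


class TestCycleCost:
    """Costs follow the excess-over-common-care convention: the mild/non-AD
    community increment is the background care level; severity adds its
    excess, and the LTCF facility cost displaces community-level care."""

    def test_mild_community_accrues_baseline_only(self, ps):
        s = HealthState("AD", "mild", "community", False)
        assert cycle_cost(s, 65, ps) == pytest.approx(baseline_annual_cost(65, ps) / 12)

    def test_moderate_community_excess(self, ps):
        s = HealthState("AD", "moderate", "community", False)
        expected = (baseline_annual_cost(65, ps) + (33_845 - 24_128)) / 12
        assert cycle_cost(s, 65, ps) == pytest.approx(expected)

    def test_severe_ltcf_on_memantine(self, ps):
        s = HealthState("AD", "severe", "ltcf", True)
        expected = (baseline_annual_cost(80, ps)
                    + 83_950 + 9_847 - 24_128 + 3_192) / 12
        assert cycle_cost(s, 80, ps) == pytest.approx(expected)

    def test_nonad_equals_mild_ad(self, ps):
        nonad = HealthState("nonAD", None, "community", False)
        mild = HealthState("AD", "mild", "community", False)
        assert cycle_cost(nonad, 72, ps) == pytest.approx(cycle_cost(mild, 72, ps))

    def test_treated_adds_drug_cost(self, ps):
        off = HealthState("AD", "mild", "community", False)
        on = HealthState("AD", "mild", "community", True)
        assert cycle_cost(on, 65, ps) - cycle_cost(off, 65, ps) == \
            pytest.approx(2_473 / 12)

    def test_dead_accrues_nothing(self, ps):
        assert cycle_cost(DEAD, 65, ps) == 0.0


class TestCycleUtility:
    def test_age_band_times_state_weight(self, ps):
        s = HealthState("AD", "moderate", "community", False)
        assert cycle_utility(s, 67, ps) == pytest.approx(0.82 * 0.54 / 12)

    def test_memantine_increment_for_treated_severe(self, ps):
        s = HealthState("AD", "severe", "community", True)
        assert cycle_utility(s, 67, ps) == pytest.approx((0.82 * 0.37 + 0.051) / 12)

    def test_age_band_boundaries(self, ps):
        s = HealthState("nonAD", None, "community", False)
        assert cycle_utility(s, 59, ps) == pytest.approx(0.83 * 0.68 / 12)
        assert cycle_utility(s, 80, ps) == pytest.approx(0.74 * 0.68 / 12)

    def test_dead_utility_zero(self, ps):
        assert cycle_utility(DEAD, 70, ps) == 0.0


class TestTransitionMatrix:
    @pytest.mark.parametrize("group", GROUPS)
    def test_rows_stochastic_across_ages(self, ps, group):
        for age in (55, 65, 75, 85, 95, 110):
            m = build_cycle_transition_matrix(age, group, ps)
            assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert (m >= 0).all()
            assert m[-1, -1] == 1.0  # dead is absorbing

    def test_off_treatment_progression_probability(self, ps):
        # mild->moderate, off treatment: 1 - exp(-0.2771/12) ~ 0.02283
        m = build_cycle_transition_matrix(65, "FN", ps)
        mild_off = 0
        to_moderate = m[mild_off, [1, 4]].sum()  # community + LTCF destinations
        surv = 1 - m[mild_off, -1]
        assert to_moderate / surv == pytest.approx(0.02283, abs=2e-5)

    def test_treatment_halves_progression_hazard(self, ps):
        m = build_cycle_transition_matrix(65, "TP", ps)
        surv = 1 - m[0, -1]
        off = m[0, [1, 4, 7, 10]].sum() / surv  # any moderate destination
        on = m[6, [1, 4, 7, 10]].sum() / (1 - m[6, -1])
        assert off == pytest.approx(0.02283, abs=2e-4)
        assert on == pytest.approx(0.01148, abs=2e-4)

    def test_ltcf_never_returns_to_community(self, ps):
        for group in GROUPS:
            m = build_cycle_transition_matrix(70, group, ps)
            L = m.shape[0] - 1
            states = range(L)
            for i in states:
                loc_i = (i // 3) % 2 if L == 12 else i % 2
                for j in states:
                    loc_j = (j // 3) % 2 if L == 12 else j % 2
                    if loc_i == 1 and loc_j == 0:
                        assert m[i, j] == 0.0

    def test_untreated_groups_hold_no_treated_mass(self, ps):
        for group, L in (("FN", 12), ("TN", 4)):
            o = run_cohort(group, ps, keep_trace=True)
            occ = o.trace[:, 3:3 + L]
            on_cols = slice(6, 12) if L == 12 else slice(2, 4)
            assert np.abs(occ[:, on_cols]).max() == 0.0


class TestRunCohort:
    def test_fp_and_tn_share_survival_and_qalys(self, outcomes):
        # treatment affects neither mortality nor utility for non-AD patients
        assert outcomes["FP"].life_years == pytest.approx(
            outcomes["TN"].life_years, abs=1e-12)
        assert outcomes["FP"].discounted_qalys == pytest.approx(
            outcomes["TN"].discounted_qalys, abs=1e-12)
        assert outcomes["FP"].discounted_cost > outcomes["TN"].discounted_cost

    def test_treatment_benefits_ad_patients(self, outcomes):
        assert outcomes["TP"].discounted_cost < outcomes["FN"].discounted_cost
        assert outcomes["TP"].discounted_qalys > outcomes["FN"].discounted_qalys
        assert outcomes["TP"].life_years >= outcomes["FN"].life_years

    def test_tp_equals_fn_without_treatment_access(self):
        ps = default_parameters()
        ps.treatment.donepezil_uptake.value = 0.0
        ps.treatment.memantine_uptake.value = 0.0
        ps.treatment.reinit_donepezil.value = 0.0
        ps.treatment.reinit_memantine.value = 0.0
        tp = run_cohort("TP", ps)
        fn = run_cohort("FN", ps)
        assert tp.discounted_cost == pytest.approx(fn.discounted_cost, rel=1e-12)
        assert tp.discounted_qalys == pytest.approx(fn.discounted_qalys, rel=1e-12)

    def test_undiscounted_exceeds_discounted(self, outcomes):
        for o in outcomes.values():
            assert o.life_years_undiscounted > o.life_years

    def test_zero_discount_raises_qalys(self, ps, outcomes):
        ps0 = ps.copy()
        ps0.settings.discount_rate_annual = 0.0
        o0 = run_cohort("TN", ps0)
        assert o0.discounted_qalys > outcomes["TN"].discounted_qalys

    def test_qalys_bounded_by_life_years(self, outcomes):
        for o in outcomes.values():
            assert 0 < o.discounted_qalys <= o.life_years * 0.83

    def test_qalys_nonincreasing_in_start_age(self, ps):
        qalys = []
        for age in (55, 65, 75):
            psa = ps.copy()
            psa.cohort.start_age.value = age
            qalys.append(run_cohort("TP", psa).discounted_qalys)
        assert qalys[0] > qalys[1] > qalys[2]

    def test_trace_mass_conservation(self, ps):
        o = run_cohort("TP", ps, keep_trace=True)
        occ = o.trace[:, 3:15]
        live = occ.sum(axis=1)
        assert live[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(live) <= 1e-12)  # monotone extinction

    def test_unknown_group_rejected(self, ps):
        with pytest.raises(ValueError):
            run_cohort("XX", ps)


class TestScenarios:
    def test_progressive_nonad_shortens_life(self, ps, outcomes):
        prog = run_all_groups(ps, ScenarioFlags(nonad_history="progressive_like_ad"))
        assert prog["TN"].life_years < outcomes["TN"].life_years

    def test_stable_moderate_lowers_qalys(self, ps, outcomes):
        mod = run_all_groups(ps, ScenarioFlags(nonad_history="stable_moderate"))
        assert mod["TN"].discounted_qalys < outcomes["TN"].discounted_qalys

    def test_fn_correction_improves_fn_outcomes(self, ps, outcomes):
        corr = run_cohort("FN", ps, ScenarioFlags(fn_correction_on_progression=True))
        assert corr.discounted_qalys > outcomes["FN"].discounted_qalys

    def test_invalid_history_rejected(self):
        with pytest.raises(ValueError):
            ScenarioFlags(nonad_history="cured")
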