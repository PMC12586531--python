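"""Scenario transforms: worked arithmetic, TMREL, improvements, mediation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morbsim import (
    MediationSpec,
    Scenario,
    apply_bmi_mediation,
    apply_relative_improvement,
    relative_excess_reduction,
)
from morbsim._streams import StreamFactory
from morbsim.exposure import CURRENT, EX, NEVER, simulate_base_trajectories
from morbsim.scenario import build_arm_trajectories


class TestRelativeImprovement:
    def test_worked_bmi_example(self):
        """BMI 28 against TMREL 22 under the 10%-of-excess rule gives 27.4."""
        assert apply_relative_improvement(28.0, 22.0, 0.10) == pytest.approx(27.4)

    def test_at_tmrel_unchanged(self):
        assert apply_relative_improvement(22.0, 22.0, 0.10) == 22.0

    def test_full_elimination_reaches_tmrel(self):
        assert apply_relative_improvement(28.0, 22.0, 1.0) == 22.0

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            apply_relative_improvement(28.0, 22.0, -0.1)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(base=st.floats(10, 60), tmrel=st.floats(10, 60),
           frac=st.floats(0, 1))
    def test_never_crosses_tmrel_and_is_monotone(self, base, tmrel, frac):
        out = apply_relative_improvement(base, tmrel, frac)
        assert out <= base + 1e-12
        if base > tmrel:
            assert out >= tmrel - 1e-12
        else:
            assert out == pytest.approx(base)  # no excess, no change


class TestExcessReduction:
    def test_worked_sbp_example(self):
        """SBP falling 125.3 -> 122.6 against TMREL 112 removes 20.3% of the
        excess."""
        r = relative_excess_reduction(125.3, 122.6, 112.0)
        assert round(100 * r, 1) == 20.3

    def test_smoking_prevalence_relative_reduction(self):
        """Prevalence falling 15.5% -> 12.9% is a 17% relative reduction."""
        r = relative_excess_reduction(15.5, 12.9, 0.0)
        assert round(100 * r) == 17

    def test_no_change_is_zero(self):
        assert relative_excess_reduction(125.3, 125.3, 112.0) == 0.0

    def test_reduction_to_tmrel_is_one(self):
        assert relative_excess_reduction(125.3, 112.0, 112.0) == 1.0

    def test_no_excess_rejected(self):
        with pytest.raises(ValueError):
            relative_excess_reduction(110.0, 108.0, 112.0)


class TestMediation:
    def test_unit_decrease_coefficients(self):
        assert apply_bmi_mediation(1.0, 30.0, MediationSpec()) == \
            (pytest.approx(2.55), pytest.approx(0.23))

    def test_linear_scaling(self):
        d_sbp, d_tc = apply_bmi_mediation(0.6, 28.0, MediationSpec())
        assert d_sbp == pytest.approx(1.53)
        assert d_tc == pytest.approx(0.138)

    def test_off_below_floor(self):
        assert apply_bmi_mediation(1.0, 24.0, MediationSpec()) == (0.0, 0.0)

    def test_negative_decrease_rejected(self):
        with pytest.raises(ValueError):
            apply_bmi_mediation(-0.5, 30.0, MediationSpec())


@pytest.fixture(scope="module")
def arm_setup(small_cohort, registry):
    cfg, cohort, _, _ = small_cohort
    streams = StreamFactory(99)
    base = simulate_base_trajectories(cohort, cfg, streams, 9)
    tmrels = registry.sample_tmrels(streams("tmrel"))
    return cfg, cohort, streams, base, tmrels


def build(arm_setup, scenario):
    cfg, cohort, streams, base, tmrels = arm_setup
    return build_arm_trajectories(base, scenario, tmrels, cohort, cfg, streams)


class TestArmTransforms:
    def test_baseline_passthrough(self, arm_setup):
        base = arm_setup[3]
        assert build(arm_setup, Scenario.baseline()) is base

    def test_tmrel_sets_continuous_factors(self, arm_setup):
        cfg, cohort, _, base, tmrels = arm_setup
        arm = build(arm_setup, Scenario(name="t", family="tmrel"))
        t0 = arm.col(2023)
        for name in ("bmi", "sbp", "total_cholesterol", "fruit", "vegetables"):
            assert np.all(arm.continuous[name][:, t0:] == tmrels[name])
        assert np.all(arm.continuous["physical_activity"][:, t0:] == 7.0)
        # history before the scenario start is untouched
        np.testing.assert_array_equal(arm.continuous["bmi"][:, :t0],
                                      base.continuous["bmi"][:, :t0])

    def test_tmrel_smoking_and_ets(self, arm_setup):
        cfg, cohort, _, base, _ = arm_setup
        arm = build(arm_setup, Scenario(name="t", family="tmrel"))
        t0 = arm.col(2023)
        assert not np.any(arm.smk_status[:, t0:] == CURRENT)
        assert not np.any(arm.ets[:, t0:])
        # smokers at the start year become ex with the quit clock at zero
        was_current = base.smk_status[:, t0] == CURRENT
        assert np.all(arm.smk_status[was_current, t0] == EX)
        assert np.all(arm.years_since_quit[was_current, t0] == 0.0)
        assert np.all(arm.smk_cigs[was_current, t0:] == 0.0)
        # pack-years frozen at quitting
        later = arm.col(2030)
        np.testing.assert_allclose(arm.pack_years[was_current, later],
                                   arm.pack_years[was_current, t0])
        # initiation rate zero: never-smokers at start stay never
        never0 = base.smk_status[:, t0 - 1] == NEVER
        assert np.all(arm.smk_status[never0, t0:] == NEVER)

    def test_tmrel_idempotent(self, arm_setup):
        cfg, cohort, streams, base, tmrels = arm_setup
        scen = Scenario(name="t", family="tmrel")
        once = build_arm_trajectories(base, scen, tmrels, cohort, cfg, streams)
        twice = build_arm_trajectories(once, scen, tmrels, cohort, cfg, streams)
        for name in once.continuous:
            np.testing.assert_array_equal(twice.continuous[name],
                                          once.continuous[name])
        np.testing.assert_array_equal(twice.smk_status, once.smk_status)

    def test_monotone_dose_for_bmi(self, arm_setup):
        """For every simulant and year, base-case BMI >= 10%-improved BMI >=
        TMREL-scenario BMI."""
        base = arm_setup[3]
        tmrels = arm_setup[4]
        ten = build(arm_setup, Scenario(name="i", family="relative_improvement",
                                        factors=("bmi",), mediation_on=False))
        tm = build(arm_setup, Scenario(name="t", family="tmrel",
                                       factors=("bmi",)))
        t0 = base.col(2023)
        b = base.continuous["bmi"][:, t0:]
        i = ten.continuous["bmi"][:, t0:]
        t = tm.continuous["bmi"][:, t0:]
        assert np.all(i <= b + 1e-12)
        assert np.all(i >= np.minimum(t, b) - 1e-12)

    def test_fruit_veg_exact_ten_percent(self, arm_setup):
        base = arm_setup[3]
        arm = build(arm_setup, Scenario(name="fv", family="relative_improvement",
                                        factors=("fruit_veg",)))
        cfg = arm_setup[0]
        t0 = base.col(2023)
        hi = cfg.exposures["fruit"].hi
        np.testing.assert_allclose(
            arm.continuous["fruit"][:, t0:],
            np.clip(base.continuous["fruit"][:, t0:] * 1.10, 0.0, hi))
        assert np.all(arm.continuous["vegetables"][:, t0:] >= 0.0)

    def test_smoking_improvement_quits_expected_fraction(self, arm_setup):
        base = arm_setup[3]
        arm = build(arm_setup, Scenario(name="s", family="relative_improvement",
                                        factors=("smoking",)))
        t0 = base.col(2023)
        for t in (t0, t0 + 5):
            n_base = (base.smk_status[:, t] == CURRENT).sum()
            n_scen = (arm.smk_status[:, t] == CURRENT).sum()
            expected = 0.9 * n_base
            se = np.sqrt(n_base * 0.1 * 0.9)
            assert abs(n_scen - expected) < 4 * se + 1
        # remaining smokers cut cigarettes by exactly 10%
        smoker = arm.smk_status[:, t0] == CURRENT
        np.testing.assert_allclose(arm.smk_cigs[smoker, t0],
                                   base.smk_cigs[smoker, t0] * 0.9)

    def test_smoking_improvement_fraction_one_ends_smoking(self, arm_setup):
        arm = build(arm_setup, Scenario(name="s1", family="relative_improvement",
                                        factors=("smoking",),
                                        improvement_fraction=1.0))
        t0 = arm.col(2023)
        assert not np.any(arm.smk_status[:, t0:] == CURRENT)

    def test_physical_activity_gain_is_one_day_capped(self, arm_setup):
        base = arm_setup[3]
        arm = build(arm_setup, Scenario(name="pa", family="relative_improvement",
                                        factors=("physical_activity",)))
        t0 = base.col(2023)
        b = base.continuous["physical_activity"][:, t0:]
        a = arm.continuous["physical_activity"][:, t0:]
        diff = a - b
        assert np.all((np.isclose(diff, 0) | np.isclose(diff, 1))
                      | np.isclose(a, 7.0))
        assert np.all(a <= 7.0)
        changed = ~np.isclose(diff, 0)
        frac = changed[b < 7.0 - 1e-9].mean()
        assert frac == pytest.approx(0.10, abs=0.02)

    def test_ets_prevalence_non_increasing_under_smoking_scenarios(self, arm_setup):
        base = arm_setup[3]
        arm = build(arm_setup, Scenario(name="s", family="relative_improvement",
                                        factors=("smoking",)))
        t0 = base.col(2023)
        for t in range(t0, base.n_years):
            assert arm.ets[:, t].mean() <= base.ets[:, t].mean() + 1e-12

    def test_mediation_lowers_sbp_and_tc(self, arm_setup):
        cfg, cohort, _, base, tmrels = arm_setup
        direct = build(arm_setup, Scenario(
            name="b", family="relative_improvement", factors=("bmi",),
            mediation_on=False))
        mediated = build(arm_setup, Scenario(
            name="bm", family="relative_improvement", factors=("bmi",)))
        t0 = base.col(2023)
        # direct-only arm leaves SBP at base; mediated arm lowers it for
        # those with base BMI >= 25, never below the TMREL
        np.testing.assert_array_equal(direct.continuous["sbp"],
                                      base.continuous["sbp"])
        s_med = mediated.continuous["sbp"][:, t0:]
        s_base = base.continuous["sbp"][:, t0:]
        assert np.all(s_med <= s_base + 1e-12)
        assert np.all(s_med >= np.minimum(s_base, tmrels["sbp"]) - 1e-12)
        high_bmi = base.continuous["bmi"][:, t0] >= 25.0
        above = s_base[high_bmi, 0] > tmrels["sbp"]
        assert np.all(s_med[high_bmi, 0][above] < s_base[high_bmi, 0][above])


class TestScenarioValidation:
    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError, match="factors"):
            Scenario(name="x", family="tmrel", factors=("ets",))

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            Scenario(name="x", family="relative_improvement",
                     improvement_fraction=1.5)

    def test_all_expands_to_six_groups(self):
        assert len(Scenario(name="x", family="tmrel").expanded_factors) == 6
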