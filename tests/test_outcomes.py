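"""Metric aggregation: incidence, case-years, standardisation, inequality."""

import numpy as np
import pandas as pd
import pytest

from morbsim.outcomes import (
    ResultsCube,
    case_years_prevented,
    inequality_gradient,
    major_illness_incidence,
    standardise_to_reference,
    summarise,
)


def scripted_cube(count_major_base, count_major_scen, years=None,
                  n_iter=3, metric="count_major"):
    """Build a minimal two-arm cube with identical values per iteration."""
    years = years or list(range(2023, 2044))
    rows = []
    for it in range(n_iter):
        for scen, counts in (("baseline", count_major_base),
                             ("scenario", count_major_scen)):
            for y, v in zip(years, counts):
                rows.append(dict(iteration=it, scenario=scen, year=y,
                                 stratum_type="overall", stratum="all",
                                 metric=metric, value=v))
    return ResultsCube(pd.DataFrame(rows))


class TestMajorIllnessIncidence:
    def test_no_crossings(self):
        major = np.zeros((10, 2), dtype=bool)
        assert major_illness_incidence(major, np.ones(10, bool)) == 0.0

    def test_three_per_thousand(self):
        major = np.zeros((1000, 2), dtype=bool)
        major[:3, 1] = True
        assert major_illness_incidence(major, np.ones(1000, bool)) == \
            pytest.approx(0.003)

    def test_dementia_crossing_counts_once(self, registry):
        """A simulant whose score jumps from 0 to 2.50 (dementia) is exactly
        one crossing of the 1.5 threshold."""
        score_before, score_after = 0.0, registry.cms_weights["dementia"]
        major = np.array([[score_before > 1.5, score_after > 1.5]])
        assert major_illness_incidence(major, np.ones(1, bool)) == 1.0

    def test_already_major_not_at_risk(self):
        major = np.ones((5, 2), dtype=bool)
        assert major_illness_incidence(major, np.ones(5, bool)) is None

    def test_empty_denominator_flagged(self):
        major = np.zeros((5, 2), dtype=bool)
        assert major_illness_incidence(major, np.zeros(5, bool)) is None


class TestCaseYears:
    def test_identical_arms_zero(self):
        base = [500] * 21
        cube = scripted_cube(base, base)
        s = case_years_prevented(cube, "scenario")
        assert s.central == 0.0 and s.lower == s.upper == 0.0

    def test_hand_summed_identity(self):
        """100 fewer major-ill persons in each of 21 years: 2,100 case-years
        prevented."""
        cube = scripted_cube([500] * 21, [400] * 21)
        s = case_years_prevented(cube, "scenario")
        assert s.central == pytest.approx(2100.0)

    def test_negative_totals_permitted(self):
        """A scenario can increase case-years (people living longer with
        major illness)."""
        cube = scripted_cube([500] * 21, [520] * 21)
        s = case_years_prevented(cube, "scenario")
        assert s.central == pytest.approx(-420.0)
        assert s.direction_probability == 0.0

    def test_horizon_restriction(self):
        cube = scripted_cube([500] * 21, [400] * 21)
        s = case_years_prevented(cube, "scenario", horizon=(2023, 2032))
        assert s.central == pytest.approx(1000.0)

    def test_mismatched_arms_rejected(self):
        cube = scripted_cube([500] * 21, [400] * 21)
        trimmed = ResultsCube(cube.data[~((cube.data.scenario == "scenario")
                                          & (cube.data.iteration == 2))])
        with pytest.raises(ValueError, match="mismatched"):
            case_years_prevented(trimmed, "scenario")

    def test_brute_force_recount_matches(self, small_results):
        """The cube-level case-years identity equals a per-simulant recount
        of major-illness person-years on the stored flags."""
        py = small_results.person_years
        cfg = small_results.config
        it = 0
        base = py[(it, "baseline")]
        scen = py[(it, "tmrel_all")]
        brute = 0
        for mb, ms in zip(base["major"], scen["major"]):
            brute += int(mb.sum()) - int(ms.sum())
        t_base = small_results.cube.table("count_major", "baseline")
        t_scen = small_results.cube.table("count_major", "tmrel_all")
        years = [y for y in t_base.columns
                 if cfg.scenario_start <= y <= cfg.end_year]
        cube_diff = (t_base.loc[it, years] - t_scen.loc[it, years]).sum()
        assert brute == cube_diff


class TestStandardisation:
    def test_constant_prevalence_unchanged(self):
        prev = pd.Series(0.2, index=["30-39", "40-49", "50-59"])
        ref = pd.Series([100, 200, 50], index=prev.index)
        assert standardise_to_reference(prev, ref) == pytest.approx(0.2)

    def test_zero_weight_ages_ignored(self):
        prev = pd.Series([0.1, 0.9], index=["a", "b"])
        ref = pd.Series([100, 0], index=["a", "b"])
        assert standardise_to_reference(prev, ref) == pytest.approx(0.1)

    def test_two_age_hand_example(self):
        prev = pd.Series([0.10, 0.30], index=["young", "old"])
        ref = pd.Series([300, 100], index=["young", "old"])
        expected = 0.10 * 0.75 + 0.30 * 0.25
        assert standardise_to_reference(prev, ref) == pytest.approx(expected)

    def test_mismatched_support_rejected(self):
        prev = pd.Series([0.1], index=["a"])
        ref = pd.Series([1, 1], index=["a", "b"])
        with pytest.raises(ValueError, match="supports"):
            standardise_to_reference(prev, ref)


class TestInequalityGradient:
    def _quintile_cube(self, red_most, red_least, n_iter=10):
        rows = []
        for it in range(n_iter):
            for q, base_p, scen_p in (("1", 0.30, 0.30 - red_most),
                                      ("5", 0.20, 0.20 - red_least)):
                for scen, p in (("baseline", base_p), ("scenario", scen_p)):
                    rows.extend([
                        dict(iteration=it, scenario=scen, year=2043,
                             stratum_type="quintile", stratum=q,
                             metric="count_major", value=p * 1000),
                        dict(iteration=it, scenario=scen, year=2043,
                             stratum_type="quintile", stratum=q,
                             metric="population", value=1000),
                    ])
        return ResultsCube(pd.DataFrame(rows))

    def test_constant_gap_certain_direction(self):
        """A constant 0.4 pp extra reduction in the most deprived quintile
        gives difference 0.4 pp with direction probability 1."""
        cube = self._quintile_cube(red_most=0.014, red_least=0.010)
        s = inequality_gradient(cube, 2043, "scenario")
        assert s.central == pytest.approx(0.004)
        assert s.direction_probability == 1.0

    def test_null_gradient(self):
        cube = self._quintile_cube(red_most=0.01, red_least=0.01)
        s = inequality_gradient(cube, 2043, "scenario")
        assert s.central == pytest.approx(0.0)

    def test_sign_convention(self):
        """Larger reduction in the least deprived gives a negative difference."""
        cube = self._quintile_cube(red_most=0.005, red_least=0.009)
        s = inequality_gradient(cube, 2043, "scenario")
        assert s.central < 0
        assert s.direction_probability == 0.0


class TestSummarise:
    def test_identical_iterations_zero_width(self):
        s = summarise(np.full(50, 3.3))
        assert s.central == pytest.approx(3.3)
        assert s.lower == s.upper == pytest.approx(3.3)

    def test_percentiles_against_sorted_oracle(self):
        """The 2.5/97.5 percentiles of 1..100 match a hand interpolation on
        the sorted array."""
        values = np.arange(1.0, 101.0)
        s = summarise(values)

        def oracle(q):
            pos = q / 100 * (len(values) - 1)
            lo = int(np.floor(pos))
            return values[lo] + (pos - lo) * (values[lo + 1] - values[lo])

        assert s.lower == pytest.approx(oracle(2.5))
        assert s.upper == pytest.approx(oracle(97.5))

    def test_relative_difference_definition(self):
        base = np.array([0.30, 0.32])
        scen = np.array([0.27, 0.28])
        s = summarise(scen, comparator=base, relative=True)
        expected = np.mean([(0.30 - 0.27) / 0.30, (0.32 - 0.28) / 0.32])
        assert s.central == pytest.approx(expected)

    def test_single_iteration_has_no_interval(self):
        s = summarise(np.array([1.0]))
        assert s.lower is None and s.upper is None

    def test_pairing_matters(self):
        """Shuffling the iteration pairing must widen the interval of a
        paired difference (regression guard against unpaired summaries)."""
        rng = np.random.default_rng(0)
        common = rng.normal(0, 1.0, 200)
        base = common + rng.normal(0.5, 0.05, 200)
        scen = common + rng.normal(0.0, 0.05, 200)
        paired = summarise(scen, comparator=base)
        shuffled = summarise(scen, comparator=np.roll(base, 7))
        assert (shuffled.upper - shuffled.lower) > \
            2 * (paired.upper - paired.lower)


class TestCubeIntegrity:
    def test_count_conservation(self, small_results):
        """count_major + count_without equals the alive population in every
        scenario-year-stratum-iteration cell."""
        small_results.cube.validate_conservation()

    def test_demographic_accounting(self, small_results):
        """alive(t+1) = alive(t) - deaths(t+1) + entrants(t+1), exactly, from
        the stored person-year flags."""
        py = small_results.person_years
        for (it, arm), d in py.items():
            for k in range(1, len(d["years"])):
                alive_prev = d["alive"][k - 1].sum()
                expected = (alive_prev - d["deaths"][k].sum()
                            + d["entrants"][k].sum())
                assert d["alive"][k].sum() == expected, (arm, d["years"][k])

    def test_cohorts_partition_without_overlap(self, small_results):
        cube = small_results.cube.data
        cohorts = cube[cube.stratum_type == "cohort"]["stratum"].unique()
        assert len(cohorts) == 3
        # cohort age windows are disjoint by construction (30-34/50-54/70-74)
        spans = [tuple(map(int, c.split("@")[0].split("-"))) for c in cohorts]
        for (a, b), (c, d) in zip(sorted(spans), sorted(spans)[1:]):
            assert b < c
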