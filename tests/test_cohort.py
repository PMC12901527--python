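"""Grouping, exclusion cascade, stratum statistics, intersection search,
factor derivation and the basic statistical helpers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vatslice as v
from vatslice import cohort as ca


class TestAssignGroups:
    @pytest.mark.parametrize("bmi,expected", [
        (18.5, "I"), (24.9, "I"), (25.0, "II"), (29.9, "II"), (30.0, "III"),
        (34.9, "III"), (35.0, "IV"), (40.0, "V"), (49.4, "V"),
    ])
    def test_bmi_boundaries(self, bmi, expected):
        assert ca.bmi_group_of(bmi) == expected

    @pytest.mark.parametrize("age,expected", [
        (20, "i"), (29, "i"), (30, "ii"), (59, "iv"), (60, "v"), (72, "v"),
    ])
    def test_age_boundaries(self, age, expected):
        assert ca.age_group_of(age) == expected

    def test_underweight_and_underage_raise(self):
        with pytest.raises(ca.ExclusionError, match="nderweight"):
            ca.bmi_group_of(18.4)
        with pytest.raises(ca.ExclusionError):
            ca.age_group_of(19)

    def test_record_interface(self):
        g = v.assign_groups({"sex": "F", "bmi": 32.4, "age": 72})
        assert (g.sex, g.bmi_group, g.age_group) == ("F", "III", "v")


class TestApplyExclusions:
    def test_clean_cohort_unchanged(self, small_cohort):
        out, counts = ca.apply_exclusions(small_cohort)
        assert sum(counts.values()) == len(small_cohort) - len(out)
        assert counts["fat_water_swap"] == 0
        assert counts["underweight"] == 0

    def test_small_stratum_members_removed_exactly(self):
        cohort = v.generate_participants(3000, seed=9)
        planted = v.inject_exclusions(cohort, {"small_stratum": 9}, seed=10)
        out, counts = ca.apply_exclusions(planted)
        # counting oracle: every removal is accounted for by one criterion
        assert counts["small_stratum"] == 9
        assert len(out) == len(cohort) - 9

    def test_removals_conserved(self):
        cohort = v.generate_participants(2000, seed=3)
        planted = v.inject_exclusions(
            cohort, {"fat_water_swap": 4, "underweight": 6}, seed=4)
        out, counts = ca.apply_exclusions(planted)
        assert len(planted) - len(out) == sum(counts.values())


class TestStratumProfiles:
    def test_identical_profiles_have_zero_sem(self):
        profiles = pd.DataFrame({"L5": [2.0, 2.0, 2.0],
                                 "L4": [1.0, 1.0, 1.0]},
                                index=["a", "b", "c"])
        groups = pd.DataFrame({"sex": "M", "bmi_group": "I",
                               "age_group": "ii"}, index=["a", "b", "c"])
        stats = ca.stratum_profiles(profiles, groups)
        assert (stats.sem_pct == 0).all()
        assert stats.loc[stats.location == "L5", "mean_pct"].iloc[0] == 2.0

    def test_two_profile_stratum_matches_hand_computation(self):
        profiles = pd.DataFrame({"L3": [1.0, 3.0]}, index=["a", "b"])
        groups = pd.DataFrame({"sex": "F", "bmi_group": "II",
                               "age_group": "i"}, index=["a", "b"])
        stats = ca.stratum_profiles(profiles, groups)
        row = stats.iloc[0]
        assert row.mean_pct == pytest.approx(2.0)
        assert row.sem_pct == pytest.approx(np.sqrt(2.0) / np.sqrt(2))
        assert row.n == 2


def _stats_from_curves(curves: dict[str, list[float]], locations,
                       n: int = 50) -> pd.DataFrame:
    rows = []
    for ag, vals in curves.items():
        for loc, val in zip(locations, vals):
            rows.append({"sex": "M", "bmi_group": "I", "age_group": ag,
                         "location": loc, "n": n, "mean_pct": val,
                         "sem_pct": 0.0})
    return pd.DataFrame(rows)


class TestFindIntersection:
    locations = ["L5-1 cm", "L5-0.5 cm", "L5", "L5/4", "L4"]

    def test_planted_noise_free_crossing(self):
        # closed-form oracle: two lines crossing at the middle location
        stats = _stats_from_curves(
            {"i": [2.0, 1.5, 1.0, 0.5, 0.4],
             "v": [0.5, 0.75, 1.0, 1.25, 1.3]}, self.locations)
        assert ca.find_intersection(stats, "M", "I") == "L5"

    def test_identical_curves_tie_break_to_largest_mean(self):
        stats = _stats_from_curves(
            {"i": [1.0, 2.0, 3.0, 2.0, 1.0],
             "v": [1.0, 2.0, 3.0, 2.0, 1.0]}, self.locations)
        assert ca.find_intersection(stats, "M", "I") == "L5"

    def test_invariant_to_age_group_relabeling_and_offset(self):
        base = {"i": [2.0, 1.5, 1.0, 0.6, 0.5],
                "v": [0.5, 0.7, 1.0, 1.2, 1.4]}
        stats = _stats_from_curves(base, self.locations)
        loc = ca.find_intersection(stats, "M", "I")
        relabeled = _stats_from_curves(
            {"v": base["i"], "ii": base["v"]}, self.locations)
        assert ca.find_intersection(relabeled, "M", "I") == loc
        shifted = _stats_from_curves(
            {k: [x + 5.0 for x in vals] for k, vals in base.items()},
            self.locations)
        assert ca.find_intersection(shifted, "M", "I") == loc

    def test_single_age_group_is_an_error(self):
        stats = _stats_from_curves({"i": [1, 2, 3, 2, 1]}, self.locations)
        with pytest.raises(ValueError, match="two age groups"):
            ca.find_intersection(stats, "M", "I")

    def test_near_zero_locations_not_selected(self):
        # a tail location with no VAT has zero spread but carries no signal
        stats = _stats_from_curves(
            {"i": [2.0, 1.5, 1.0, 0.5, 0.001],
             "v": [0.6, 0.8, 1.2, 1.5, 0.001]}, self.locations)
        assert ca.find_intersection(stats, "M", "I") != "L4"


class TestDeriveFactor:
    def _matrix(self, pct, vat):
        df = pd.DataFrame({"L3": pct, "vat_total_l": vat},
                          index=[f"p{i}" for i in range(len(pct))])
        groups = pd.DataFrame({"sex": "M", "bmi_group": "I",
                               "age_group": "ii"}, index=df.index)
        return df, groups

    def test_closed_form_constant_fraction(self):
        # every participant holds 0.3% of VAT in the reference slice at
        # 0.3 cm thickness -> factor t/p = 100
        profiles, groups = self._matrix([0.3, 0.3, 0.3], [2.0, 3.0, 4.0])
        f = ca.derive_factor(profiles, groups, "L3", "M", "I")
        assert f == pytest.approx(100.0)

    def test_ratio_oracle(self):
        # mean VAT 2.8 l over mean area 27.2 cm² gives a factor near 103
        area = np.array([27.2, 27.2])
        vat = np.array([2.8, 2.8])
        pct = area * 0.3 / (vat * 1000) * 100
        profiles, groups = self._matrix(pct, vat)
        f = ca.derive_factor(profiles, groups, "L3", "M", "I")
        assert f == pytest.approx(1000 * 2.8 / 27.2, rel=1e-9)
        assert round(f) == 103

    def test_zero_area_rejected(self):
        profiles, groups = self._matrix([0.0, 0.0], [2.0, 3.0])
        with pytest.raises(ValueError, match="zero mean area"):
            ca.derive_factor(profiles, groups, "L3", "M", "I")

    def test_recovery_on_synthetic_stratum(self, standardized_cohort):
        # on generated data the factor must reproduce the direct
        # mean-VAT / mean-area ratio of the same stratum
        profiles, groups = standardized_cohort
        sel = groups[(groups.sex == "M") & (groups.bmi_group == "II")]
        sub = profiles.loc[sel.index]
        f = ca.derive_factor(profiles, groups, "L3", "M", "II")
        areas = sub["L3"] / 100 * sub["vat_total_l"] * 1000 / 0.3
        f_star = 1000 * sub["vat_total_l"].mean() / areas.mean()
        assert f == pytest.approx(f_star, rel=1e-12)


class TestTwoSampleT:
    def test_printed_degrees_of_freedom(self):
        rng = np.random.default_rng(1)
        res = ca.two_sample_t(rng.normal(size=5681), rng.normal(size=5355))
        assert res.df == 11_034

    def test_identical_groups_give_zero(self):
        res = ca.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0

    def test_closed_form_example(self):
        res = ca.two_sample_t([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-np.sqrt(1.5), rel=1e-6)  # -1.2247
        assert res.df == 4

    def test_matches_scipy(self):
        from scipy import stats as sps
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=40), rng.normal(0.3, 1.2, size=55)
        res = ca.two_sample_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)


class TestKdeDistance:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(0)
        d = rng.normal(12.9, 1.1, 500)
        grid, dens = ca.kde_distance(d)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_symmetric_input_symmetric_density(self):
        d = np.array([10.0, 11.0, 12.0, 14.0, 15.0, 16.0])
        grid = np.linspace(8, 18, 201)
        _, dens = ca.kde_distance(d, grid=grid)
        np.testing.assert_allclose(dens, dens[::-1], rtol=1e-9)

    def test_mode_near_population_mean(self, small_cohort):
        d = [v.generate_geometry(small_cohort.iloc[0], seed=s
                                 ).fh_l5_distance_cm for s in range(800)]
        grid, dens = ca.kde_distance(np.asarray(d))
        assert abs(grid[np.argmax(dens)] - 12.9) < 0.5

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            ca.kde_distance([12.9, 12.9, 12.9])


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_find_intersection_offset_invariance_property(seed):
    rng = np.random.default_rng(seed)
    locations = [f"loc{i}" for i in range(12)]
    curves = {ag: list(rng.uniform(1.0, 3.0, 12)) for ag in ("i", "iii", "v")}
    stats = _stats_from_curves(curves, locations)
    loc = ca.find_intersection(stats, "M", "I", min_level_frac=0.0)
    shifted = _stats_from_curves(
        {k: [x + 2.5 for x in vals] for k, vals in curves.items()}, locations)
    assert ca.find_intersection(shifted, "M", "I", min_level_frac=0.0) == loc
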