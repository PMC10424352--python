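import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amdgxe import diet
from amdgxe.io import CohortIOError, FREQUENCY_LEVELS


class TestFrequencyMapping:
    @pytest.mark.parametrize(
        "level, expected",
        [
            (FREQUENCY_LEVELS[0], 0.0),
            (FREQUENCY_LEVELS[1], 2.0 / 30.44),
            (FREQUENCY_LEVELS[2], 1.0 / 7.0),
            (FREQUENCY_LEVELS[3], 3.0 / 7.0),
            (FREQUENCY_LEVELS[4], 5.5 / 7.0),
            (FREQUENCY_LEVELS[5], 1.0),
            (FREQUENCY_LEVELS[6], 2.5),
            (FREQUENCY_LEVELS[7], 4.5),
            (FREQUENCY_LEVELS[8], 6.0),
        ],
    )
    def test_category_midpoints(self, level, expected):
        assert diet.frequency_to_daily(level) == pytest.approx(expected)

    def test_unknown_category_errors(self):
        with pytest.raises(CohortIOError):
            diet.frequency_to_daily("twice daily")

    def test_mapping_overridable(self):
        custom = dict.fromkeys(FREQUENCY_LEVELS, 2.0)
        assert diet.frequency_to_daily(FREQUENCY_LEVELS[0], custom) == 2.0


class TestItemDailyGrams:
    def test_seasonal_item_down_weighted_by_quarter(self):
        # 1/day of a 100 g serving, seasonal: 100 * 0.25 = 25 g/day
        assert diet.item_daily_grams("1 time/day", 1.0, 100.0, True) == pytest.approx(25.0)

    def test_never_consumed_gives_zero(self):
        assert diet.item_daily_grams(FREQUENCY_LEVELS[0], 5.0, 500.0, False) == 0.0

    def test_hand_arithmetic(self):
        # (3/7) occasions/day * 2 servings * 50 g
        got = diet.item_daily_grams("2-4 times/week", 2.0, 50.0, False)
        assert got == pytest.approx(3.0 / 7.0 * 2.0 * 50.0)


def _catalog(rows):
    return pd.DataFrame(
        rows, columns=["item_id", "grams_per_serving", "mufa_per_100g", "sfa_per_100g", "group"]
    )


def _ffq(rows):
    return pd.DataFrame(
        rows,
        columns=["subject_id", "item_id", "frequency_category", "servings_per_occasion", "seasonal"],
    )


class TestAggregation:
    def test_single_item_lands_in_its_group_only(self):
        cat = _catalog([["v", 100.0, 0.0, 0.0, "vegetables"]])
        ffq = _ffq([["s1", "v", "1 time/day", 1.0, False]])
        groups = diet.aggregate_groups(diet.daily_intakes(ffq, cat), cat)
        row = groups.iloc[0]
        assert row["vegetables"] == pytest.approx(100.0)
        assert all(row[g] == 0.0 for g in ("legumes", "fruits", "cereals", "fish", "meat", "dairy", "alcohol"))

    def test_group_totals_are_additive(self):
        cat = _catalog([["f1", 50.0, 0.0, 0.0, "fruits"], ["f2", 70.0, 0.0, 0.0, "fruits"]])
        ffq = _ffq([["s1", "f1", "1 time/day", 1.0, False], ["s1", "f2", "1 time/day", 1.0, False]])
        groups = diet.aggregate_groups(diet.daily_intakes(ffq, cat), cat)
        assert groups.iloc[0]["fruits"] == pytest.approx(120.0)

    def test_lipid_ratio_hand_arithmetic(self):
        # 200 g/day of (mufa 10, sfa 5) and 100 g/day of (mufa 2, sfa 8):
        # ratio = (20 + 2) / (10 + 8) = 22/18
        cat = _catalog(
            [["a", 200.0, 10.0, 5.0, "fat_only"], ["b", 100.0, 2.0, 8.0, "other"]]
        )
        ffq = _ffq(
            [["s1", "a", "1 time/day", 1.0, False], ["s1", "b", "1 time/day", 1.0, False]]
        )
        groups = diet.aggregate_groups(diet.daily_intakes(ffq, cat), cat)
        assert groups.iloc[0]["mufa_sfa_ratio"] == pytest.approx(22.0 / 18.0)

    def test_zero_saturated_fat_leaves_ratio_missing(self):
        cat = _catalog([["v", 100.0, 5.0, 0.0, "vegetables"]])
        ffq = _ffq([["s1", "v", "1 time/day", 1.0, False]])
        groups = diet.aggregate_groups(diet.daily_intakes(ffq, cat), cat)
        assert np.isnan(groups.iloc[0]["mufa_sfa_ratio"])


class TestMedians:
    def _groups(self, values_by_sex):
        rows = []
        for sex, values in values_by_sex.items():
            for i, v in enumerate(values):
                rows.append(
                    {"subject_id": f"{sex}{i}", "sex": sex, "vegetables": v, "legumes": 0.0,
                     "fruits": 0.0, "cereals": 0.0, "fish": 0.0, "meat": 0.0, "dairy": 0.0,
                     "alcohol": 0.0, "mufa_sfa_ratio": 1.0}
                )
        return pd.DataFrame(rows)

    def test_odd_and_even_count_conventions(self):
        cut = diet.sex_specific_medians(
            self._groups({"male": [10.0, 20.0, 30.0], "female": [10.0, 20.0, 30.0, 40.0]})
        )
        assert cut.medians["male"]["vegetables"] == 20.0
        assert cut.medians["female"]["vegetables"] == 25.0  # midpoint of middle two

    def test_constant_consumption_median_is_that_value(self):
        cut = diet.sex_specific_medians(self._groups({"male": [100.0, 100.0], "female": [1.0]}))
        assert cut.medians["male"]["vegetables"] == 100.0

    def test_empty_sex_stratum_errors(self):
        with pytest.raises(CohortIOError, match="no subjects"):
            diet.sex_specific_medians(self._groups({"male": [1.0]}))

    def test_cutoffs_round_trip_via_frame(self):
        cut = diet.sex_specific_medians(self._groups({"male": [1.0, 2.0], "female": [3.0]}))
        again = diet.MediScoreCutoffs.from_frame(cut.to_frame())
        assert again.medians == cut.medians


@pytest.fixture
def cutoffs():
    medians = {
        sex: {"vegetables": 100.0, "legumes": 10.0, "fruits": 100.0, "cereals": 100.0,
              "fish": 30.0, "meat": 80.0, "dairy": 150.0, "mufa_sfa_ratio": 1.0}
        for sex in ("male", "female")
    }
    return diet.MediScoreCutoffs(medians=medians)


class TestMediscore:
    def _score_one(self, make, cutoffs, **kwargs):
        return diet.mediscore(pd.DataFrame([make(**kwargs)]), cutoffs).iloc[0]

    def test_maximum_score_and_high_adherence(self, group_intake_row, cutoffs):
        row = self._score_one(
            group_intake_row, cutoffs, vegetables=200.0, legumes=20.0, fruits=200.0,
            cereals=200.0, fish=60.0, meat=10.0, dairy=10.0, alcohol=30.0, mufa_sfa_ratio=2.0,
        )
        assert row["total"] == 9 and bool(row["high_adherence"])

    def test_minimum_score(self, group_intake_row, cutoffs):
        row = self._score_one(
            group_intake_row, cutoffs, vegetables=0.0, legumes=0.0, fruits=0.0, cereals=0.0,
            fish=0.0, meat=200.0, dairy=400.0, alcohol=0.0, mufa_sfa_ratio=0.5,
        )
        assert row["total"] == 0 and not bool(row["high_adherence"])

    @pytest.mark.parametrize(
        "sex, alcohol, expected",
        [
            ("male", 30.0, 1), ("female", 30.0, 0),  # same intake scores by sex
            ("male", 10.0, 1), ("male", 50.0, 1), ("male", 9.99, 0), ("male", 50.01, 0),
            ("female", 5.0, 1), ("female", 25.0, 1), ("female", 4.99, 0), ("female", 25.01, 0),
        ],
    )
    def test_sex_specific_alcohol_window_inclusive(self, group_intake_row, cutoffs, sex, alcohol, expected):
        row = self._score_one(group_intake_row, cutoffs, sex=sex, alcohol=alcohol)
        assert row["alcohol"] == expected

    def test_adherence_boundary_at_six(self, group_intake_row, cutoffs):
        # five points: all beneficial above median, everything else scoring 0
        five = dict(vegetables=200.0, legumes=20.0, fruits=200.0, cereals=200.0, fish=60.0,
                    meat=200.0, dairy=400.0, alcohol=0.0, mufa_sfa_ratio=0.5)
        row5 = self._score_one(group_intake_row, cutoffs, **five)
        assert row5["total"] == 5 and not bool(row5["high_adherence"])
        row6 = self._score_one(group_intake_row, cutoffs, **{**five, "alcohol": 30.0})
        assert row6["total"] == 6 and bool(row6["high_adherence"])

    def test_tie_at_median_scores_against_beneficial_for_detrimental(self, group_intake_row, cutoffs):
        # exactly at the median: beneficial "above" fails, detrimental "<=" earns the point
        row = self._score_one(group_intake_row, cutoffs, vegetables=100.0, meat=80.0)
        assert row["vegetables"] == 0 and row["meat"] == 1

    def test_missing_ratio_scores_zero_and_flags(self, group_intake_row, cutoffs):
        row = self._score_one(group_intake_row, cutoffs, mufa_sfa_ratio=np.nan)
        assert row["fat_ratio"] == 0 and bool(row["ratio_missing"])


intake_values = st.floats(min_value=0.0, max_value=500.0, allow_nan=False)

_PROP_CUTOFFS = diet.MediScoreCutoffs(
    medians={
        sex: {"vegetables": 100.0, "legumes": 10.0, "fruits": 100.0, "cereals": 100.0,
              "fish": 30.0, "meat": 80.0, "dairy": 150.0, "mufa_sfa_ratio": 1.0}
        for sex in ("male", "female")
    }
)


def _intake_row(subject_id="s1", sex="male", mufa_sfa_ratio=np.nan, **groups):
    base = dict.fromkeys(
        ("vegetables", "legumes", "fruits", "cereals", "fish", "meat", "dairy", "alcohol"), 0.0
    )
    base.update(groups)
    return {"subject_id": subject_id, "sex": sex, "mufa_sfa_ratio": mufa_sfa_ratio, **base}


class TestScoreProperties:
    @settings(max_examples=60, deadline=None)
    @given(
        vals=st.lists(intake_values, min_size=8, max_size=8),
        ratio=st.floats(min_value=0.0, max_value=5.0),
        sex=st.sampled_from(["male", "female"]),
    )
    def test_total_in_range_and_equals_component_sum(self, vals, ratio, sex):
        keys = ("vegetables", "legumes", "fruits", "cereals", "fish", "meat", "dairy", "alcohol")
        row = diet.mediscore(
            pd.DataFrame([_intake_row(sex=sex, mufa_sfa_ratio=ratio, **dict(zip(keys, vals)))]),
            _PROP_CUTOFFS,
        ).iloc[0]
        components = [row[c] for c in diet.COMPONENT_NAMES]
        assert 0 <= row["total"] <= 9
        assert row["total"] == sum(components)
        assert bool(row["high_adherence"]) == (row["total"] >= 6)

    @settings(max_examples=40, deadline=None)
    @given(
        vals=st.lists(intake_values.filter(lambda v: v > 0), min_size=8, max_size=8),
        ratio=st.floats(min_value=0.01, max_value=5.0),
    )
    def test_doubling_intakes_moves_components_monotonically(self, vals, ratio):
        keys = ("vegetables", "legumes", "fruits", "cereals", "fish", "meat", "dairy", "alcohol")
        base = diet.mediscore(
            pd.DataFrame([_intake_row(mufa_sfa_ratio=ratio, **dict(zip(keys, vals)))]), _PROP_CUTOFFS
        ).iloc[0]
        doubled = diet.mediscore(
            pd.DataFrame([_intake_row(mufa_sfa_ratio=ratio,
                                      **dict(zip(keys, [2 * v for v in vals])))]), _PROP_CUTOFFS
        ).iloc[0]
        from amdgxe.io import MEDISCORE_BENEFICIAL, MEDISCORE_DETRIMENTAL
        for g in MEDISCORE_BENEFICIAL:
            assert doubled[g] >= base[g]  # can only gain the point
        for g in MEDISCORE_DETRIMENTAL:
            assert doubled[g] <= base[g]  # can only lose it

    def test_item_order_invariance(self):
        cat = _catalog(
            [["a", 100.0, 1.0, 2.0, "vegetables"], ["b", 50.0, 3.0, 1.0, "fruits"],
             ["c", 20.0, 0.5, 0.5, "meat"]]
        )
        rows = [["s1", i, "1 time/day", 1.0, False] for i in ("a", "b", "c")]
        fwd = diet.aggregate_groups(diet.daily_intakes(_ffq(rows), cat), cat)
        rev = diet.aggregate_groups(diet.daily_intakes(_ffq(rows[::-1]), cat), cat)
        pd.testing.assert_frame_equal(fwd, rev)

    def test_median_split_prevalence_bounded(self):
        # when cut-offs come from the scored population itself, each
        # beneficial component's prevalence cannot exceed 50% plus tie mass
        rng = np.random.default_rng(4)
        rows = []
        for i in range(202):
            rows.append(
                {"subject_id": f"s{i}", "sex": "male" if i % 2 else "female",
                 **{g: rng.gamma(2.0, 50.0) for g in ("vegetables", "legumes", "fruits", "cereals", "fish", "meat", "dairy")},
                 "alcohol": 0.0, "mufa_sfa_ratio": rng.gamma(2.0, 0.5)}
            )
        groups = pd.DataFrame(rows)
        scores = diet.mediscore(groups, diet.sex_specific_medians(groups)).merge(
            groups[["subject_id", "sex"]], on="subject_id"
        )
        from amdgxe.io import MEDISCORE_BENEFICIAL
        for sex, stratum in scores.groupby("sex"):
            for g in MEDISCORE_BENEFICIAL:
                assert stratum[g].mean() <= 0.5 + 1.0 / len(stratum)
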