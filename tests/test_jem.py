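"""Median cut-offs, dichotomization, and exposure-share aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import jemkit as jk
from jemkit.items import ConfigError
from brute_force import brute_median, brute_pipeline
from conftest import constant_survey, survey_from_rows

QD = "quantitative_demands"


def qd_survey(values, item_set, code="1000", gender="female"):
    return survey_from_rows(
        [(code, gender, {QD: v}) for v in values], item_set
    )


class TestCutoffs:
    def test_worked_example_median_two(self, item_set):
        """Responses {1,2,2,2,4,5,5}: median 2, so 3/4/5 count as exposed."""
        survey = qd_survey([1, 2, 2, 2, 4, 5, 5], item_set)
        cuts = jk.compute_cutoffs(survey, jk.ItemSet((item_set[QD],)))
        assert cuts[QD] == 2.0
        flags = jk.dichotomize(survey, cuts, jk.ItemSet((item_set[QD],)))
        exposed_values = sorted(survey.loc[flags[QD] == 1.0, QD])
        assert exposed_values == [4, 5, 5]

    def test_even_count_midpoint(self, item_set):
        """{1,2,3,4}: central pair (2,3) -> cut-off 2.5, exposed {3,4}."""
        sub = jk.ItemSet((item_set[QD],))
        survey = qd_survey([1, 2, 3, 4], item_set)
        cuts = jk.compute_cutoffs(survey, sub)
        assert cuts[QD] == brute_median([1, 2, 3, 4]) == 2.5
        flags = jk.dichotomize(survey, cuts, sub)
        assert sorted(survey.loc[flags[QD] == 1.0, QD]) == [3, 4]

    def test_constant_sample_nobody_exposed(self, item_set):
        survey = constant_survey([3, 3, 3, 3], item_set)
        cuts = jk.compute_cutoffs(survey, item_set)
        flags = jk.dichotomize(survey, cuts, item_set)
        assert cuts[QD] == 3.0
        assert (flags[QD] == 0.0).all()

    def test_reflection_applied_before_median(self, item_set):
        # decide_how raw {1,1,5}: aligned {5,5,1} -> median 5.
        survey = survey_from_rows(
            [("1000", "female", {"decide_how": v}) for v in (1, 1, 5)], item_set
        )
        cuts = jk.compute_cutoffs(survey, jk.ItemSet((item_set["decide_how"],)))
        assert cuts["decide_how"] == 5.0

    def test_missing_excluded_and_empty_item_errors(self, item_set):
        sub = jk.ItemSet((item_set[QD],))
        survey = qd_survey([np.nan, 2, 4, np.nan], item_set)
        cuts = jk.compute_cutoffs(survey, sub)
        assert cuts[QD] == 3.0 and cuts.n_used[QD] == 2
        with pytest.raises(ConfigError, match="no non-missing"):
            jk.compute_cutoffs(qd_survey([np.nan], item_set), sub)

    def test_out_of_range_response_rejected(self, item_set):
        sub = jk.ItemSet((item_set[QD],))
        with pytest.raises(ValueError, match="outside"):
            jk.compute_cutoffs(qd_survey([2, 9], item_set), sub)

    def test_per_wave_cutoffs(self, item_set):
        sub = jk.ItemSet((item_set[QD],))
        survey = pd.concat(
            [
                qd_survey([1, 1, 1, 2, 5], item_set).assign(wave=2006),
                qd_survey([4, 4, 4, 5, 1], item_set).assign(wave=2019),
            ],
            ignore_index=True,
        )
        by_wave = jk.compute_cutoffs(survey, sub, per_wave=True)
        assert by_wave[2006][QD] == 1.0
        assert by_wave[2019][QD] == 4.0
        flags = jk.dichotomize(survey, by_wave, sub)
        # value 2 is exposed in 2006 (cut 1) but 4 is not in 2019 (cut 4)
        assert flags.loc[(survey["wave"] == 2006) & (survey[QD] == 2), QD].eq(1).all()
        assert flags.loc[(survey["wave"] == 2019) & (survey[QD] == 4), QD].eq(0).all()


class TestDichotomize:
    @pytest.mark.parametrize(
        "cut, value, expected", [(2.0, 3, 1.0), (2.0, 2, 0.0), (2.5, 2, 0.0), (2.5, 3, 1.0)]
    )
    def test_strict_greater_rule(self, item_set, cut, value, expected):
        sub = jk.ItemSet((item_set[QD],))
        cuts = jk.CutoffTable({QD: cut}, {QD: 1})
        flags = jk.dichotomize(qd_survey([value], item_set), cuts, sub)
        assert flags[QD].iloc[0] == expected

    def test_half_integer_cut_enumerates_scale(self, item_set):
        sub = jk.ItemSet((item_set[QD],))
        cuts = jk.CutoffTable({QD: 2.5}, {QD: 5})
        flags = jk.dichotomize(qd_survey([1, 2, 3, 4, 5], item_set), cuts, sub)
        assert flags[QD].tolist() == [0.0, 0.0, 1.0, 1.0, 1.0]

    def test_missing_propagates_and_unknown_code_warns(self, item_set):
        sub = jk.ItemSet((item_set[QD],))
        survey = qd_survey([np.nan, 3], item_set)
        cuts = jk.CutoffTable({QD: 2.0}, {QD: 1})
        with pytest.warns(UserWarning, match="validation list"):
            flags = jk.dichotomize(survey, cuts, sub, valid_codes={"9999"})
        assert np.isnan(flags[QD].iloc[0]) and flags[QD].iloc[1] == 1.0


def flags_frame(cells, item_set):
    """cells: {(code, gender): list of 0/1/None flags for QD}."""
    rows = []
    for (code, gender), values in cells.items():
        for v in values:
            rows.append(
                {
                    "respondent_id": f"R{len(rows)}",
                    "wave": 2016,
                    "occupation_code": code,
                    "gender": gender,
                    QD: np.nan if v is None else float(v),
                }
            )
    df = pd.DataFrame(rows)
    for item in item_set.item_ids:
        if item != QD:
            df[item] = 0.0
    return df


class TestBuildJem:
    def test_share_is_percent_of_nonmissing(self, item_set):
        gm = jk.JemGroupMap.from_pairs([("1000", "G1")])
        flags = flags_frame({("1000", "female"): [1, 1, 1, 0, 0, 0, 0, 0]}, item_set)
        jem = jk.build_jem(flags, gm, item_set, n_min=1)
        assert jem.cell_share("G1", "female", QD) == 100.0 * 3 / 8 == 37.5

    def test_boundary_biconditionals(self, item_set):
        gm = jk.JemGroupMap.from_pairs([("1000", "G1"), ("2000", "G2")])
        flags = flags_frame(
            {
                ("1000", "female"): [1] * 12,
                ("2000", "female"): [0] * 12 + [None] * 3,
            },
            item_set,
        )
        jem = jk.build_jem(flags, gm, item_set, n_min=1)
        assert jem.cell_share("G1", "female", QD) == 100.0
        assert jem.cell_share("G2", "female", QD) == 0.0
        # and the reverse directions: share 0/100 pin the counts exactly
        t = jem.table.set_index("jem_group_id")
        assert t.loc["G1", f"n_{QD}"] == 12
        assert t.loc["G2", f"n_{QD}"] == 12  # missing flags excluded

    def test_small_cells_suppressed_to_missing_not_zero(self, item_set):
        gm = jk.JemGroupMap.from_pairs([("1000", "G1")])
        flags = flags_frame({("1000", "male"): [1, 0, 0]}, item_set)
        jem = jk.build_jem(flags, gm, item_set, n_min=10)
        assert np.isnan(jem.cell_share("G1", "male", QD))
        assert jem.table[f"n_{QD}"].iloc[0] == 3

    def test_unmapped_codes_reported_not_dropped_silently(self, item_set):
        gm = jk.JemGroupMap.from_pairs([("1000", "G1")])
        flags = flags_frame(
            {("1000", "female"): [1, 0], ("9999", "female"): [1]}, item_set
        )
        jem = jk.build_jem(flags, gm, item_set, n_min=1)
        assert jem.excluded["occupation_code"].tolist() == ["9999"]
        assert int(jem.excluded["n_rows"].sum()) == 1
        assert "9999" in jem.build_log()

    def test_empty_and_uncovered_inputs_error(self, item_set):
        gm = jk.JemGroupMap.from_pairs([("1000", "G1")])
        with pytest.raises(ConfigError, match="no exposure flags"):
            jk.build_jem(flags_frame({}, item_set), gm, item_set)
        flags = flags_frame({("8888", "female"): [1]}, item_set)
        with pytest.raises(ConfigError, match="covers none"):
            jk.build_jem(flags, gm, item_set)

    def test_permutation_invariance(self, small_survey, small_scenario, item_set):
        cuts = jk.compute_cutoffs(small_survey, item_set)
        flags = jk.dichotomize(small_survey, cuts, item_set)
        jem = jk.build_jem(flags, small_scenario.group_map, item_set, n_min=1)
        shuffled = flags.sample(frac=1, random_state=5).reset_index(drop=True)
        jem2 = jk.build_jem(shuffled, small_scenario.group_map, item_set, n_min=1)
        pd.testing.assert_frame_equal(jem.table, jem2.table)

    def test_pooling_identity(self, item_set):
        """Splitting a cell and rebuilding adds counts; shares recombine."""
        gm = jk.JemGroupMap.from_pairs([("1000", "G1")])
        part_a = {("1000", "female"): [1, 1, 0]}
        part_b = {("1000", "female"): [1, 0, 0, 0]}
        whole = {("1000", "female"): [1, 1, 0, 1, 0, 0, 0]}
        ja = jk.build_jem(flags_frame(part_a, item_set), gm, item_set, n_min=1)
        jb = jk.build_jem(flags_frame(part_b, item_set), gm, item_set, n_min=1)
        jw = jk.build_jem(flags_frame(whole, item_set), gm, item_set, n_min=1)
        na = ja.table[f"n_{QD}"].iloc[0]
        nb = jb.table[f"n_{QD}"].iloc[0]
        nw = jw.table[f"n_{QD}"].iloc[0]
        assert na + nb == nw
        weighted = (
            ja.cell_share("G1", "female", QD) * na + jb.cell_share("G1", "female", QD) * nb
        ) / nw
        assert jw.cell_share("G1", "female", QD) == pytest.approx(weighted)

    def test_pooled_genders_option(self, item_set):
        gm = jk.JemGroupMap.from_pairs([("1000", "G1")])
        flags = flags_frame(
            {("1000", "female"): [1, 1], ("1000", "male"): [0, 0]}, item_set
        )
        jem = jk.build_jem(flags, gm, item_set, stratify_by_gender=False, n_min=1)
        assert jem.table["gender"].tolist() == ["all"]
        assert jem.cell_share("G1", "all", QD) == 50.0


class TestOracleEquivalence:
    def test_shares_match_naive_double_loop(self, item_set):
        """Vectorized aggregation equals explicit per-respondent counting."""
        rng = np.random.default_rng(21)
        scenario = jk.random_scenario(
            21, n_codes=40, n_groups=15, waves=[2013, 2016],
            n_per_cell=20, missing_rate=0.1,
        )
        survey = jk.generate_survey(scenario, item_set)
        assert len(survey) >= 1000
        cuts = jk.compute_cutoffs(survey, item_set)
        flags = jk.dichotomize(survey, cuts, item_set)
        jem = jk.build_jem(flags, scenario.group_map, item_set, n_min=1)

        rows = [
            {
                "occupation_code": r.occupation_code,
                "gender": r.gender,
                **{
                    i: (None if pd.isna(getattr(r, i)) else int(getattr(r, i)))
                    for i in item_set.item_ids
                },
            }
            for r in survey.itertuples()
        ]
        oracle = brute_pipeline(
            rows, item_set, dict(scenario.group_map.entries), n_min=1
        )
        assert oracle["cutoffs"] == dict(cuts.cutoffs)
        for _, row in jem.table.iterrows():
            cell = oracle["cell_shares"][(row["jem_group_id"], row["gender"])]
            for item in item_set.item_ids:
                got = row[f"share_{item}"]
                if cell[item] is None:
                    assert pd.isna(got)
                else:
                    assert got == cell[item]


class TestExpandToCodes:
    def test_codes_inherit_group_shares_verbatim(self, item_set):
        gm = jk.JemGroupMap.from_pairs(
            [("1000", "G1"), ("1001", "G1"), ("2000", "G2")]
        )
        flags = flags_frame(
            {("1000", "female"): [1, 0], ("2000", "female"): [1, 1]}, item_set
        )
        jem = jk.build_jem(flags, gm, item_set, n_min=1)
        expanded = jk.expand_to_codes(jem, gm)
        assert len(expanded) == 3  # 3 codes x 1 gender present
        twin = expanded[expanded["jem_group_id"] == "G1"]
        assert twin[f"share_{QD}"].nunique() == 1
        assert set(twin["occupation_code"]) == {"1000", "1001"}

    def test_identity_map_is_renaming(self, item_set):
        gm = jk.JemGroupMap.from_pairs([("1000", "A"), ("2000", "B")])
        flags = flags_frame(
            {("1000", "male"): [1, 0], ("2000", "male"): [0, 0]}, item_set
        )
        jem = jk.build_jem(flags, gm, item_set, n_min=1)
        expanded = jk.expand_to_codes(jem, gm)
        assert len(expanded) == jem.n_cells
        assert expanded[f"share_{QD}"].tolist() == jem.table[f"share_{QD}"].tolist()

    def test_paper_scale_row_count(self, item_set):
        scenario = jk.random_scenario(
            17, n_codes=333, n_groups=268, waves=[2016], n_per_cell=2
        )
        survey = jk.generate_survey(scenario, item_set)
        cuts = jk.compute_cutoffs(survey, item_set)
        flags = jk.dichotomize(survey, cuts, item_set)
        jem = jk.build_jem(flags, scenario.group_map, item_set, n_min=1)
        expanded = jk.expand_to_codes(jem, scenario.group_map)
        assert len(expanded) == 333 * 2


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    values=st.lists(st.integers(1, 5), min_size=1, max_size=40),
    adverse_high=st.booleans(),
)
def test_cutoff_always_within_scale(values, adverse_high):
    """Property: the median cut-off lies inside the item's scale bounds."""
    item = jk.ItemDefinition(QD, dimension="demand", adverse_high=adverse_high)
    sub = jk.ItemSet((item,))
    survey = qd_survey(values, jk.default_item_set())
    cuts = jk.compute_cutoffs(survey, sub)
    assert 1 <= cuts[QD] <= 5
    assert cuts[QD] == brute_median(
        [v if adverse_high else 6 - v for v in values]
    )


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    flags=st.lists(
        st.one_of(st.none(), st.integers(0, 1)), min_size=1, max_size=60
    )
)
def test_share_bounds_and_boundary_equivalence(flags):
    """Property: shares live in [0,100]; 0/100 iff no exposed/non-exposed."""
    item_set = jk.default_item_set()
    gm = jk.JemGroupMap.from_pairs([("1000", "G1")])
    frame = flags_frame({("1000", "female"): flags}, item_set)
    n_obs = sum(f is not None for f in flags)
    if n_obs == 0:
        return
    jem = jk.build_jem(frame, gm, item_set, n_min=1)
    share = jem.cell_share("G1", "female", QD)
    assert 0.0 <= share <= 100.0
    n_exposed = sum(f == 1 for f in flags)
    assert (share == 0.0) == (n_exposed == 0)
    assert (share == 100.0) == (n_exposed == n_obs)
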