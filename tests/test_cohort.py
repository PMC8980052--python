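"""Index dates, phase windows, code matrices, splitting and labels."""

import numpy as np
import pandas as pd
import pytest

from tbimine import cohort
from tbimine.pipeline import default_mapping_path


@pytest.fixture
def index_dates(tiny_visits):
    return cohort.assign_index_dates(tiny_visits)


class TestIndexDates:
    def test_case_index_is_earliest_tbi_visit(self, index_dates):
        a = index_dates.set_index("patient_id").loc["A"]
        assert a["index_date"] == pd.Timestamp("2010-06-15")

    def test_reference_midpoint_odd_count(self, index_dates):
        b = index_dates.set_index("patient_id").loc["B"]
        assert b["index_date"] == pd.Timestamp("2010-06-01")

    def test_reference_midpoint_even_count_takes_earlier_middle(self, index_dates):
        d = index_dates.set_index("patient_id").loc["D"]
        assert d["index_date"] == pd.Timestamp("2011-06-01")

    def test_case_without_tbi_code_is_hard_error(self, tiny_visits):
        bad = tiny_visits.copy()
        bad["codes"] = bad["codes"].str.replace(r"S0\d\d", "I10", regex=True)
        with pytest.raises(ValueError, match="index-event code"):
            cohort.assign_index_dates(bad)

    def test_input_order_does_not_matter(self, tiny_visits):
        shuffled = tiny_visits.sample(frac=1.0, random_state=1)
        a = cohort.assign_index_dates(tiny_visits)
        b = cohort.assign_index_dates(shuffled)
        pd.testing.assert_frame_equal(a, b)


class TestPhases:
    def test_event_window_boundary_30_days(self, tiny_visits, index_dates):
        extra = pd.DataFrame(
            [
                dict(tiny_visits.iloc[1]) | {"visit_date": pd.Timestamp("2010-05-16"), "codes": "I10"},
                dict(tiny_visits.iloc[1]) | {"visit_date": pd.Timestamp("2010-05-15"), "codes": "I10"},
            ]
        )
        phased = cohort.assign_phases(pd.concat([tiny_visits, extra]), index_dates)
        by_date = phased[phased["patient_id"] == "A"].set_index("visit_date")["phase"]
        assert by_date[pd.Timestamp("2010-05-16")] == "event_window"
        assert by_date[pd.Timestamp("2010-05-15")] == "pre_injury"

    def test_window_spans_61_days_for_any_index(self, index_dates, tiny_visits):
        # every calendar day around a leap-february index; exactly 61 fall in-window
        idx = pd.DataFrame(
            [{"patient_id": "L", "pair_id": "MX", "role": "case", "sex": "M",
              "age_band": "0-17", "rural": 0, "income_q": 1,
              "index_date": pd.Timestamp("2012-02-29")}]
        )
        days = pd.date_range("2011-11-01", "2012-06-01", freq="D")
        visits = pd.DataFrame(
            {"patient_id": "L", "pair_id": "MX", "role": "case", "sex": "M",
             "age_band": "0-17", "rural": 0, "income_q": 1,
             "visit_date": days, "setting": "ED", "codes": "S060"}
        )
        phased = cohort.assign_phases(visits, idx)
        assert (phased["phase"] == "event_window").sum() == 61

    def test_five_year_boundary(self):
        idx = pd.DataFrame(
            [{"patient_id": "P", "pair_id": "M", "role": "case", "sex": "F",
              "age_band": "0-17", "rural": 0, "income_q": 1,
              "index_date": pd.Timestamp("2012-06-15")}]
        )
        visits = pd.DataFrame(
            {"patient_id": "P", "pair_id": "M", "role": "case", "sex": "F",
             "age_band": "0-17", "rural": 0, "income_q": 1,
             "visit_date": [pd.Timestamp("2007-06-15"), pd.Timestamp("2007-06-14")],
             "setting": "ED", "codes": "I10"}
        )
        phased = cohort.assign_phases(visits, idx).set_index("visit_date")["phase"]
        assert phased[pd.Timestamp("2007-06-15")] == "pre_injury"
        assert phased[pd.Timestamp("2007-06-14")] == "excluded"

    def test_every_visit_gets_exactly_one_phase(self, tiny_visits, index_dates):
        phased = cohort.assign_phases(tiny_visits, index_dates)
        assert phased["phase"].isin(["pre_injury", "event_window", "excluded"]).all()
        assert len(phased) == len(tiny_visits)


class TestCodeMatrix:
    def test_truncation_and_presence_semantics(self, tiny_visits, index_dates):
        phased = cohort.assign_phases(tiny_visits, index_dates)
        mat = cohort.build_code_matrix(phased, "event_window")
        # A's event window holds S060 twice and W19 once -> presence 1
        assert mat.loc["A", "S06"] == 1
        assert mat.loc["A", "W19"] == 1
        assert mat.to_numpy().max() == 1

    def test_u98_u99_dropped(self):
        visits = pd.DataFrame(
            {"patient_id": ["X"], "pair_id": ["M"], "role": ["case"], "sex": "M",
             "age_band": "0-17", "rural": 0, "income_q": 1,
             "visit_date": [pd.Timestamp("2010-01-01")], "setting": "ED",
             "codes": ["U98;U99;I10"], "phase": ["event_window"]}
        )
        mat = cohort.build_code_matrix(visits, "event_window")
        assert list(mat.columns) == ["I10"]

    def test_malformed_codes_warn_and_skip(self):
        visits = pd.DataFrame(
            {"patient_id": ["X"], "pair_id": ["M"], "role": ["case"], "sex": "M",
             "age_band": "0-17", "rural": 0, "income_q": 1,
             "visit_date": [pd.Timestamp("2010-01-01")], "setting": "ED",
             "codes": ["1AB;I10"], "phase": ["event_window"]}
        )
        with pytest.warns(UserWarning, match="malformed"):
            mat = cohort.build_code_matrix(visits, "event_window")
        assert list(mat.columns) == ["I10"]

    def test_idempotent_and_order_insensitive(self, tiny_visits, index_dates):
        phased = cohort.assign_phases(tiny_visits, index_dates)
        a = cohort.build_code_matrix(phased, "event_window")
        b = cohort.build_code_matrix(phased.sample(frac=1.0, random_state=2), "event_window")
        pd.testing.assert_frame_equal(a, b)

    def test_columns_lexicographic(self, tiny_visits, index_dates):
        phased = cohort.assign_phases(tiny_visits, index_dates)
        mat = cohort.build_code_matrix(phased, "event_window")
        assert list(mat.columns) == sorted(mat.columns)


class TestSplit:
    def test_sizes_8_pairs(self):
        s = cohort.split_cohort([f"M{i}" for i in range(8)], (0.5, 0.25, 0.25), seed=0)
        assert s.value_counts().to_dict() == {"train": 4, "validation": 2, "test": 2}

    def test_deterministic(self):
        pairs = [f"M{i}" for i in range(101)]
        a = cohort.split_cohort(pairs, seed=3)
        b = cohort.split_cohort(pairs, seed=3)
        pd.testing.assert_series_equal(a, b)

    def test_pair_is_the_unit_of_splitting(self, tiny_visits):
        split = cohort.split_cohort(tiny_visits["pair_id"], seed=1)
        merged = tiny_visits.merge(
            split.rename_axis("pair_id").reset_index(), on="pair_id"
        )
        assert (merged.groupby("pair_id")["split"].nunique() == 1).all()

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            cohort.split_cohort(["M0"], (0.5, 0.2, 0.2))


class TestLabels:
    @pytest.fixture
    def maps(self):
        return (
            cohort.load_mapping(default_mapping_path("severity_map.csv")),
            cohort.load_mapping(default_mapping_path("cause_map.csv")),
        )

    def test_unqualified_concussion_is_unspecified(self, maps):
        phased = pd.DataFrame(
            {"patient_id": ["A"], "pair_id": "M", "role": "case",
             "visit_date": [pd.Timestamp("2010-01-01")], "codes": ["S060"],
             "phase": ["event_window"]}
        )
        out = cohort.label_severity_and_cause(phased, *maps)
        assert out.loc["A", "severity"] == "unspecified"

    def test_falls_and_mvc_indicators(self, tiny_visits, maps):
        idx = cohort.assign_index_dates(tiny_visits)
        phased = cohort.assign_phases(tiny_visits, idx)
        out = cohort.label_severity_and_cause(phased, *maps)
        assert out.loc["A", "falls"] == 1  # W19
        assert out.loc["C", "MVC"] == 1  # V43
        assert out.loc["C", "struck"] == 1  # W22: several designations allowed
        assert out.loc["C", "severity"] == "mild"  # S061

    def test_priority_order_picks_most_severe_first(self, maps):
        phased = pd.DataFrame(
            {"patient_id": ["A"], "pair_id": "M", "role": "case",
             "visit_date": [pd.Timestamp("2010-01-01")], "codes": ["S060;S065"],
             "phase": ["event_window"]}
        )
        out = cohort.label_severity_and_cause(phased, *maps)
        assert out.loc["A", "severity"] == "severe"

    def test_contradictory_mapping_is_hard_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("pattern,category,priority\nS06,mild,1\nS06,severe,2\n")
        with pytest.raises(ValueError, match="contradictory"):
            cohort.load_mapping(p)

    def test_no_cause_match_sets_missing(self, maps):
        phased = pd.DataFrame(
            {"patient_id": ["A"], "pair_id": "M", "role": "case",
             "visit_date": [pd.Timestamp("2010-01-01")], "codes": ["S060"],
             "phase": ["event_window"]}
        )
        out = cohort.label_severity_and_cause(phased, *maps)
        assert out.loc["A", "missing"] == 1
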