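"""Species table loading, latitude index, coding, summaries, order subsets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from moltevo.simulate import make_study_like_dataset
from moltevo.traits import (TraitTable, code_binary, latitude_index,
                            load_species_table, match_tree, order_subsets,
                            summarize_by_strategy)
from moltevo.treeio import parse_newick


def _table(rows):
    cols = ["species", "order", "family", "molt_strategy", "body_mass_g",
            "mid_latitude_deg", "bdpr_flag"]
    return TraitTable(pd.DataFrame(rows, columns=cols))


TOY = [
    ("sp_a", "O1", "F1", "complete", 10.0, 5.0, False),
    ("sp_b", "O1", "F1", "partial", 20.0, 15.0, False),
    ("sp_c", "O1", "F2", "absent", 30.0, 25.0, True),
    ("sp_d", "O2", "F3", "absent", 40.0, 35.0, False),
]


class TestLoading:
    def test_valid_csv_loads(self, tmp_path):
        csv = tmp_path / "toy.csv"
        _table(TOY).to_csv(csv)
        table = load_species_table(csv)
        assert table.n_species == 4
        assert table.data["bdpr_flag"].tolist() == [False, False, True, False]

    def test_out_of_range_latitude_rejected_with_row_number(self):
        rows = list(TOY)
        rows[1] = ("sp_b", "O1", "F1", "partial", 20.0, 95.0, False)
        with pytest.raises(ValueError, match=r"row 3.*mid_latitude_deg"):
            _table(rows)

    def test_duplicate_species_rejected(self):
        rows = TOY + [("sp_a", "O9", "F9", "absent", 1.0, 1.0, False)]
        with pytest.raises(ValueError, match="duplicate species"):
            _table(rows)

    def test_missing_column_and_bad_strategy(self):
        with pytest.raises(ValueError, match="missing required columns"):
            TraitTable(pd.DataFrame({"species": ["a"]}))
        rows = list(TOY)
        rows[0] = ("sp_a", "O1", "F1", "molting", 10.0, 5.0, False)
        with pytest.raises(ValueError, match="molt_strategy"):
            _table(rows)

    def test_strategy_strings_case_insensitive(self):
        rows = [("x", "O", "F", "Complete", 1.0, 0.0, False),
                ("z", "O", "F", "ABSENT", 2.0, 1.0, False)]
        t = _table(rows)
        assert t.data["molt_strategy"].tolist() == ["complete", "absent"]


class TestLatitudeIndex:
    @pytest.mark.parametrize("south,north,expected", [
        (-10.0, 30.0, 10.0),
        (-40.0, -20.0, 30.0),
        (-25.0, 25.0, 0.0),
    ])
    def test_examples(self, south, north, expected):
        assert latitude_index(south, north) == pytest.approx(expected)

    def test_reversed_bounds_rejected(self):
        with pytest.raises(ValueError):
            latitude_index(30.0, -10.0)

    @given(st.floats(-90, 90), st.floats(-90, 90))
    def test_bounded_and_hemisphere_symmetric(self, a, b):
        south, north = min(a, b), max(a, b)
        idx = latitude_index(south, north)
        assert 0.0 <= idx <= 90.0
        assert idx == pytest.approx(latitude_index(-north, -south), abs=1e-9)


class TestCoding:
    def test_partial_excluded_and_binary_values(self):
        y, X, species = code_binary(_table(TOY))
        assert species == ["sp_a", "sp_c", "sp_d"]
        assert y.tolist() == [1, 0, 0]
        assert list(X.columns) == ["body_mass_g", "mid_latitude_deg"]

    def test_study_scale_retains_1591(self):
        _, table = make_study_like_dataset(seed=0)
        y, X, species = code_binary(table)
        assert len(species) == 1591
        assert int(y.sum()) == 532

    def test_all_partial_rejected(self):
        rows = [("a", "O", "F", "partial", 1.0, 0.0, False),
                ("b", "O", "F", "partial", 2.0, 1.0, False)]
        with pytest.raises(ValueError):
            code_binary(_table(rows))

    def test_counts_conserve(self):
        _, table = make_study_like_dataset(seed=3, n_species=400)
        counts = table.data["molt_strategy"].value_counts()
        _, _, species = code_binary(table)
        assert len(species) == table.n_species - counts.get("partial", 0)


class TestSummaries:
    def test_toy_group_statistics(self):
        rows = [("a", "O", "F", "complete", 10.0, 1.0, False),
                ("b", "O", "F", "complete", 20.0, 2.0, False),
                ("c", "O", "F", "complete", 30.0, 3.0, False),
                ("d", "O", "F", "absent", 5.0, 4.0, False)]
        s = summarize_by_strategy(_table(rows)).set_index(["group", "variable"])
        row = s.loc[("complete", "body_mass_g")]
        assert row["n"] == 3
        assert row["mean"] == pytest.approx(20.0)
        assert row["sd"] == pytest.approx(10.0)  # sample SD, n-1 denominator
        assert (row["min"], row["max"]) == (10.0, 30.0)
        other = s.loc[("partial_absent", "body_mass_g")]
        assert other["n"] == 1 and other["mean"] == pytest.approx(5.0)

    def test_empty_group_flagged(self):
        rows = [("a", "O", "F", "complete", 10.0, 1.0, False),
                ("b", "O", "F", "complete", 20.0, 2.0, False)]
        s = summarize_by_strategy(_table(rows))
        empty = s[(s.group == "partial_absent")]
        assert empty["empty"].all()
        assert empty["mean"].isna().all()


class TestOrderSubsets:
    def test_threshold_is_strictly_more_than_twenty(self):
        rows = []
        for i in range(25):
            rows.append((f"c{i}", "BigOrder", "F", "complete", 1.0, 0.0, False))
            rows.append((f"a{i}", "BigOrder", "F", "absent", 1.0, 0.0, False))
        for i in range(25):
            rows.append((f"x{i}", "Lopsided", "F", "complete", 1.0, 0.0, False))
        for i in range(5):
            rows.append((f"y{i}", "Lopsided", "F", "absent", 1.0, 0.0, False))
        for i in range(20):
            rows.append((f"u{i}", "Boundary", "F", "complete", 1.0, 0.0, False))
            rows.append((f"v{i}", "Boundary", "F", "absent", 1.0, 0.0, False))
        table = _table(rows)
        assert order_subsets(table) == ["BigOrder"]  # 20/20 is not > 20


class TestTreeMatching:
    def test_normalized_matching_and_error_listing(self):
        tree = parse_newick("((Sp_A:1,sp_b:1):1,Sp_C:2);")
        rows = [("sp a", "O", "F", "complete", 1.0, 0.0, False),
                ("SP_B", "O", "F", "absent", 1.0, 0.0, False),
                ("sp_c", "O", "F", "absent", 1.0, 0.0, False)]
        mapping = match_tree(_table(rows), tree)
        assert mapping["sp a"] == "Sp_A"
        assert mapping["SP_B"] == "sp_b"
        rows.append(("missing_one", "O", "F", "absent", 1.0, 0.0, False))
        with pytest.raises(KeyError, match="missing_one"):
            match_tree(_table(rows), tree)

    def test_bdpr_exclusion_counts(self):
        _, table = make_study_like_dataset(seed=1, n_species=500)
        flagged = int(table.data["bdpr_flag"].sum())
        reduced = table.exclude_bdpr()
        assert reduced.n_species == table.n_species - flagged
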