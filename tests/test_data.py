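"""Data model, embedded inventory, binary encoding and tabular I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cultshare.data import (
    PRACTICE_CODES,
    SchemaError,
    SocietyDataset,
    SocietyRecord,
    ValidationError,
    builtin_fixture,
    encode_practices,
    load_society_table,
    read_results,
    write_results,
    write_society_table,
)


class TestFixture:
    def test_has_22_societies(self, fixture_dataset):
        assert len(fixture_dataset) == 22

    def test_all_codes_in_vocabulary_and_nonempty(self, fixture_dataset):
        for s in fixture_dataset.societies:
            assert s.practices
            assert s.practices <= set(PRACTICE_CODES)

    @pytest.mark.parametrize(
        "name, expected",
        [
            ("Nganasan", {"RM", "KS", "WD", "NS", "PR", "RA", "DS"}),
            ("Chukchi", {"RM", "OD", "GS", "SD", "NN", "KS"}),
            ("Assiniboine", {"KS", "GS"}),
            ("Dene", {"GS", "WD", "NS", "PR", "RA"}),
        ],
    )
    def test_practice_sets(self, fixture_dataset, name, expected):
        assert set(fixture_dataset.society(name).practices) == expected

    def test_coordinates_absent(self, fixture_dataset):
        assert not any(s.has_coordinates for s in fixture_dataset.societies)


class TestEncoding:
    def test_row_sums_match_set_sizes(self, fixture_dataset, fixture_matrix):
        for s in fixture_dataset.societies:
            assert fixture_matrix.loc[s.name].sum() == len(s.practices)

    def test_total_cells_match_hand_count(self, fixture_matrix):
        # 92 practice listings across the 22 inventory rows
        assert fixture_matrix.to_numpy().sum() == 92

    def test_column_order_is_vocabulary_order(self, fixture_matrix):
        assert list(fixture_matrix.columns) == list(PRACTICE_CODES)

    def test_saturated_society_is_all_ones(self):
        ds = SocietyDataset(
            (
                SocietyRecord(name="everything", practices=frozenset(PRACTICE_CODES)),
                SocietyRecord(name="minimal", practices=frozenset({"KS"})),
            )
        )
        m = encode_practices(ds)
        assert (m.loc["everything"] == 1).all()
        assert m.loc["minimal"].sum() == 1

    @settings(deadline=None, derandomize=True)
    @given(
        sets=st.lists(
            st.frozensets(st.sampled_from(PRACTICE_CODES), min_size=1),
            min_size=2,
            max_size=8,
        )
    )
    def test_encoding_injective_on_practice_sets(self, sets):
        ds = SocietyDataset(
            tuple(
                SocietyRecord(name=f"s{i}", practices=s) for i, s in enumerate(sets)
            )
        )
        m = encode_practices(ds)
        for i, a in enumerate(sets):
            for j, b in enumerate(sets):
                rows_equal = (m.iloc[i] == m.iloc[j]).all()
                assert rows_equal == (a == b)


class TestValidation:
    def test_unknown_code_rejected(self):
        with pytest.raises(ValidationError, match="XX"):
            SocietyRecord(name="bad", practices=frozenset({"XX"}))

    def test_empty_practices_rejected(self):
        with pytest.raises(ValidationError, match="empty practice set"):
            SocietyRecord(name="bad", practices=frozenset())

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(ValidationError, match="latitude"):
            SocietyRecord(name="bad", latitude=95.0, longitude=0.0,
                          practices=frozenset({"KS"}))

    def test_duplicate_names_rejected(self):
        r = SocietyRecord(name="dup", practices=frozenset({"KS"}))
        with pytest.raises(ValidationError, match="dup"):
            SocietyDataset((r, r))


class TestSocietyTableIO:
    def test_round_trip(self, tmp_path, joined_fixture):
        path = tmp_path / "societies.csv"
        write_society_table(joined_fixture, path)
        back = load_society_table(path)
        assert back.names == joined_fixture.names
        for a, b in zip(back.societies, joined_fixture.societies):
            assert a.practices == b.practices
            assert a.latitude == pytest.approx(b.latitude)
            for v in joined_fixture.variable_roster:
                assert a.covariates[v] == pytest.approx(b.covariates[v])

    def test_unknown_practice_code_names_society(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "society,latitude,longitude,practices\nSomewhere,0.0,0.0,KS;XX\n"
        )
        with pytest.raises(ValidationError, match="Somewhere"):
            load_society_table(path)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("society,latitude,longitude\nSomewhere,0.0,0.0\n")
        with pytest.raises(SchemaError, match="practices"):
            load_society_table(path)

    def test_empty_file_is_schema_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(SchemaError, match="empty"):
            load_society_table(path)


class TestResultIO:
    def test_round_trip_preserves_pvalues(self, tmp_path, rng):
        table = pd.DataFrame(
            {"name": [f"row{i}" for i in range(20)], "p_value": rng.random(20)}
        )
        path = tmp_path / "res.csv"
        write_results(table, path)
        back = read_results(path)
        assert np.array_equal(back["p_value"].to_numpy(), table["p_value"].to_numpy())

    def test_empty_table_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            write_results(pd.DataFrame(), tmp_path / "empty.csv")


def test_fixture_is_freshly_constructed_each_call():
    a, b = builtin_fixture(), builtin_fixture()
    assert a.names == b.names and a is not b
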