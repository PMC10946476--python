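import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bloodmealnet.records import (
    RecordError, RecordTable, SchemaError, SympatryTable, read_records,
    resolve_taxa, write_records,
)
from conftest import record_rows


def _sympatry(entries):
    return SympatryTable({(t, s): n for t, s, n in entries})


class TestReadValidate:
    def test_well_formed_file_round_trips(self, tmp_path, simple_records):
        path = tmp_path / "records.csv"
        write_records(simple_records, path)
        assert read_records(path) == simple_records

    def test_unknown_habitat_label_is_schema_error(self):
        df = record_rows(("S1", "Agricultural", "Aedes aegypti", "cattle", 1))
        df["habitat"] = "Urban"
        with pytest.raises(SchemaError, match="Urban"):
            RecordTable(df)

    def test_fractional_count_is_row_error(self):
        df = record_rows(("S1", "Agricultural", "Aedes aegypti", "cattle", 1))
        df["count"] = "2.5"
        with pytest.raises(RecordError, match="2.5"):
            RecordTable(df)

    def test_missing_column_is_schema_error(self):
        df = record_rows(("S1", "Agricultural", "Aedes aegypti", "cattle", 1))
        with pytest.raises(SchemaError, match="host_taxon"):
            RecordTable(df.drop(columns=["host_taxon"]))

    def test_out_of_range_latitude_rejected(self):
        df = record_rows(("S1", "Agricultural", "Aedes aegypti", "cattle", 1))
        df["latitude"] = 95.0
        with pytest.raises(RecordError):
            RecordTable(df)

    def test_zero_count_rows_dropped_with_warning(self):
        df = record_rows(
            ("S1", "Agricultural", "Aedes aegypti", "cattle", 1),
            ("S1", "Agricultural", "Culex pipiens", "cattle", 0))
        with pytest.warns(UserWarning, match="zero-count"):
            table = RecordTable(df)
        assert len(table) == 1

    def test_duplicate_records_summed_with_warning(self):
        df = record_rows(
            ("S1", "Agricultural", "Aedes aegypti", "cattle", 2),
            ("S1", "Agricultural", "Aedes aegypti", "cattle", 3))
        with pytest.warns(UserWarning, match="duplicate"):
            table = RecordTable(df)
        assert len(table) == 1
        assert table.total_count() == 5

    def test_empty_table_writes_header_only(self, tmp_path, simple_records):
        empty = RecordTable(simple_records.frame.iloc[:0])
        path = tmp_path / "empty.csv"
        write_records(empty, path)
        assert len(read_records(path)) == 0
        assert "study_id" in path.read_text()

    def test_unicode_taxon_names_survive_round_trip(self, tmp_path):
        df = record_rows(("S1", "Agricultural", "Aedes ægypti", "Å-øst ræv", 1))
        table = RecordTable(df)
        path = tmp_path / "unicode.csv"
        write_records(table, path)
        back = read_records(path)
        assert back == table
        assert back.frame["host_taxon"].iloc[0] == "Å-øst ræv"


class TestResolveTaxa:
    def test_single_unresolved_species_becomes_spp_node(self):
        table = RecordTable(record_rows(
            ("S1", "Agricultural", "Culicoides sp.", "cattle", 2,
             {"diptera_rank": "genus", "diptera_family": "Ceratopogonidae"})))
        out, log = resolve_taxa(table)
        assert out.frame["diptera_taxon"].tolist() == ["Culicoides spp."]
        assert log.removed_interactions == 0

    def test_ambiguous_congeners_removed_when_sympatric(self):
        table = RecordTable(record_rows(
            ("S1", "Agricultural", "Culicoides sp. A", "cattle", 2,
             {"diptera_rank": "genus", "diptera_family": "Ceratopogonidae"}),
            ("S1", "Agricultural", "Culicoides sp. B", "human", 1,
             {"diptera_rank": "genus", "diptera_family": "Ceratopogonidae"})))
        out, log = resolve_taxa(table, _sympatry([("Culicoides", "S1", 3)]))
        assert len(out) == 0
        assert log.removed_interactions == 2

    def test_multiple_unresolved_collapse_when_no_congeners(self):
        table = RecordTable(record_rows(
            ("S1", "Agricultural", "Culicoides sp. A", "cattle", 2,
             {"diptera_rank": "genus", "diptera_family": "Ceratopogonidae"}),
            ("S1", "Agricultural", "Culicoides sp. B", "human", 1,
             {"diptera_rank": "genus", "diptera_family": "Ceratopogonidae"})))
        out, log = resolve_taxa(table, _sympatry([("Culicoides", "S1", 1)]))
        assert set(out.frame["diptera_taxon"]) == {"Culicoides spp."}
        assert len(out) == 2

    def test_missing_sympatry_entry_removes_rows_with_disposition(self):
        table = RecordTable(record_rows(
            ("S1", "Agricultural", "Anopheles sp. A", "cattle", 1,
             {"diptera_rank": "genus"}),
            ("S1", "Agricultural", "Anopheles sp. B", "cattle", 1,
             {"diptera_rank": "genus"})))
        out, log = resolve_taxa(table)   # empty sympatry table
        assert len(out) == 0
        reasons = {d["reason"] for d in log.dispositions}
        assert "unresolvable_no_sympatry_entry" in reasons

    def test_above_family_rank_removed(self):
        table = RecordTable(record_rows(
            ("S1", "Agricultural", "Aedes aegypti", "Aves", 3,
             {"host_rank": "class"})))
        out, log = resolve_taxa(table)
        assert len(out) == 0
        assert log.removed_interactions == 1
        assert log.removed_hosts == 1

    def test_fully_resolved_table_unchanged(self, simple_records):
        out, log = resolve_taxa(simple_records)
        assert out == simple_records
        assert log.empty

    def test_sympatry_rule_applies_per_study(self):
        rows = record_rows(
            ("S1", "Agricultural", "Culicoides sp. A", "cattle", 1,
             {"diptera_rank": "genus"}),
            ("S1", "Agricultural", "Culicoides sp. B", "cattle", 1,
             {"diptera_rank": "genus"}),
            ("S2", "Agricultural", "Culicoides sp. A", "cattle", 1,
             {"diptera_rank": "genus"}),
            ("S2", "Agricultural", "Culicoides sp. B", "cattle", 1,
             {"diptera_rank": "genus"}))
        sym = _sympatry([("Culicoides", "S1", 4), ("Culicoides", "S2", 1)])
        out, log = resolve_taxa(RecordTable(rows), sym)
        assert set(out.frame["study_id"]) == {"S2"}
        assert log.removed_interactions == 2

    def test_row_conservation_and_idempotence(self):
        rows = record_rows(
            ("S1", "Agricultural", "Culicoides sp.", "cattle", 2,
             {"diptera_rank": "genus"}),
            ("S1", "Agricultural", "Aedes aegypti", "Anas sp.", 1,
             {"host_rank": "genus"}),
            ("S1", "Agricultural", "Anopheles sp. A", "human", 1,
             {"diptera_rank": "genus"}),
            ("S1", "Agricultural", "Anopheles sp. B", "human", 1,
             {"diptera_rank": "genus"}),
            ("S2", "NearNatural", "Culex pipiens", "Vulpes vulpes", 5))
        table = RecordTable(rows)
        out, log = resolve_taxa(table)
        assert len(table) == len(out) + log.removed_interactions
        again, log2 = resolve_taxa(out)
        assert again == out
        assert log2.removed_interactions == 0


@settings(max_examples=30, deadline=None)
@given(counts=st.lists(st.integers(min_value=1, max_value=50),
                       min_size=1, max_size=8))
def test_round_trip_preserves_any_valid_table(tmp_path_factory, counts):
    """read(write(x)) == x for arbitrary count vectors."""
    rows = record_rows(*[
        ("S1", "Agricultural", f"Fly {i}", f"Host {i}", c)
        for i, c in enumerate(counts)])
    table = RecordTable(rows)
    path = tmp_path_factory.mktemp("rt") / "r.csv"
    write_records(table, path)
    assert read_records(path) == table
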