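import numpy as np
import pandas as pd
import pytest

from kinetrace import (
    ReadOnlyError,
    SchemaVersionError,
    Store,
    to_long,
    to_wide,
)
from kinetrace.store import SCHEMA_VERSION


def table_names(store):
    return {
        r[0]
        for r in store.conn.execute(
            "SELECT name FROM sqlite_master WHERE type IN ('table', 'view')"
        )
    }


class TestSchema:
    def test_core_tables_and_views_exist(self, store):
        names = table_names(store)
        assert {"experiment", "roi", "iocbio"} <= names
        assert {"roi_linear", "roi_stats", "mm_fit", "rate_summary"} <= names
        assert {"protein_content", "experiment_summary"} <= names

    def test_double_init_is_noop(self, store):
        before = table_names(store)
        store.init_schema()
        assert table_names(store) == before
        rows = store.conn.execute("SELECT COUNT(*) FROM iocbio").fetchone()[0]
        assert rows == 1
        assert store.schema_version() == SCHEMA_VERSION

    def test_forward_migration_from_older_version(self):
        with Store(":memory:") as s:
            s.init_schema()
            # wind the store back to schema v1 (no hardware column)
            s.conn.execute("ALTER TABLE experiment DROP COLUMN hardware")
            s.conn.execute("UPDATE iocbio SET version = 1")
            s.init_schema()
            cols = {r[1] for r in s.conn.execute("PRAGMA table_info(experiment)")}
            assert "hardware" in cols
            assert s.schema_version() == SCHEMA_VERSION

    def test_newer_version_refused(self):
        with Store(":memory:") as s:
            s.init_schema()
            s.conn.execute("UPDATE iocbio SET version = ?", (SCHEMA_VERSION + 1,))
            with pytest.raises(SchemaVersionError, match="upgrade"):
                s.init_schema()


class TestImport:
    def test_reimport_same_bytes_is_deduplicated(self, store, clean_experiment):
        data, _ = clean_experiment
        first = store.import_experiment(data)
        assert not first.duplicate
        n_raw = store.conn.execute("SELECT COUNT(*) FROM raw_trace").fetchone()[0]
        second = store.import_experiment(data)
        assert second.duplicate
        assert store.conn.execute("SELECT COUNT(*) FROM experiment").fetchone()[0] == 1
        assert store.conn.execute("SELECT COUNT(*) FROM raw_trace").fetchone()[0] == n_raw

    def test_different_experiments_coexist(self, store, clean_experiment):
        import kinetrace as kt

        data, _ = clean_experiment
        other, _ = kt.simulate_respirometry(kt.SyntheticProtocol(seed=1, noise_sd=0.1))
        store.import_experiment(data)
        store.import_experiment(other)
        assert store.conn.execute("SELECT COUNT(*) FROM experiment").fetchone()[0] == 2

    def test_load_data_round_trip(self, store, clean_experiment):
        data, _ = clean_experiment
        store.import_experiment(data)
        back = store.load_data(data.experiment_id)
        assert back.experiment_id == data.experiment_id
        assert back.kind == data.kind
        np.testing.assert_array_equal(
            back.trace("O2").argument, data.trace("O2").argument
        )
        np.testing.assert_array_equal(back.trace("O2").values, data.trace("O2").values)
        assert [e.text for e in back.events] == [e.text for e in data.events]
        assert back.config["chamber_volume_ml"] == 2.0

    def test_import_in_read_only_mode(self, store, clean_experiment):
        data, _ = clean_experiment
        store.set_read_only(True)
        with pytest.raises(ReadOnlyError):
            store.import_experiment(data)

    def test_delete_cascades_to_rois_traces_results(self, analyzed_store):
        store, experiment_id = analyzed_store
        store.delete_experiment(experiment_id)
        for table in ("roi", "raw_trace", "roi_linear", "mm_fit", "rate_summary",
                      "event", "config"):
            count = store.conn.execute(f"SELECT COUNT(*) FROM {table}").fetchone()[0]
            assert count == 0, table


class TestProteinContent:
    def test_success_filtered_batch_mean_difference(self, store):
        for value, ok in [(2.0, True), (2.2, True), (9.9, False)]:
            store.add_protein_measurement("bs", value, success=ok)
        for value in (0.1, 0.1):
            store.add_protein_measurement("bb", value)
        store.link_protein_batches("s1", "bs", "bb")
        assert store.mean_protein_content("s1") == pytest.approx(2.0)

    def test_all_sample_readings_failed_row_absent(self, store):
        store.add_protein_measurement("bs", 2.0, success=False)
        store.add_protein_measurement("bb", 0.1)
        store.link_protein_batches("s1", "bs", "bb")
        assert store.mean_protein_content("s1") is None

    def test_negative_cp_emitted_as_is(self, store):
        store.add_protein_measurement("bs", 0.1)
        store.add_protein_measurement("bb", 2.0)
        store.link_protein_batches("s1", "bs", "bb")
        assert store.mean_protein_content("s1") == pytest.approx(-1.9)


class TestNormalizedSummary:
    def _add_metadata(self, store, experiment_id, cp_sample=2.1, cp_buffer=0.1):
        store.add_sample_link(experiment_id, "s1", 2.0, 0.05)
        store.add_protein_measurement("bs", cp_sample)
        store.add_protein_measurement("bb", cp_buffer)
        store.link_protein_batches("s1", "bs", "bb")

    def test_rate_normalization_formula(self, analyzed_store):
        store, experiment_id = analyzed_store
        self._add_metadata(store, experiment_id)  # Cp = 2.0 mg/ml
        factor = 2.0 / (0.05 * 2.0)  # Vc / (Vs * Cp) = 20 ml per mg
        mm = store.table("mm_fit").iloc[0]
        rs = store.table("rate_summary").iloc[0]
        row = store.table("experiment_summary").iloc[0]
        assert row["v0"] == pytest.approx(mm["v0"] * factor, rel=1e-9)
        assert row["vmax"] == pytest.approx(mm["vmax"] * factor, rel=1e-9)
        assert row["vtotal"] == pytest.approx((mm["v0"] + mm["vmax"]) * factor, rel=1e-9)
        assert row["vmin"] == pytest.approx(rs["vmin"] * factor, rel=1e-9)
        assert row["vmax_measured"] == pytest.approx(
            rs["vmax_measured"] * factor, rel=1e-9
        )
        # km and fcr need no normalization and pass through unchanged
        assert row["km"] == mm["km"]
        assert row["fcr"] == rs["fcr"]

    def test_experiment_without_sample_link_absent(self, analyzed_store):
        store, _ = analyzed_store
        assert len(store.table("experiment_summary")) == 0

    def test_nonpositive_cp_excluded(self, analyzed_store):
        store, experiment_id = analyzed_store
        self._add_metadata(store, experiment_id, cp_sample=0.1, cp_buffer=2.0)
        assert len(store.table("experiment_summary")) == 0


class TestExport:
    def test_long_unpivots_non_key_columns(self, store):
        df = pd.DataFrame(
            {"experiment_id": ["a", "b"], "v0": [1.0, 2.0], "vmax": [3.0, 4.0],
             "km": [0.1, 0.2]}
        )
        long = to_long(df)
        assert len(long) == 6  # 2 rows x 3 value columns
        assert set(long.columns) == {"experiment_id", "variable", "value"}

    def test_long_wide_long_round_trip(self, analyzed_store):
        store, _ = analyzed_store
        long = store.query_export("SELECT * FROM rate_summary", shape="long")
        back = to_long(to_wide(long))
        key = ["experiment_id", "variable"]
        a = long.sort_values(key).reset_index(drop=True)
        b = back.sort_values(key).reset_index(drop=True)[long.columns]
        pd.testing.assert_frame_equal(a, b)

    def test_extra_key_columns(self, store):
        df = pd.DataFrame({"batch": ["x"], "v": [1.0], "w": [2.0]})
        long = to_long(df, keys=("batch",))
        assert set(long["variable"]) == {"v", "w"}
        assert list(long.columns) == ["batch", "variable", "value"]

    def test_mutating_query_rejected(self, store):
        with pytest.raises(ReadOnlyError):
            store.query_export("DELETE FROM roi")
        with pytest.raises(ReadOnlyError):
            store.query_export("DROP TABLE roi")
        # store untouched
        assert "roi" in table_names(store)

    def test_reads_identical_in_both_modes(self, analyzed_store):
        store, _ = analyzed_store
        wide = store.query_export("SELECT * FROM mm_fit")
        store.set_read_only(True)
        pd.testing.assert_frame_equal(store.query_export("SELECT * FROM mm_fit"), wide)
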