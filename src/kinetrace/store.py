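"""Relational persistence for experiments, ROIs, analysis results and the
normalization views.

The store keeps everything an analysis touches — raw samples, regions of
interest, per-ROI and per-experiment results, and the sample/protein metadata
used for normalization — in one relational database, so a finished analysis
can be reproduced or audited end-to-end with plain SQL. The default engine is
a single-file SQLite database (``:memory:`` works for throwaway sessions);
core tables are ``experiment``, ``roi`` and the ``iocbio`` schema-version
table, everything else is owned by analysis modules.

Normalization happens in views, the database analogue of a spreadsheet
formula column:

* ``protein_content(sample_id, cp)`` — mean of the successful sample-batch
  protein readings minus mean of the successful buffer-batch readings;
* ``experiment_summary`` — per-experiment kinetic results with every rate
  multiplied by chamber volume and divided by sample volume and protein
  content (nmol O2 min^-1 mg protein^-1); km and the flux control ratio
  need no normalization and are carried over unchanged.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ReadOnlyError, SchemaVersionError, ValidationError
from .trace_model import Data, Trace, build_data

__all__ = ["Store", "ExperimentRecord", "to_long", "to_wide"]

SCHEMA_VERSION = 2
_COMPONENT = "kinetrace"

_SCHEMA = """
CREATE TABLE IF NOT EXISTS iocbio (
    component TEXT PRIMARY KEY,
    version   INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS experiment (
    experiment_id TEXT PRIMARY KEY,
    filename      TEXT,
    kind          TEXT NOT NULL,
    imported_at   TEXT NOT NULL,
    hardware      TEXT
);
CREATE TABLE IF NOT EXISTS roi (
    roi_id        INTEGER PRIMARY KEY,
    experiment_id TEXT NOT NULL REFERENCES experiment(experiment_id) ON DELETE CASCADE,
    lo            REAL NOT NULL,
    hi            REAL NOT NULL,
    trace_name    TEXT NOT NULL DEFAULT 'all',
    event_name    TEXT,
    event_value   REAL,
    analysis_id   TEXT NOT NULL,
    UNIQUE (experiment_id, lo, hi, trace_name),
    CHECK (lo < hi)
);
CREATE TABLE IF NOT EXISTS raw_trace (
    experiment_id TEXT NOT NULL REFERENCES experiment(experiment_id) ON DELETE CASCADE,
    trace_name    TEXT NOT NULL,
    argument      REAL NOT NULL,
    value         REAL NOT NULL
);
CREATE INDEX IF NOT EXISTS raw_trace_exp ON raw_trace(experiment_id, trace_name);
CREATE TABLE IF NOT EXISTS trace_channel (
    experiment_id TEXT NOT NULL REFERENCES experiment(experiment_id) ON DELETE CASCADE,
    trace_name    TEXT NOT NULL,
    unit          TEXT NOT NULL DEFAULT '',
    argument_kind TEXT NOT NULL DEFAULT 'time',
    PRIMARY KEY (experiment_id, trace_name)
);
CREATE TABLE IF NOT EXISTS event (
    experiment_id TEXT NOT NULL REFERENCES experiment(experiment_id) ON DELETE CASCADE,
    at            REAL NOT NULL,
    text          TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS config (
    experiment_id TEXT NOT NULL REFERENCES experiment(experiment_id) ON DELETE CASCADE,
    key           TEXT NOT NULL,
    value         TEXT,
    PRIMARY KEY (experiment_id, key)
);
CREATE TABLE IF NOT EXISTS roi_stats (
    roi_id  INTEGER PRIMARY KEY REFERENCES roi(roi_id) ON DELETE CASCADE,
    mean    REAL,
    median  REAL,
    sd      REAL,
    status  TEXT NOT NULL DEFAULT 'ok'
);
CREATE TABLE IF NOT EXISTS roi_linear (
    roi_id    INTEGER PRIMARY KEY REFERENCES roi(roi_id) ON DELETE CASCADE,
    slope     REAL,
    intercept REAL,
    r2        REAL,
    rate      REAL,
    status    TEXT NOT NULL DEFAULT 'ok'
);
CREATE TABLE IF NOT EXISTS mm_fit (
    experiment_id TEXT PRIMARY KEY REFERENCES experiment(experiment_id) ON DELETE CASCADE,
    v0        REAL,
    vmax      REAL,
    km        REAL,
    rss       REAL,
    n         INTEGER,
    converged INTEGER,
    status    TEXT NOT NULL DEFAULT 'ok'
);
CREATE TABLE IF NOT EXISTS rate_summary (
    experiment_id TEXT PRIMARY KEY REFERENCES experiment(experiment_id) ON DELETE CASCADE,
    vmin          REAL,
    vmax_measured REAL,
    fcr           REAL
);
CREATE TABLE IF NOT EXISTS sample_link (
    experiment_id     TEXT PRIMARY KEY REFERENCES experiment(experiment_id) ON DELETE CASCADE,
    sample_id         TEXT NOT NULL,
    chamber_volume_ml REAL NOT NULL CHECK (chamber_volume_ml > 0),
    sample_volume_ml  REAL NOT NULL CHECK (sample_volume_ml > 0)
);
CREATE TABLE IF NOT EXISTS protein_measurement (
    measurement_id INTEGER PRIMARY KEY,
    batch_id       TEXT NOT NULL,
    value          REAL NOT NULL CHECK (value >= 0),
    success        INTEGER NOT NULL DEFAULT 1
);
CREATE TABLE IF NOT EXISTS protein_batch_link (
    sample_id    TEXT PRIMARY KEY,
    sample_batch TEXT NOT NULL,
    buffer_batch TEXT NOT NULL,
    CHECK (sample_batch <> buffer_batch)
);
CREATE VIEW IF NOT EXISTS protein_content AS
    SELECT l.sample_id AS sample_id,
           s.cp - b.cp AS cp
    FROM protein_batch_link AS l
    JOIN (SELECT batch_id, AVG(value) AS cp
          FROM protein_measurement WHERE success = 1 GROUP BY batch_id) AS s
         ON s.batch_id = l.sample_batch
    JOIN (SELECT batch_id, AVG(value) AS cp
          FROM protein_measurement WHERE success = 1 GROUP BY batch_id) AS b
         ON b.batch_id = l.buffer_batch;
CREATE VIEW IF NOT EXISTS experiment_summary AS
    SELECT m.experiment_id AS experiment_id,
           sl.sample_id AS sample_id,
           m.km AS km,
           r.fcr AS fcr,
           m.n AS n,
           m.converged AS converged,
           m.v0   * sl.chamber_volume_ml / (sl.sample_volume_ml * pc.cp) AS v0,
           m.vmax * sl.chamber_volume_ml / (sl.sample_volume_ml * pc.cp) AS vmax,
           (m.v0 + m.vmax) * sl.chamber_volume_ml / (sl.sample_volume_ml * pc.cp) AS vtotal,
           r.vmin * sl.chamber_volume_ml / (sl.sample_volume_ml * pc.cp) AS vmin,
           r.vmax_measured * sl.chamber_volume_ml / (sl.sample_volume_ml * pc.cp) AS vmax_measured
    FROM mm_fit AS m
    JOIN rate_summary AS r ON r.experiment_id = m.experiment_id
    JOIN sample_link  AS sl ON sl.experiment_id = m.experiment_id
    JOIN protein_content AS pc ON pc.sample_id = sl.sample_id
    WHERE pc.cp > 0;
"""

# forward migrations: version -> callable(conn) bringing the schema to version+1
def _migrate_1_to_2(conn: sqlite3.Connection) -> None:
    # v1 experiment table had no hardware tag
    cols = [r[1] for r in conn.execute("PRAGMA table_info(experiment)")]
    if "hardware" not in cols:
        conn.execute("ALTER TABLE experiment ADD COLUMN hardware TEXT")


_MIGRATIONS = {1: _migrate_1_to_2}

#: sqlite authorizer actions permitted while running a read-only export query
_READ_ACTIONS = {
    sqlite3.SQLITE_SELECT,
    sqlite3.SQLITE_READ,
    sqlite3.SQLITE_FUNCTION,
    getattr(sqlite3, "SQLITE_RECURSIVE", 33),
}


def _deny_writes(action, *_args):
    return sqlite3.SQLITE_OK if action in _READ_ACTIONS else sqlite3.SQLITE_DENY


@dataclass(frozen=True)
class ExperimentRecord:
    experiment_id: str
    filename: str | None
    kind: str
    imported_at: str
    hardware: str | None
    duplicate: bool = False


def _parse_scalar(text):
    if text is None:
        return None
    try:
        return float(text)
    except (TypeError, ValueError):
        return text


class Store:
    """Connection to the result database plus the operations the pipeline needs.

    ``read_only`` guards every mutating verb; reads are always allowed.
    """

    def __init__(self, path: str | Path = ":memory:", read_only: bool = False):
        self.path = str(path)
        self.read_only = bool(read_only)
        self.conn = sqlite3.connect(self.path)
        self.conn.execute("PRAGMA foreign_keys = ON")

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- read-only toggle --------------------------------------------------

    def set_read_only(self, flag: bool) -> "Store":
        self.read_only = bool(flag)
        return self

    def _writable(self) -> None:
        if self.read_only:
            raise ReadOnlyError(
                "store is in read-only mode; toggle it off to modify data"
            )

    # -- schema ------------------------------------------------------------

    def schema_version(self) -> int | None:
        try:
            row = self.conn.execute(
                "SELECT version FROM iocbio WHERE component = ?", (_COMPONENT,)
            ).fetchone()
        except sqlite3.OperationalError:
            return None
        return None if row is None else int(row[0])

    def init_schema(self) -> "Store":
        """Create missing tables/views and apply forward schema migrations.

        Idempotent: rerunning at the current version changes nothing. A store
        written by a newer code version is refused rather than corrupted.
        """
        self._writable()
        version = self.schema_version()
        if version is not None and version > SCHEMA_VERSION:
            raise SchemaVersionError(
                f"store schema version {version} is newer than the supported "
                f"{SCHEMA_VERSION}; upgrade kinetrace to open this database"
            )
        with self.conn:
            while version is not None and version < SCHEMA_VERSION:
                _MIGRATIONS[version](self.conn)
                version += 1
            self.conn.executescript(_SCHEMA)
            self.conn.execute(
                "INSERT INTO iocbio (component, version) VALUES (?, ?) "
                "ON CONFLICT(component) DO UPDATE SET version = excluded.version",
                (_COMPONENT, SCHEMA_VERSION),
            )
        return self

    # -- experiments -------------------------------------------------------

    def import_experiment(self, data: Data) -> ExperimentRecord:
        """Insert an experiment and its raw samples; deduplicate on ID.

        Re-importing byte-identical raw data (same experiment ID) writes
        nothing and returns the existing record flagged ``duplicate``.
        """
        self._writable()
        row = self.conn.execute(
            "SELECT experiment_id, filename, kind, imported_at, hardware "
            "FROM experiment WHERE experiment_id = ?",
            (data.experiment_id,),
        ).fetchone()
        if row is not None:
            return ExperimentRecord(*row, duplicate=True)

        imported_at = datetime.now(timezone.utc).isoformat(timespec="seconds")
        filename = data.config.get("filename")
        hardware = data.config.get("hardware")
        with self.conn:
            self.conn.execute(
                "INSERT INTO experiment (experiment_id, filename, kind, imported_at, hardware) "
                "VALUES (?, ?, ?, ?, ?)",
                (data.experiment_id, filename, data.kind, imported_at, hardware),
            )
            for name, tr in data.traces.items():
                self.conn.execute(
                    "INSERT INTO trace_channel (experiment_id, trace_name, unit, argument_kind) "
                    "VALUES (?, ?, ?, ?)",
                    (data.experiment_id, name, tr.unit, tr.argument_kind),
                )
                self.conn.executemany(
                    "INSERT INTO raw_trace (experiment_id, trace_name, argument, value) "
                    "VALUES (?, ?, ?, ?)",
                    (
                        (data.experiment_id, name, float(a), float(v))
                        for a, v in zip(tr.argument, tr.values)
                    ),
                )
            self.conn.executemany(
                "INSERT INTO event (experiment_id, at, text) VALUES (?, ?, ?)",
                ((data.experiment_id, ev.at, ev.text) for ev in data.events),
            )
            self.conn.executemany(
                "INSERT INTO config (experiment_id, key, value) VALUES (?, ?, ?)",
                ((data.experiment_id, k, str(v)) for k, v in data.config.items()),
            )
        return ExperimentRecord(
            data.experiment_id, filename, data.kind, imported_at, hardware
        )

    def has_experiment(self, experiment_id: str) -> bool:
        row = self.conn.execute(
            "SELECT 1 FROM experiment WHERE experiment_id = ?", (experiment_id,)
        ).fetchone()
        return row is not None

    def load_data(self, experiment_id: str) -> Data:
        """Reconstruct the Data object for an already-imported experiment."""
        row = self.conn.execute(
            "SELECT kind FROM experiment WHERE experiment_id = ?", (experiment_id,)
        ).fetchone()
        if row is None:
            raise LookupError(f"unknown experiment {experiment_id!r}")
        kind = row[0]
        traces = {}
        for name, unit, argkind in self.conn.execute(
            "SELECT trace_name, unit, argument_kind FROM trace_channel "
            "WHERE experiment_id = ? ORDER BY trace_name",
            (experiment_id,),
        ):
            samples = self.conn.execute(
                "SELECT argument, value FROM raw_trace "
                "WHERE experiment_id = ? AND trace_name = ? ORDER BY rowid",
                (experiment_id, name),
            ).fetchall()
            arr = np.asarray(samples, dtype=float)
            traces[name] = Trace(
                name=name, argument=arr[:, 0], values=arr[:, 1],
                unit=unit, argument_kind=argkind,
            )
        events = self.conn.execute(
            "SELECT at, text FROM event WHERE experiment_id = ? ORDER BY at, rowid",
            (experiment_id,),
        ).fetchall()
        config = {
            k: _parse_scalar(v)
            for k, v in self.conn.execute(
                "SELECT key, value FROM config WHERE experiment_id = ?",
                (experiment_id,),
            )
        }
        return build_data(
            traces, events=events, config=config, kind=kind,
            experiment_id=experiment_id,
        )

    def delete_experiment(self, experiment_id: str) -> None:
        self._writable()
        with self.conn:
            self.conn.execute(
                "DELETE FROM experiment WHERE experiment_id = ?", (experiment_id,)
            )

    # -- regions of interest -----------------------------------------------

    def insert_roi(
        self,
        experiment_id: str,
        lo: float,
        hi: float,
        trace_name: str = "all",
        event_name: str | None = None,
        event_value: float | None = None,
        analysis_id: str = "roi_linear",
    ) -> int:
        """Insert a ROI; keyed by (experiment, lo, hi, trace) so a re-run of
        the automatic split never duplicates rows. Returns the roi_id."""
        self._writable()
        with self.conn:
            cur = self.conn.execute(
                "INSERT INTO roi (experiment_id, lo, hi, trace_name, event_name, "
                "event_value, analysis_id) VALUES (?, ?, ?, ?, ?, ?, ?) "
                "ON CONFLICT(experiment_id, lo, hi, trace_name) DO NOTHING",
                (experiment_id, lo, hi, trace_name, event_name, event_value, analysis_id),
            )
            if cur.lastrowid and cur.rowcount:
                return int(cur.lastrowid)
        row = self.conn.execute(
            "SELECT roi_id FROM roi WHERE experiment_id = ? AND lo = ? AND hi = ? "
            "AND trace_name = ?",
            (experiment_id, lo, hi, trace_name),
        ).fetchone()
        return int(row[0])

    def get_rois(self, experiment_id: str) -> list[sqlite3.Row]:
        cur = self.conn.execute(
            "SELECT roi_id, experiment_id, lo, hi, trace_name, event_name, "
            "event_value, analysis_id FROM roi WHERE experiment_id = ? ORDER BY lo",
            (experiment_id,),
        )
        cur.row_factory = sqlite3.Row
        return cur.fetchall()

    def update_roi_bounds(self, roi_id: int, lo: float, hi: float) -> None:
        """Replace ROI bounds and invalidate every downstream result."""
        self._writable()
        if not lo < hi:
            raise ValidationError(f"degenerate ROI range [{lo}, {hi})")
        with self.conn:
            row = self.conn.execute(
                "SELECT experiment_id FROM roi WHERE roi_id = ?", (roi_id,)
            ).fetchone()
            if row is None:
                raise LookupError(f"unknown roi_id {roi_id}")
            self.conn.execute(
                "UPDATE roi SET lo = ?, hi = ? WHERE roi_id = ?", (lo, hi, roi_id)
            )
            self._invalidate_roi(roi_id, row[0])

    def delete_roi(self, roi_id: int) -> None:
        self._writable()
        with self.conn:
            row = self.conn.execute(
                "SELECT experiment_id FROM roi WHERE roi_id = ?", (roi_id,)
            ).fetchone()
            if row is not None:
                self._invalidate_roi(roi_id, row[0])
            self.conn.execute("DELETE FROM roi WHERE roi_id = ?", (roi_id,))

    def _invalidate_roi(self, roi_id: int, experiment_id: str) -> None:
        self.conn.execute("DELETE FROM roi_linear WHERE roi_id = ?", (roi_id,))
        self.conn.execute("DELETE FROM roi_stats WHERE roi_id = ?", (roi_id,))
        self.conn.execute(
            "DELETE FROM mm_fit WHERE experiment_id = ?", (experiment_id,)
        )
        self.conn.execute(
            "DELETE FROM rate_summary WHERE experiment_id = ?", (experiment_id,)
        )

    # -- analysis results --------------------------------------------------

    def write_result(self, table: str, key_column: str, key, columns: dict) -> None:
        """Replace-on-rerun upsert into a module-owned result table."""
        self._writable()
        if table not in ("roi_stats", "roi_linear", "mm_fit", "rate_summary"):
            raise ValidationError(f"unknown result table {table!r}")
        cols = [key_column, *columns]
        placeholders = ", ".join("?" for _ in cols)
        with self.conn:
            self.conn.execute(
                f"INSERT OR REPLACE INTO {table} ({', '.join(cols)}) "
                f"VALUES ({placeholders})",
                (key, *columns.values()),
            )

    def table(self, name: str) -> pd.DataFrame:
        """Whole table or view as a DataFrame (read path, always allowed)."""
        return pd.read_sql_query(f"SELECT * FROM {name}", self.conn)

    # -- normalization metadata ---------------------------------------------

    def add_sample_link(
        self,
        experiment_id: str,
        sample_id: str,
        chamber_volume_ml: float,
        sample_volume_ml: float,
    ) -> None:
        self._writable()
        with self.conn:
            self.conn.execute(
                "INSERT OR REPLACE INTO sample_link "
                "(experiment_id, sample_id, chamber_volume_ml, sample_volume_ml) "
                "VALUES (?, ?, ?, ?)",
                (experiment_id, sample_id, chamber_volume_ml, sample_volume_ml),
            )

    def add_protein_measurement(
        self, batch_id: str, value: float, success: bool = True
    ) -> None:
        self._writable()
        with self.conn:
            self.conn.execute(
                "INSERT INTO protein_measurement (batch_id, value, success) "
                "VALUES (?, ?, ?)",
                (batch_id, value, int(success)),
            )

    def link_protein_batches(
        self, sample_id: str, sample_batch: str, buffer_batch: str
    ) -> None:
        self._writable()
        with self.conn:
            self.conn.execute(
                "INSERT OR REPLACE INTO protein_batch_link "
                "(sample_id, sample_batch, buffer_batch) VALUES (?, ?, ?)",
                (sample_id, sample_batch, buffer_batch),
            )

    def mean_protein_content(self, sample_id: str) -> float | None:
        """Cp for a sample from the protein_content view; None when no
        successful reading exists in either batch (absent row, not zero)."""
        row = self.conn.execute(
            "SELECT cp FROM protein_content WHERE sample_id = ?", (sample_id,)
        ).fetchone()
        return None if row is None else float(row[0])

    # -- export --------------------------------------------------------------

    def query_export(
        self, query: str, shape: str = "wide", keys: tuple[str, ...] = ()
    ) -> pd.DataFrame:
        """Run a read-only SQL query and return the table in wide or long form.

        Mutating statements are rejected at the engine level (sqlite
        authorizer), regardless of the store's read-only toggle.
        """
        if shape not in ("wide", "long"):
            raise ValidationError(f"shape must be 'wide' or 'long', got {shape!r}")
        self.conn.set_authorizer(_deny_writes)
        try:
            df = pd.read_sql_query(query, self.conn)
        except (sqlite3.DatabaseError, pd.errors.DatabaseError) as exc:
            if "not authorized" in str(exc):
                raise ReadOnlyError(f"mutating query rejected: {query!r}") from exc
            raise
        finally:
            self.conn.set_authorizer(None)
        return to_long(df, keys) if shape == "long" else df


def to_long(df: pd.DataFrame, keys: tuple[str, ...] = ()) -> pd.DataFrame:
    """Unpivot all non-key columns into (keys..., variable, value) rows.

    Key columns are those named ``*_id`` plus any explicitly listed in
    ``keys``.
    """
    key_cols = [c for c in df.columns if c.endswith("_id") or c in keys]
    value_cols = [c for c in df.columns if c not in key_cols]
    return df.melt(
        id_vars=key_cols, value_vars=value_cols, var_name="variable", value_name="value"
    )


def to_wide(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long (keys..., variable, value) table back to wide form.

    Inverse of :func:`to_long` whenever (keys, variable) pairs are unique.
    """
    key_cols = [c for c in df.columns if c not in ("variable", "value")]
    wide = df.pivot(index=key_cols, columns="variable", values="value").reset_index()
    wide.columns.name = None
    return wide
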