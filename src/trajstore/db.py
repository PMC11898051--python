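"""Self-contained relational store backing the four-tier schema.

The store runs on SQLite (file-based or in-memory), executing the SQLite
dialect of the schema; the PostgreSQL DDL emitted by
:mod:`trajstore.schema` documents the standard's native target.  Array and
composite values (residues, bound partners, coordinate 4-tuples, the
12-element box) are carried as JSON text, which round-trips double
precision exactly.

By default every deposition commits immediately, so each row is validated
and visible as soon as the call returns; a batch mode (commit every N
writes) is available for bulk conversion.
"""

from __future__ import annotations

import json
import re
import sqlite3
from datetime import datetime, timezone
from pathlib import Path

from .schema import SchemaConfig, emit_schema, snapshot_table_ddl

__all__ = ["Store", "connect"]

_IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*\Z")


def _check_ident(name: str) -> str:
    if not _IDENT_RE.match(name):
        raise ValueError(f"invalid SQL identifier {name!r}")
    return name


class Store:
    """A connection to a trajectory database plus commit policy.

    Parameters
    ----------
    path:
        SQLite database file, or ``":memory:"`` for an ephemeral store.
    batch_size:
        Commit after every *batch_size* row writes.  1 (the default) gives
        the per-row commit safety the standard recommends.
    """

    def __init__(self, path: str | Path = ":memory:", batch_size: int = 1):
        if batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        self.path = str(path)
        self.batch_size = batch_size
        self._pending = 0
        self.conn = sqlite3.connect(self.path)
        self.conn.execute("PRAGMA foreign_keys = ON")

    # -- lifecycle ---------------------------------------------------------

    def init_schema(self) -> None:
        """Create the fixed tables if absent (idempotent)."""
        for stmt in emit_schema(SchemaConfig(dialect="sqlite")):
            self.conn.execute(stmt)
        self.conn.commit()

    def close(self) -> None:
        self.flush()
        self.conn.close()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- commit policy -----------------------------------------------------

    def note_write(self) -> None:
        self._pending += 1
        if self._pending >= self.batch_size:
            self.flush()

    def flush(self) -> None:
        self.conn.commit()
        self._pending = 0

    # -- helpers -----------------------------------------------------------

    def execute(self, sql: str, params=()) -> sqlite3.Cursor:
        return self.conn.execute(sql, params)

    def fetchone(self, sql: str, params=()):
        return self.conn.execute(sql, params).fetchone()

    def fetchall(self, sql: str, params=()):
        return self.conn.execute(sql, params).fetchall()

    def table_exists(self, name: str) -> bool:
        row = self.fetchone(
            "SELECT 1 FROM sqlite_master WHERE type='table' AND name=?", (name,)
        )
        return row is not None

    def columns_of(self, table: str) -> list[str]:
        """Introspected column names of *table*, in declaration order."""
        return [r[1] for r in self.fetchall(f"PRAGMA table_info({_check_ident(table)})")]

    def snapshot_tables(self) -> list[str]:
        rows = self.fetchall(
            "SELECT name FROM sqlite_master WHERE type='table' "
            "AND name LIKE 'snapshots\\_%' ESCAPE '\\'"
        )
        return [r[0] for r in rows]

    def create_snapshot_table(self, name: str) -> None:
        self.conn.execute(snapshot_table_ddl(_check_ident(name),
                                             SchemaConfig(dialect="sqlite")))
        self.flush()

    def next_id(self, table: str, column: str) -> int:
        row = self.fetchone(
            f"SELECT COALESCE(MAX({_check_ident(column)}), 0) "
            f"FROM {_check_ident(table)}"
        )
        return int(row[0]) + 1

    @staticmethod
    def now() -> str:
        return datetime.now(timezone.utc).strftime("%Y-%m-%d %H:%M:%S.%f")

    # -- JSON-carried arrays ----------------------------------------------

    @staticmethod
    def pack_json(value) -> str:
        return json.dumps(value, separators=(",", ":"))

    @staticmethod
    def unpack_json(text: str):
        return json.loads(text)


def connect(path: str | Path = ":memory:", batch_size: int = 1,
            init: bool = True) -> Store:
    """Open a store and (by default) ensure the schema exists."""
    store = Store(path, batch_size=batch_size)
    if init:
        store.init_schema()
    return store
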