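"""Four-tier relational schema definition and DDL emission.

The standard is defined against PostgreSQL (arrays, a composite coordinate
element type, TIMESTAMP).  :func:`emit_schema` produces the PostgreSQL DDL
verbatim, and an equivalent SQLite dialect with identical column names and
ordering; the SQLite dialect backs the bundled self-contained store, where
array-valued columns are carried as JSON text.

Only the three fixed tables (ensembles, simulations, atoms) and the
composite coordinate element type are created up front; snapshot tables are
created later, one per registered simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SchemaConfig", "emit_schema", "ENSEMBLES_COLUMNS",
           "SIMULATIONS_COLUMNS", "ATOMS_COLUMNS", "SNAPSHOT_COLUMNS"]

# (column name, PostgreSQL type, SQLite type) in table order
ENSEMBLES_COLUMNS = [
    ("ens_id", "INTEGER PRIMARY KEY", "INTEGER PRIMARY KEY"),
    ("ens_key", "TEXT UNIQUE NOT NULL", "TEXT UNIQUE NOT NULL"),
    ("nratoms", "INTEGER", "INTEGER"),
    ("residues", "TEXT[]", "TEXT"),          # SQLite: JSON array of tokens
    ("timestamp", "TIMESTAMP", "TEXT"),
]

SIMULATIONS_COLUMNS = [
    ("ens_id", "INTEGER REFERENCES {schema}ensembles(ens_id)",
     "INTEGER REFERENCES ensembles(ens_id)"),
    ("sim_id", "INTEGER PRIMARY KEY", "INTEGER PRIMARY KEY"),
    ("sim_rank", "INTEGER", "INTEGER"),
    ("sim_parent", "INTEGER", "INTEGER"),
    ("sim_summary", "TEXT", "TEXT"),
    ("sim_software", "TEXT", "TEXT"),
    ("nratoms", "INTEGER", "INTEGER"),
    ("equilibration_steps", "INTEGER", "INTEGER"),
    ("snap_interval", "INTEGER", "INTEGER"),
    ("box_shape", "INTEGER", "INTEGER"),
    ("box_periodicity", "INTEGER", "INTEGER"),
    ("ensemble_type", "INTEGER", "INTEGER"),
    ("sampler_type", "INTEGER", "INTEGER"),
    ("parallel_mode", "INTEGER", "INTEGER"),
    ("united_atom_model", "INTEGER", "INTEGER"),
    ("deposit_mode", "INTEGER", "INTEGER"),
]

ATOMS_COLUMNS = [
    ("ens_id", "INTEGER REFERENCES {schema}ensembles(ens_id)",
     "INTEGER REFERENCES ensembles(ens_id)"),
    ("atom_id", "BIGINT PRIMARY KEY", "INTEGER PRIMARY KEY"),
    ("atom_seq", "INTEGER", "INTEGER"),
    ("sys_seq", "INTEGER", "INTEGER"),
    ("atom_name", "CHAR(5)", "TEXT"),
    ("resid_seq", "INTEGER", "INTEGER"),
    ("resid_name", "CHAR(4)", "TEXT"),
    ("chain_seq", "CHAR(2)", "TEXT"),
    ("keyword", "CHAR(6)", "TEXT"),
    ("occupancy", "DOUBLE PRECISION", "REAL"),
    ("tempfactor", "DOUBLE PRECISION", "REAL"),
    ("biotype", "INTEGER", "INTEGER"),
    ("molecule_id", "INTEGER", "INTEGER"),
    ("mass", "DOUBLE PRECISION", "REAL"),
    ("partial_charge", "DOUBLE PRECISION", "REAL"),
    ("formal_charge", "SMALLINT", "INTEGER"),
    ("charge_group_id", "INTEGER", "INTEGER"),
    ("rfos_contribution", "DOUBLE PRECISION", "REAL"),
    ("solvation_group_id", "INTEGER", "INTEGER"),
    ("bound_partners", "INTEGER[5]", "TEXT"),         # JSON [5 ints]
    ("zmatrix_references", "INTEGER[4]", "TEXT"),     # JSON [4 ints]
    ("zmatrix_values", "DOUBLE PRECISION[3]", "TEXT"),  # JSON [3 reals]
]

SNAPSHOT_COLUMNS = [
    ("ens_id", "BIGINT", "INTEGER"),
    ("snap_id", "BIGINT PRIMARY KEY", "INTEGER PRIMARY KEY"),
    ("sim_step", "BIGINT", "INTEGER"),
    ("previous_id", "BIGINT", "INTEGER"),
    ("previous_rank", "INTEGER", "INTEGER"),
    ("previous_snap", "BIGINT", "INTEGER"),
    ("sampler_id", "SMALLINT", "INTEGER"),
    ("trajectories", "{schema}atomxyz[]", "TEXT"),  # JSON [[atom_seq,x,y,z],...]
    ("box", "DOUBLE PRECISION[12]", "TEXT"),        # JSON [12 reals]
]

_SQL_IDENT = r"[A-Za-z_][A-Za-z0-9_]*"


@dataclass
class SchemaConfig:
    """Options for DDL emission.

    ``schema`` is the target namespace (PostgreSQL schema); empty means the
    default namespace.  ``dialect`` is ``"postgresql"`` or ``"sqlite"``.
    """

    schema: str = ""
    dialect: str = "postgresql"

    def __post_init__(self) -> None:
        import re

        if self.schema and not re.match(_SQL_IDENT + r"\Z", self.schema):
            raise ValueError(f"invalid schema identifier {self.schema!r}")
        if self.dialect not in ("postgresql", "sqlite"):
            raise ValueError(f"unknown dialect {self.dialect!r}")

    @property
    def prefix(self) -> str:
        return f"{self.schema}." if self.schema else ""


def _table_ddl(name: str, columns: list[tuple[str, str, str]],
               config: SchemaConfig) -> str:
    idx = 1 if config.dialect == "postgresql" else 2
    cols = ",\n  ".join(
        f"{c[0]} {c[idx].format(schema=config.prefix)}" for c in columns
    )
    return f"CREATE TABLE IF NOT EXISTS {config.prefix}{name} (\n  {cols}\n)"


def composite_type_ddl(config: SchemaConfig) -> str:
    """DDL for the coordinate element type ``atomxyz``.

    PostgreSQL's CREATE TYPE has no IF NOT EXISTS, so the statement is
    wrapped to swallow the duplicate-object error, keeping the emitted
    script idempotent.
    """
    if config.dialect == "sqlite":
        # SQLite has no composite types; coordinate 4-tuples travel as JSON.
        return ""
    return (
        "DO $$ BEGIN\n"
        f"  CREATE TYPE {config.prefix}atomxyz AS (\n"
        "    atom_seq INTEGER, x DOUBLE PRECISION,\n"
        "    y DOUBLE PRECISION, z DOUBLE PRECISION\n"
        "  );\n"
        "EXCEPTION WHEN duplicate_object THEN NULL;\n"
        "END $$"
    )


def emit_schema(config: SchemaConfig | None = None) -> list[str]:
    """Emit the data-definition statements for the three fixed tables plus
    the composite coordinate element type.

    Statements are create-if-absent, so applying them twice is a no-op.
    Snapshot tables are not included: one is created per registered
    simulation (see :func:`snapshot_table_ddl`).
    """
    config = config or SchemaConfig()
    stmts = []
    if config.schema and config.dialect == "postgresql":
        stmts.append(f"CREATE SCHEMA IF NOT EXISTS {config.schema}")
    ct = composite_type_ddl(config)
    if ct:
        stmts.append(ct)
    stmts.append(_table_ddl("ensembles", ENSEMBLES_COLUMNS, config))
    stmts.append(_table_ddl("simulations", SIMULATIONS_COLUMNS, config))
    stmts.append(_table_ddl("atoms", ATOMS_COLUMNS, config))
    return stmts


def snapshot_table_ddl(table_name: str, config: SchemaConfig | None = None) -> str:
    """DDL for one coordinate-tier table (one per (sim_id, sim_rank))."""
    config = config or SchemaConfig()
    return _table_ddl(table_name, SNAPSHOT_COLUMNS, config)
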