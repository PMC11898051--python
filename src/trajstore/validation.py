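"""Database-integrity validation.

The schema carries deliberate redundancy (nratoms in two tiers, the
residues array, systematic table names) so that corruption is detectable.
:func:`validate_database` checks every invariant of the standard,
read-only, and reports each violation with its tier and row identity.
An empty report means the database is healthy.

Checked invariants (one violation kind each):

1.  ``ens_nratoms``      — atoms-row count equals ensembles.nratoms
2.  ``sim_nratoms``      — simulations.nratoms equals the ensemble's
3.  ``atom_seq_range``   — atom_seq values form the contiguous 1..nratoms
4.  ``missing_table``    — a snapshot table exists per (sim_id, sim_rank)
5.  ``coord_index``      — trajectories atom indices within 1..nratoms
6.  ``coord_order``      — trajectories atom indices strictly increasing
7.  ``box_length``       — box arrays have exactly 12 elements
8.  ``dangling_parent``  — backward triples resolve to an existing row
9.  ``lineage_cycle``    — backward map is acyclic
10. ``box_consistency``  — (box_shape, box_periodicity) pair admissible
11. ``code_book``        — every integer code is within its code book
12. ``ens_key_format``   — ensemble keys contain no special characters
"""

from __future__ import annotations

from dataclasses import dataclass

from . import codebooks
from .db import Store

__all__ = ["Violation", "validate_database", "VIOLATION_KINDS"]

VIOLATION_KINDS = (
    "ens_nratoms", "sim_nratoms", "atom_seq_range", "missing_table",
    "coord_index", "coord_order", "box_length", "dangling_parent",
    "lineage_cycle", "box_consistency", "code_book", "ens_key_format",
)

_CODE_FIELDS = (
    "box_shape", "box_periodicity", "ensemble_type", "sampler_type",
    "parallel_mode", "united_atom_model", "deposit_mode",
)


@dataclass(frozen=True)
class Violation:
    kind: str
    tier: str
    identity: str
    message: str

    def __str__(self) -> str:
        return f"[{self.kind}] {self.tier} {self.identity}: {self.message}"


def validate_database(store: Store) -> list[Violation]:
    """Run every integrity check; returns the (possibly empty) report."""
    report: list[Violation] = []
    report += _check_ensembles(store)
    report += _check_simulations(store)
    report += _check_snapshot_tables(store)
    return report


def _check_ensembles(store: Store) -> list[Violation]:
    out = []
    for ens_id, ens_key, nratoms in store.fetchall(
            "SELECT ens_id, ens_key, nratoms FROM ensembles"):
        ident = f"ens_id={ens_id} ({ens_key!r})"
        try:
            codebooks.validate_ens_key(ens_key or "")
        except codebooks.KeyValidationError as exc:
            out.append(Violation("ens_key_format", "ensembles", ident, str(exc)))
        count = store.fetchone(
            "SELECT COUNT(*) FROM atoms WHERE ens_id=?", (ens_id,))[0]
        if count != nratoms:
            out.append(Violation(
                "ens_nratoms", "ensembles", ident,
                f"atoms tier holds {count} rows but nratoms={nratoms}"))
        seqs = [r[0] for r in store.fetchall(
            "SELECT atom_seq FROM atoms WHERE ens_id=? ORDER BY atom_seq",
            (ens_id,))]
        if seqs != list(range(1, len(seqs) + 1)):
            out.append(Violation(
                "atom_seq_range", "atoms", ident,
                f"atom_seq values are not the contiguous range 1..{len(seqs)}"))
    return out


def _check_simulations(store: Store) -> list[Violation]:
    out = []
    rows = store.fetchall(
        "SELECT s.sim_id, s.sim_rank, s.nratoms, e.nratoms, s.box_shape,"
        " s.box_periodicity, s.ensemble_type, s.sampler_type,"
        " s.parallel_mode, s.united_atom_model, s.deposit_mode"
        " FROM simulations s LEFT JOIN ensembles e ON s.ens_id = e.ens_id")
    for row in rows:
        sim_id, sim_rank = int(row[0]), int(row[1])
        ident = f"sim_id={sim_id} sim_rank={sim_rank}"
        if row[3] is not None and row[2] != row[3]:
            out.append(Violation(
                "sim_nratoms", "simulations", ident,
                f"nratoms={row[2]} does not match the ensemble's {row[3]}"))
        codes = dict(zip(_CODE_FIELDS, row[4:11]))
        for field, code in codes.items():
            if not codebooks.is_valid_code(field, code):
                out.append(Violation(
                    "code_book", "simulations", ident,
                    f"{field}={code} is outside the code book"))
        if (codebooks.is_valid_code("box_shape", codes["box_shape"])
                and codebooks.is_valid_code("box_periodicity",
                                            codes["box_periodicity"])
                and not codebooks.periodicity_admissible(
                    codes["box_shape"], codes["box_periodicity"])):
            out.append(Violation(
                "box_consistency", "simulations", ident,
                f"box_shape={codes['box_shape']} forbids "
                f"box_periodicity={codes['box_periodicity']}"))
        if not store.table_exists(
                codebooks.snapshot_table_name(sim_id, sim_rank)):
            out.append(Violation(
                "missing_table", "coordinates", ident,
                "snapshot table is missing"))
    return out


def _check_snapshot_tables(store: Store) -> list[Violation]:
    out = []
    nratoms_by_sim = {
        (int(r[0]), int(r[1])): int(r[2]) for r in store.fetchall(
            "SELECT sim_id, sim_rank, nratoms FROM simulations")
    }
    existing: dict[str, set[int]] = {}
    parents: dict[tuple[int, int, int], tuple[int, int, int]] = {}
    for table in store.snapshot_tables():
        sim_id, sim_rank = codebooks.parse_snapshot_table_name(table)
        nratoms = nratoms_by_sim.get((sim_id, sim_rank))
        rows = store.fetchall(
            f"SELECT snap_id, previous_id, previous_rank, previous_snap,"
            f" trajectories, box FROM {table}")
        existing[table] = {int(r[0]) for r in rows}
        for snap_id, pid, prank, psnap, traj_json, box_json in rows:
            ident = f"{table} snap_id={snap_id}"
            parents[(sim_id, sim_rank, int(snap_id))] = (
                int(pid), int(prank), int(psnap))
            box = store.unpack_json(box_json)
            if len(box) != 12:
                out.append(Violation(
                    "box_length", "coordinates", ident,
                    f"box has {len(box)} elements instead of 12"))
            prev = 0
            for t in store.unpack_json(traj_json):
                seq = int(t[0])
                if seq <= prev:
                    out.append(Violation(
                        "coord_order", "coordinates", ident,
                        f"atom index {seq} after {prev} is not strictly "
                        f"increasing"))
                    break
                prev = seq
                if nratoms is not None and (seq < 1 or seq > nratoms):
                    out.append(Violation(
                        "coord_index", "coordinates", ident,
                        f"atom index {seq} outside 1..{nratoms}"))
                    break
    # backward map: dangling references and cycles
    for (sim_id, sim_rank, snap_id), triple in parents.items():
        ident = (f"{codebooks.snapshot_table_name(sim_id, sim_rank)} "
                 f"snap_id={snap_id}")
        if triple == (0, 0, 0):
            continue
        ptable = (codebooks.snapshot_table_name(triple[0], triple[1])
                  if triple[0] >= 1 and triple[1] >= 0 else None)
        if (ptable is None or ptable not in existing
                or triple[2] not in existing[ptable]):
            out.append(Violation(
                "dangling_parent", "coordinates", ident,
                f"backward triple {triple} names a nonexistent snapshot"))
    for start in parents:
        seen = {start}
        current = start
        while True:
            triple = parents.get(current)
            if triple is None or triple == (0, 0, 0):
                break
            if triple not in parents:
                break  # dangling, reported above
            if triple in seen:
                out.append(Violation(
                    "lineage_cycle", "coordinates",
                    f"{codebooks.snapshot_table_name(start[0], start[1])} "
                    f"snap_id={start[2]}",
                    f"backward map revisits {triple}"))
                break
            seen.add(triple)
            current = triple
    return out
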