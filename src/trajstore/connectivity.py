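"""Backward-connectivity traversal: lineages and trajectory-ensemble
demultiplexing.

Every snapshot stores the address of its geometric parent as the triple
(previous_id, previous_rank, previous_snap) — a backward map, because the
forward direction can be one-to-many (reseeding) but never many-to-one.
Tracing this map reconstructs where, in a trajectory ensemble, exchanges
or replacements took place, and turns a replica-exchange data set from
swaps of conditions into geometrically continuous trajectories (swaps of
conformations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import codebooks
from .db import Store
from .errors import IntegrityError, NotFoundError
from .records import NIL_REF, LineageRef

__all__ = ["parent_of", "trace_lineage", "demultiplex", "DemuxResult"]


def _fetch_parent_rows(store: Store, table: str, snap_ids: list[int]
                       ) -> dict[int, tuple[int, int, int]]:
    """Batched parent lookup: triples for many snap_ids in one query."""
    if not snap_ids:
        return {}
    qs = ",".join("?" * len(snap_ids))
    rows = store.fetchall(
        f"SELECT snap_id, previous_id, previous_rank, previous_snap "
        f"FROM {table} WHERE snap_id IN ({qs})", snap_ids,
    )
    return {int(r[0]): (int(r[1]), int(r[2]), int(r[3])) for r in rows}


def _resolve(store: Store, ref: LineageRef) -> tuple[int, int, int]:
    table = codebooks.snapshot_table_name(ref.sim_id, ref.sim_rank)
    if not store.table_exists(table):
        raise NotFoundError(f"snapshot table {table} does not exist")
    row = _fetch_parent_rows(store, table, [ref.snap_id]).get(ref.snap_id)
    if row is None:
        raise NotFoundError(f"snapshot {ref} does not exist")
    return row


def parent_of(store: Store, ref: LineageRef) -> LineageRef | None:
    """The geometric parent of *ref*, or None at the start of a lineage."""
    triple = _resolve(store, ref)
    parent = LineageRef(*triple)
    if parent.is_nil():
        return None
    try:
        _resolve(store, parent)
    except NotFoundError as exc:
        raise IntegrityError(
            f"snapshot {ref} has dangling parent reference {parent}"
        ) from exc
    return parent


def trace_lineage(store: Store, ref: LineageRef,
                  max_depth: int | None = None) -> list[LineageRef]:
    """Ancestors of *ref* from the origin (oldest first) to *ref* inclusive.

    Follows the backward map until the nil sentinel, or until *max_depth*
    ancestors have been collected (the result then holds the last
    *max_depth* ancestors plus *ref*).  A revisited address means the map
    is corrupt (cycles are impossible by construction).
    """
    chain = [ref]
    seen = {ref}
    current = ref
    while max_depth is None or len(chain) - 1 < max_depth:
        parent = parent_of(store, current)
        if parent is None:
            break
        if parent in seen:
            raise IntegrityError(
                f"cycle detected in backward-connectivity map at {parent}"
            )
        chain.append(parent)
        seen.add(parent)
        current = parent
    chain.reverse()
    return chain


@dataclass
class DemuxResult:
    """Continuous trajectories recovered from a trajectory ensemble.

    ``trajectories`` maps each terminal frame to its full lineage (oldest
    first).  ``branch_points`` lists addresses shared by more than one
    lineage (adaptive-sampling reseeds; frames are stored once).
    ``orphans`` lists non-initial frames with a nil parent (e.g. library
    insertions whose parentage the standard does not record).
    """

    trajectories: dict[LineageRef, list[LineageRef]]
    branch_points: list[LineageRef] = field(default_factory=list)
    orphans: list[LineageRef] = field(default_factory=list)


def demultiplex(store: Store, parent_sim_id: int) -> DemuxResult:
    """Rebuild geometrically continuous trajectories for a parallel run.

    For every member (sim_id, sim_rank) of the run whose parent is
    *parent_sim_id*, the terminal frame's lineage is traced through the
    backward map.  The result is one continuous trajectory per terminal
    frame.  Backward functionality is verified: within the ensemble each
    address may have at most one child per lineage step, i.e. the forward
    map may branch (one-to-many) but lineages never merge many-to-one at
    the same step.
    """
    members = store.fetchall(
        "SELECT sim_id, sim_rank, parallel_mode FROM simulations "
        "WHERE sim_parent=? ORDER BY sim_rank", (parent_sim_id,),
    )
    if not members:
        raise NotFoundError(f"no simulation with parent sim_id {parent_sim_id}")

    trajectories: dict[LineageRef, list[LineageRef]] = {}
    for sim_id, sim_rank, _mode in members:
        table = codebooks.snapshot_table_name(sim_id, sim_rank)
        if not store.table_exists(table):
            raise IntegrityError(f"missing snapshot table {table}")
        row = store.fetchone(f"SELECT MAX(snap_id) FROM {table}")
        if row is None or row[0] is None:
            continue
        terminal = LineageRef(int(sim_id), int(sim_rank), int(row[0]))
        # trace_lineage enforces backward functionality: exactly one stored
        # parent per snapshot, no cycles, no dangling references
        lineage = trace_lineage(store, terminal)
        trajectories[terminal] = lineage

    shared: dict[LineageRef, int] = {}
    for lineage in trajectories.values():
        for ref in lineage:
            shared[ref] = shared.get(ref, 0) + 1
    branch_points = sorted(
        (r for r, n in shared.items() if n > 1 and _is_branch(trajectories, r)),
        key=lambda r: (r.sim_id, r.sim_rank, r.snap_id),
    )

    orphans = []
    for lineage in trajectories.values():
        origin = lineage[0]
        if origin.snap_id > 1:
            orphans.append(origin)

    return DemuxResult(trajectories=trajectories,
                       branch_points=branch_points,
                       orphans=sorted(set(orphans),
                                      key=lambda r: (r.sim_id, r.sim_rank,
                                                     r.snap_id)))


def _is_branch(trajectories: dict[LineageRef, list[LineageRef]],
               ref: LineageRef) -> bool:
    """Shared frame whose successors differ across lineages (a reseed point)."""
    successors = set()
    for lineage in trajectories.values():
        try:
            i = lineage.index(ref)
        except ValueError:
            continue
        if i + 1 < len(lineage):
            successors.add(lineage[i + 1])
    return len(successors) > 1
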