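"""Data entry: ensemble creation/reuse, simulation registration, snapshot
deposition.

The entry flow protects database integrity while cross-linking tiers:

1. An ensemble key either creates a new system, silently reuses an
   identical preexisting one, or is refused if the stored system differs
   and snapshots have already been deposited.  A system with no deposited
   snapshots may be overwritten.
2. Simulation registration creates one simulation-tier row per trajectory
   of a (possibly parallel) run plus one empty snapshot table per
   (sim_id, sim_rank).  Appending to an existing run requires field-wise
   identical metadata.
3. Snapshot deposition validates atom indices and the box, assigns
   sequential snap_ids, records the backward-connectivity triple, and (by
   default) commits per row so every deposited row is immediately visible.

Systems of fluctuating composition (grand-type ensembles) are stored as a
fixed superset; absent particles are flagged by a documented coordinate
shift (:func:`mark_ghosts`).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from . import codebooks
from .boxes import BoxDescriptor, box_extent, encode_box
from .db import Store
from .errors import IntegrityError, NotFoundError, ValidationError
from .records import NIL_REF, AtomRecord, LineageRef, SimulationRecord

__all__ = [
    "open_or_create_ensemble", "register_simulation", "deposit_snapshot",
    "pack_coordinates", "unpack_coordinates", "mark_ghosts", "unmark_ghosts",
    "is_ghost", "GHOST_SHIFT_FACTOR",
]

#: ghost particles are translated by GHOST_SHIFT_FACTOR * (largest box
#: extent) along every axis; see :func:`mark_ghosts`
GHOST_SHIFT_FACTOR = 2.0

_SIM_META_FIELDS = (
    "sim_summary", "sim_software", "nratoms", "equilibration_steps",
    "snap_interval", "box_shape", "box_periodicity", "ensemble_type",
    "sampler_type", "parallel_mode", "united_atom_model", "deposit_mode",
)
_CODE_FIELDS = (
    "box_shape", "box_periodicity", "ensemble_type", "sampler_type",
    "parallel_mode", "united_atom_model", "deposit_mode",
)


# ---------------------------------------------------------------------------
# coordinate packing
# ---------------------------------------------------------------------------

def pack_coordinates(atom_seqs: Sequence[int],
                     coords: Sequence[Sequence[float]],
                     precision: int | None = None,
                     ) -> list[tuple[int, float, float, float]]:
    """Pack parallel index/coordinate lists into (atom_seq, x, y, z) 4-tuples.

    ``atom_seqs`` must be strictly increasing and 1-based, aligned with the
    atoms tier, which allows depositing subset systems.  Coordinates are
    kept in full double precision unless ``precision`` (decimal places) is
    given, which reduces precision already at packing time.
    """
    if len(atom_seqs) != len(coords):
        raise ValidationError(
            f"{len(atom_seqs)} atom indices but {len(coords)} coordinates"
        )
    prev = 0
    out = []
    for seq, xyz in zip(atom_seqs, coords):
        seq = int(seq)
        if seq <= prev:
            raise ValidationError(
                f"atom_seq values must be strictly increasing and >= 1 "
                f"(got {seq} after {prev})"
            )
        prev = seq
        x, y, z = (float(v) for v in xyz)
        if precision is not None:
            x, y, z = round(x, precision), round(y, precision), round(z, precision)
        out.append((seq, x, y, z))
    return out


def unpack_coordinates(packed: Iterable[Sequence[float]]
                       ) -> tuple[list[int], np.ndarray]:
    """Exact inverse of :func:`pack_coordinates`."""
    seqs, xyz = [], []
    for row in packed:
        seqs.append(int(row[0]))
        xyz.append((float(row[1]), float(row[2]), float(row[3])))
    return seqs, np.asarray(xyz, dtype=float).reshape(len(seqs), 3)


# ---------------------------------------------------------------------------
# ghost particles
# ---------------------------------------------------------------------------

def _ghost_shift(box: BoxDescriptor) -> float:
    return GHOST_SHIFT_FACTOR * box_extent(box)


def mark_ghosts(coords: Sequence[Sequence[float]], present: Sequence[bool],
                box: BoxDescriptor) -> np.ndarray:
    """Encode particle absence by a coordinate shift.

    Absent particles are translated by ``2 * (largest box extent)`` along
    every axis, far outside any physically valid position, so presence can
    be recovered exactly (:func:`is_ghost`).  Present coordinates are
    assumed to lie inside the container.
    """
    coords = np.asarray(coords, dtype=float).copy()
    present = np.asarray(present, dtype=bool)
    if len(coords) != len(present):
        raise ValidationError("coords and present flags differ in length")
    coords[~present] += _ghost_shift(box)
    return coords


def is_ghost(coord: Sequence[float], box: BoxDescriptor) -> bool:
    """Whether a stored coordinate encodes an absent (ghost) particle."""
    rel = np.asarray(coord, dtype=float) - box.origin
    # present particles lie within one extent of the origin on every axis;
    # ghosts sit at >= 1.5 extents (shifted by 2, container half-width <= 0.5)
    return bool(np.all(rel > 1.25 * box_extent(box)))


def unmark_ghosts(coords: Sequence[Sequence[float]], box: BoxDescriptor
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Invert :func:`mark_ghosts`: restored coordinates plus presence flags."""
    coords = np.asarray(coords, dtype=float).copy()
    present = np.array([not is_ghost(c, box) for c in coords], dtype=bool)
    coords[~present] -= _ghost_shift(box)
    return coords, present


# ---------------------------------------------------------------------------
# ensemble tier
# ---------------------------------------------------------------------------

def _validate_system(atoms: Sequence[AtomRecord]) -> None:
    n = len(atoms)
    if n == 0:
        raise ValidationError("system must contain at least one atom")
    seqs = [a.atom_seq for a in atoms]
    if sorted(seqs) != list(range(1, n + 1)):
        raise ValidationError(
            f"atom_seq values must form the contiguous range 1..{n}"
        )
    by_seq = {a.atom_seq: a for a in atoms}
    for a in atoms:
        if len(a.bound_partners) != 5:
            raise ValidationError(
                f"atom_seq {a.atom_seq}: bound_partners must have 5 entries"
            )
        for p in a.bound_partners:
            if p == 0:
                continue
            if p < 1 or p > n:
                raise ValidationError(
                    f"atom_seq {a.atom_seq}: bound partner {p} out of range"
                )
            if a.atom_seq not in by_seq[p].bound_partners:
                raise ValidationError(
                    f"covalent bonding not symmetric between atoms "
                    f"{a.atom_seq} and {p}"
                )
        if len(a.zmatrix_references) != 4 or len(a.zmatrix_values) != 3:
            raise ValidationError(
                f"atom_seq {a.atom_seq}: Z-matrix fields must have 4 "
                f"references and 3 values"
            )
        if a.occupancy != 1.0:
            raise ValidationError(
                f"atom_seq {a.atom_seq}: occupancy must be 1.0"
            )


def _stored_atoms(store: Store, ens_id: int) -> list[AtomRecord]:
    from .retrieval import fetch_atoms   # local import to avoid a cycle

    return fetch_atoms(store, ens_id)


def _ensemble_has_snapshots(store: Store, ens_id: int) -> bool:
    rows = store.fetchall(
        "SELECT sim_id, sim_rank FROM simulations WHERE ens_id=?", (ens_id,)
    )
    for sim_id, sim_rank in rows:
        tbl = codebooks.snapshot_table_name(sim_id, sim_rank)
        if store.table_exists(tbl):
            if store.fetchone(f"SELECT 1 FROM {tbl} LIMIT 1") is not None:
                return True
    return False


def _insert_atoms(store: Store, ens_id: int, atoms: Sequence[AtomRecord]) -> None:
    next_atom_id = store.next_id("atoms", "atom_id")
    for i, a in enumerate(sorted(atoms, key=lambda a: a.atom_seq)):
        store.execute(
            "INSERT INTO atoms (ens_id, atom_id, atom_seq, sys_seq, atom_name,"
            " resid_seq, resid_name, chain_seq, keyword, occupancy, tempfactor,"
            " biotype, molecule_id, mass, partial_charge, formal_charge,"
            " charge_group_id, rfos_contribution, solvation_group_id,"
            " bound_partners, zmatrix_references, zmatrix_values)"
            " VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
            (ens_id, next_atom_id + i, a.atom_seq, a.sys_seq, a.atom_name,
             a.resid_seq, a.resid_name, a.chain_seq, a.keyword, a.occupancy,
             a.tempfactor, a.biotype, a.molecule_id, a.mass, a.partial_charge,
             a.formal_charge, a.charge_group_id, a.rfos_contribution,
             a.solvation_group_id,
             store.pack_json(list(a.bound_partners)),
             store.pack_json(list(a.zmatrix_references)),
             store.pack_json(list(a.zmatrix_values))),
        )
        store.note_write()


def open_or_create_ensemble(store: Store, key: str,
                            atoms: Sequence[AtomRecord],
                            residues: Sequence[str]) -> int:
    """Create an ensemble, or reuse/overwrite an existing one consistently.

    Returns the numeric ens_id.  A preexisting key is reused silently when
    the stored system is field-wise identical to the deposited one; a key
    whose system has no deposited snapshots is overwritten; anything else
    is refused without writing.
    """
    codebooks.validate_ens_key(key)
    _validate_system(atoms)
    residues = [str(r) for r in residues]

    row = store.fetchone(
        "SELECT ens_id, nratoms, residues FROM ensembles WHERE ens_key=?",
        (key,),
    )
    if row is not None:
        ens_id, nratoms, res_json = int(row[0]), int(row[1]), row[2]
        stored = _stored_atoms(store, ens_id)
        same = (
            nratoms == len(atoms)
            and store.unpack_json(res_json) == residues
            and [a.identity() for a in stored]
            == [a.identity() for a in sorted(atoms, key=lambda a: a.atom_seq)]
        )
        if same:
            return ens_id
        if _ensemble_has_snapshots(store, ens_id):
            raise IntegrityError(
                f"ensemble key {key!r} already holds a different system with "
                f"deposited snapshots; refusing to overwrite"
            )
        # empty system: overwrite in place under the same ens_id
        store.execute("DELETE FROM atoms WHERE ens_id=?", (ens_id,))
        _insert_atoms(store, ens_id, atoms)
        store.execute(
            "UPDATE ensembles SET nratoms=?, residues=?, timestamp=? "
            "WHERE ens_id=?",
            (len(atoms), store.pack_json(residues), store.now(), ens_id),
        )
        store.execute(
            "UPDATE simulations SET nratoms=? WHERE ens_id=?",
            (len(atoms), ens_id),
        )
        store.flush()
        return ens_id

    ens_id = store.next_id("ensembles", "ens_id")
    store.execute(
        "INSERT INTO ensembles (ens_id, ens_key, nratoms, residues, timestamp)"
        " VALUES (?,?,?,?,?)",
        (ens_id, key, len(atoms), store.pack_json(residues), store.now()),
    )
    store.note_write()
    _insert_atoms(store, ens_id, atoms)
    store.flush()
    return ens_id


# ---------------------------------------------------------------------------
# simulation tier
# ---------------------------------------------------------------------------

def _validate_meta(meta: dict, nratoms_expected: int) -> dict:
    m = dict(meta)
    m.setdefault("sim_summary", "")
    m.setdefault("sim_software", "unspecified")
    m.setdefault("nratoms", nratoms_expected)
    m.setdefault("equilibration_steps", 0)
    unknown = set(m) - set(_SIM_META_FIELDS)
    if unknown:
        raise ValidationError(f"unknown simulation metadata fields {sorted(unknown)}")
    missing = set(_SIM_META_FIELDS) - set(m)
    if missing:
        raise ValidationError(f"missing simulation metadata fields {sorted(missing)}")
    for f in _CODE_FIELDS:
        if isinstance(m[f], str):
            m[f] = codebooks.encode(f, m[f])
        elif not codebooks.is_valid_code(f, m[f]):
            raise ValidationError(
                f"{f} code {m[f]!r} is outside the standard's code book"
            )
    if not codebooks.periodicity_admissible(m["box_shape"], m["box_periodicity"]):
        raise ValidationError(
            f"box_shape {m['box_shape']} with box_periodicity "
            f"{m['box_periodicity']} is not admissible"
        )
    if int(m["nratoms"]) != nratoms_expected:
        raise ValidationError(
            f"simulation nratoms {m['nratoms']} does not match the "
            f"ensemble's {nratoms_expected}"
        )
    if int(m["equilibration_steps"]) < 0:
        raise ValidationError("equilibration_steps must be >= 0")
    if int(m["snap_interval"]) < 1:
        raise ValidationError("snap_interval must be >= 1")
    return m


def register_simulation(store: Store, ens_id: int, meta: dict,
                        n_replicas: int = 1,
                        sim_id: int | None = None) -> list[tuple[int, int]]:
    """Register a run (or parallel run of *n_replicas* trajectories).

    Each trajectory receives its own simulation-tier row and an empty
    snapshot table.  The first trajectory is the parent (rank 0,
    self-referencing sim_parent); replicas store the parent's sim_id in
    sim_parent and ranks 1..n_replicas-1.

    Passing ``sim_id`` re-opens an existing run for appending: the supplied
    metadata must match the stored rows field-wise, otherwise the append is
    refused (second consistency check of the entry flow).
    """
    if n_replicas < 1:
        raise ValidationError("n_replicas must be >= 1")
    ens = store.fetchone("SELECT nratoms FROM ensembles WHERE ens_id=?", (ens_id,))
    if ens is None:
        raise NotFoundError(f"ensemble {ens_id} does not exist")
    m = _validate_meta(meta, int(ens[0]))

    if sim_id is not None:
        return _append_simulation(store, ens_id, m, n_replicas, sim_id)

    parent_id = store.next_id("simulations", "sim_id")
    pairs = []
    for rank in range(n_replicas):
        sid = parent_id + rank
        store.execute(
            "INSERT INTO simulations (ens_id, sim_id, sim_rank, sim_parent,"
            " sim_summary, sim_software, nratoms, equilibration_steps,"
            " snap_interval, box_shape, box_periodicity, ensemble_type,"
            " sampler_type, parallel_mode, united_atom_model, deposit_mode)"
            " VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
            (ens_id, sid, rank, parent_id,
             m["sim_summary"], m["sim_software"], m["nratoms"],
             m["equilibration_steps"], m["snap_interval"], m["box_shape"],
             m["box_periodicity"], m["ensemble_type"], m["sampler_type"],
             m["parallel_mode"], m["united_atom_model"], m["deposit_mode"]),
        )
        store.note_write()
        store.create_snapshot_table(codebooks.snapshot_table_name(sid, rank))
        pairs.append((sid, rank))
    store.flush()
    return pairs


def _append_simulation(store: Store, ens_id: int, m: dict, n_replicas: int,
                       parent_id: int) -> list[tuple[int, int]]:
    rows = store.fetchall(
        "SELECT sim_id, sim_rank, sim_summary, sim_software, nratoms,"
        " equilibration_steps, snap_interval, box_shape, box_periodicity,"
        " ensemble_type, sampler_type, parallel_mode, united_atom_model,"
        " deposit_mode FROM simulations WHERE ens_id=? AND sim_parent=?"
        " ORDER BY sim_rank",
        (ens_id, parent_id),
    )
    if not rows:
        raise NotFoundError(
            f"no simulation with sim_id {parent_id} under ensemble {ens_id}"
        )
    if len(rows) != n_replicas:
        raise IntegrityError(
            f"existing run has {len(rows)} trajectories, append requested "
            f"{n_replicas}"
        )
    stored_meta = dict(zip(_SIM_META_FIELDS, rows[0][2:]))
    requested = {f: m[f] for f in _SIM_META_FIELDS}
    if stored_meta != requested:
        diffs = {f: (stored_meta[f], requested[f])
                 for f in _SIM_META_FIELDS if stored_meta[f] != requested[f]}
        raise IntegrityError(
            f"metadata mismatch when appending to sim {parent_id}: {diffs}"
        )
    return [(int(r[0]), int(r[1])) for r in rows]


# ---------------------------------------------------------------------------
# coordinate tier
# ---------------------------------------------------------------------------

def deposit_snapshot(store: Store, table: tuple[int, int] | str,
                     trajectories: Sequence[Sequence[float]],
                     box: BoxDescriptor | Sequence[float],
                     sim_step: int | None = None,
                     parent: LineageRef | str | None = "previous",
                     sampler_id: int | None = None) -> int:
    """Append one frame to a snapshot table; returns the assigned snap_id.

    ``trajectories`` is a packed list of (atom_seq, x, y, z) 4-tuples (see
    :func:`pack_coordinates`).  snap_id is the previous maximum plus one,
    starting at 1.  ``sim_step`` defaults to
    ``equilibration_steps + snap_interval * snap_id``.

    ``parent`` sets the backward-connectivity triple: the default
    ``"previous"`` parents the frame to the preceding snapshot of the same
    table (nil sentinel for the first frame); an explicit
    :class:`LineageRef` records cross-table lineage (replica-exchange
    swaps, reseeding); ``None`` forces the nil sentinel.
    """
    if isinstance(table, str):
        sim_id, sim_rank = codebooks.parse_snapshot_table_name(table)
    else:
        sim_id, sim_rank = table
    tbl = codebooks.snapshot_table_name(sim_id, sim_rank)
    if not store.table_exists(tbl):
        raise NotFoundError(f"snapshot table {tbl} does not exist")
    sim = store.fetchone(
        "SELECT ens_id, nratoms, equilibration_steps, snap_interval,"
        " sampler_type FROM simulations WHERE sim_id=? AND sim_rank=?",
        (sim_id, sim_rank),
    )
    if sim is None:
        raise NotFoundError(f"no simulation row for ({sim_id}, {sim_rank})")
    ens_id, nratoms, equil, interval, sampler_type = (int(v) for v in sim)

    packed = []
    prev = 0
    for row in trajectories:
        seq = int(row[0])
        if seq <= prev:
            raise ValidationError(
                f"trajectories atom_seq must be strictly increasing "
                f"(got {seq} after {prev})"
            )
        if seq > nratoms:
            raise ValidationError(
                f"atom_seq {seq} exceeds ensemble size {nratoms}"
            )
        prev = seq
        packed.append((seq, float(row[1]), float(row[2]), float(row[3])))

    box_vec = encode_box(box) if isinstance(box, BoxDescriptor) else \
        [float(v) for v in box]
    if len(box_vec) != 12:
        raise ValidationError(f"box must have 12 elements, got {len(box_vec)}")

    snap_id = store.next_id(tbl, "snap_id")
    if sim_step is None:
        sim_step = equil + interval * snap_id

    if parent == "previous":
        ref = LineageRef(sim_id, sim_rank, snap_id - 1) if snap_id > 1 else NIL_REF
    elif parent is None:
        ref = NIL_REF
    elif isinstance(parent, LineageRef):
        ref = parent
    else:
        raise ValidationError(f"invalid parent specification {parent!r}")
    if not ref.is_nil():
        ptbl = codebooks.snapshot_table_name(ref.sim_id, ref.sim_rank)
        if not store.table_exists(ptbl) or store.fetchone(
            f"SELECT 1 FROM {ptbl} WHERE snap_id=?", (ref.snap_id,)
        ) is None:
            raise IntegrityError(
                f"parent reference {ref} names a nonexistent snapshot"
            )

    store.execute(
        f"INSERT INTO {tbl} (ens_id, snap_id, sim_step, previous_id,"
        f" previous_rank, previous_snap, sampler_id, trajectories, box)"
        f" VALUES (?,?,?,?,?,?,?,?,?)",
        (ens_id, snap_id, int(sim_step), ref.sim_id, ref.sim_rank, ref.snap_id,
         int(sampler_id if sampler_id is not None else sampler_type),
         store.pack_json([list(t) for t in packed]),
         store.pack_json(box_vec)),
    )
    store.note_write()
    return snap_id
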