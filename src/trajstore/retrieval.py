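"""Data retrieval: key listing, summary search, table enumeration,
metadata fetch, and coordinate slicing.

Retrieval follows the access pattern the schema is designed for: the
foremost reference is the ensemble key, which resolves to the snapshot
tables of its simulations (ordered by sim_parent, then sim_rank, so that
clients can request mappable data slices), after which coordinates are
sliced by snapshot id and atom subset.  Snapshot access is key-based and
near-constant time: retrieving snapshot k never scans snapshots < k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import codebooks
from .db import Store
from .errors import NotFoundError, ValidationError
from .records import AtomRecord, EnsembleRecord, SimulationRecord

__all__ = [
    "SelectionSpec", "list_keys", "tables_for_key", "search_summaries",
    "fetch_metadata", "fetch_coordinates", "fetch_atoms", "fetch_ensemble",
    "FrameResult",
]

_CODE_FIELDS = (
    "box_shape", "box_periodicity", "ensemble_type", "sampler_type",
    "parallel_mode", "united_atom_model", "deposit_mode",
)

#: client-side bound on one resolved slice, to keep intermediates small
MAX_SLICE = 1_000_000


@dataclass
class SelectionSpec:
    """A slice of a snapshot table: which frames, which atoms.

    Frames: either ``snap_ids`` (explicit list) or an inclusive 1-based
    ``snap_range`` (start, stop, stride); neither selects all frames.
    Atoms: any combination of a substring ``atom_name_pattern`` (exact
    matching behind ``exact_name``), ``molecule_id``, ``keyword``, and an
    explicit ``atom_seqs`` list; filters are conjunctive; no filter selects
    all atoms.
    """

    snap_ids: list[int] | None = None
    snap_range: tuple[int, int, int] | None = None
    atom_name_pattern: str | None = None
    exact_name: bool = False
    molecule_id: int | None = None
    keyword: str | None = None
    atom_seqs: list[int] | None = None

    def resolve_snapshots(self, max_snap: int) -> list[int]:
        if self.snap_ids is not None and self.snap_range is not None:
            raise ValidationError("give snap_ids or snap_range, not both")
        if self.snap_ids is not None:
            ids = sorted(set(int(i) for i in self.snap_ids))
        elif self.snap_range is not None:
            start, stop, stride = self.snap_range
            if start < 1 or stride < 1:
                raise ValidationError("snap_range start and stride must be >= 1")
            ids = list(range(start, min(stop, max_snap) + 1, stride))
        else:
            ids = list(range(1, max_snap + 1))
        if len(ids) > MAX_SLICE:
            raise ValidationError(
                f"selection resolves to {len(ids)} snapshots "
                f"(bound: {MAX_SLICE}); narrow the slice"
            )
        return ids

    def resolve_atoms(self, store: Store, ens_id: int) -> set[int] | None:
        """Resolved atom_seq set, or None when every atom is selected."""
        if (self.atom_name_pattern is None and self.molecule_id is None
                and self.keyword is None and self.atom_seqs is None):
            return None
        selected = None
        if self.atom_seqs is not None:
            selected = set(int(s) for s in self.atom_seqs)
        rows = store.fetchall(
            "SELECT atom_seq, atom_name, molecule_id, keyword FROM atoms "
            "WHERE ens_id=?", (ens_id,),
        )
        by_filters = set()
        for seq, name, mol, kw in rows:
            name = (name or "").strip()
            if self.atom_name_pattern is not None:
                if self.exact_name:
                    if name != self.atom_name_pattern:
                        continue
                elif self.atom_name_pattern not in name:
                    continue
            if self.molecule_id is not None and mol != self.molecule_id:
                continue
            if self.keyword is not None and (kw or "").strip() != self.keyword:
                continue
            by_filters.add(int(seq))
        return by_filters if selected is None else (selected & by_filters)


@dataclass
class FrameResult:
    """One retrieved frame: coordinate rows plus the container 12-vector."""

    snap_id: int
    sim_step: int
    coordinates: list[tuple[int, float, float, float]]
    box: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------

def list_keys(store: Store) -> list[tuple[str, int, int, str]]:
    """All ensembles as (ens_key, ens_id, nratoms, timestamp), key-sorted."""
    rows = store.fetchall(
        "SELECT ens_key, ens_id, nratoms, timestamp FROM ensembles "
        "ORDER BY ens_key"
    )
    return [(r[0], int(r[1]), int(r[2]), r[3]) for r in rows]


def _ens_id_for_key(store: Store, ens_key: str) -> int:
    row = store.fetchone("SELECT ens_id FROM ensembles WHERE ens_key=?",
                         (ens_key,))
    if row is None:
        raise NotFoundError(f"unknown ensemble key {ens_key!r}")
    return int(row[0])


def fetch_ensemble(store: Store, ens_id: int) -> EnsembleRecord:
    row = store.fetchone(
        "SELECT ens_id, ens_key, nratoms, residues, timestamp "
        "FROM ensembles WHERE ens_id=?", (ens_id,),
    )
    if row is None:
        raise NotFoundError(f"ensemble {ens_id} does not exist")
    return EnsembleRecord(int(row[0]), row[1], int(row[2]),
                          store.unpack_json(row[3]), row[4])


def tables_for_key(store: Store, ens_key: str) -> list[str]:
    """All snapshot-table names for a key, ordered by sim_parent, sim_rank."""
    ens_id = _ens_id_for_key(store, ens_key)
    rows = store.fetchall(
        "SELECT 'snapshots_' || sim_id || '_' || sim_rank FROM simulations "
        "WHERE ens_id=? ORDER BY sim_parent, sim_rank", (ens_id,),
    )
    return [r[0] for r in rows]


def _escape_like(needle: str) -> str:
    return (needle.replace("\\", "\\\\")
                  .replace("%", "\\%")
                  .replace("_", "\\_"))


def search_summaries(store: Store, needle: str,
                     case_insensitive: bool = False
                     ) -> list[tuple[int, int, int]]:
    """Simulations whose sim_summary contains *needle* as a substring.

    Wildcard characters in *needle* are escaped, so the search is a literal
    substring match (case-sensitive unless ``case_insensitive``).
    """
    if not needle:
        raise ValidationError("search needle must be nonempty")
    pattern = f"%{_escape_like(needle)}%"
    if case_insensitive:
        sql = ("SELECT ens_id, sim_id, sim_rank FROM simulations "
               "WHERE LOWER(sim_summary) LIKE LOWER(?) ESCAPE '\\' "
               "ORDER BY sim_id")
    else:
        # SQLite LIKE is case-insensitive for ASCII; use GLOB-free exact scan
        sql = ("SELECT ens_id, sim_id, sim_rank FROM simulations "
               "WHERE instr(sim_summary, ?) > 0 ORDER BY sim_id")
        pattern = needle
    rows = store.fetchall(sql, (pattern,))
    return [(int(r[0]), int(r[1]), int(r[2])) for r in rows]


def fetch_metadata(store: Store, sim_id: int, sim_rank: int
                   ) -> tuple[SimulationRecord, dict[str, str]]:
    """Full simulation record plus decoded labels for every integer code."""
    row = store.fetchone(
        "SELECT ens_id, sim_id, sim_rank, sim_parent, sim_summary,"
        " sim_software, nratoms, equilibration_steps, snap_interval,"
        " box_shape, box_periodicity, ensemble_type, sampler_type,"
        " parallel_mode, united_atom_model, deposit_mode"
        " FROM simulations WHERE sim_id=? AND sim_rank=?",
        (sim_id, sim_rank),
    )
    if row is None:
        raise NotFoundError(f"no simulation row for ({sim_id}, {sim_rank})")
    rec = SimulationRecord(*row)
    labels = {f: codebooks.decode(f, getattr(rec, f)) for f in _CODE_FIELDS}
    return rec, labels


def fetch_atoms(store: Store, ens_id: int) -> list[AtomRecord]:
    """All atoms-tier rows of an ensemble in atom_seq order."""
    rows = store.fetchall(
        "SELECT ens_id, atom_id, atom_seq, sys_seq, atom_name, resid_seq,"
        " resid_name, chain_seq, keyword, occupancy, tempfactor, biotype,"
        " molecule_id, mass, partial_charge, formal_charge, charge_group_id,"
        " rfos_contribution, solvation_group_id, bound_partners,"
        " zmatrix_references, zmatrix_values"
        " FROM atoms WHERE ens_id=? ORDER BY atom_seq", (ens_id,),
    )
    out = []
    for r in rows:
        out.append(AtomRecord(
            *r[:19],
            bound_partners=store.unpack_json(r[19]),
            zmatrix_references=store.unpack_json(r[20]),
            zmatrix_values=store.unpack_json(r[21]),
        ))
    return out


def fetch_coordinates(store: Store, table: tuple[int, int] | str,
                      selection: SelectionSpec | None = None
                      ) -> list[FrameResult]:
    """Sliced coordinates: selected frames in ascending snap_id order, each
    with its filtered coordinate rows (ascending atom_seq) and box."""
    if isinstance(table, str):
        sim_id, sim_rank = codebooks.parse_snapshot_table_name(table)
    else:
        sim_id, sim_rank = table
    tbl = codebooks.snapshot_table_name(sim_id, sim_rank)
    if not store.table_exists(tbl):
        raise NotFoundError(f"snapshot table {tbl} does not exist")
    sim = store.fetchone(
        "SELECT ens_id FROM simulations WHERE sim_id=? AND sim_rank=?",
        (sim_id, sim_rank),
    )
    if sim is None:
        raise NotFoundError(f"no simulation row for ({sim_id}, {sim_rank})")
    ens_id = int(sim[0])

    selection = selection or SelectionSpec()
    max_snap = store.next_id(tbl, "snap_id") - 1
    snap_ids = selection.resolve_snapshots(max_snap)
    atom_set = selection.resolve_atoms(store, ens_id)
    explicit = selection.snap_ids is not None

    results = []
    for sid in snap_ids:
        row = store.fetchone(
            f"SELECT sim_step, trajectories, box FROM {tbl} WHERE snap_id=?",
            (sid,),
        )
        if row is None:
            if explicit:
                raise NotFoundError(f"snapshot {sid} not found in {tbl}")
            continue
        coords = [tuple(t) for t in store.unpack_json(row[1])]
        if atom_set is not None:
            coords = [t for t in coords if int(t[0]) in atom_set]
        results.append(FrameResult(
            snap_id=sid, sim_step=int(row[0]),
            coordinates=[(int(t[0]), float(t[1]), float(t[2]), float(t[3]))
                         for t in coords],
            box=[float(v) for v in store.unpack_json(row[2])],
        ))
    return results
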