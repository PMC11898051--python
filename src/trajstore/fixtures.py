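"""Synthetic systems, trajectories and swap schedules with ground truth.

These generators make every other module testable without any external
data: a linear bead-chain toy system exercising the atoms tier (real
element masses, symmetric bonds, backward-only Z-matrix), random-walk
trajectories wrapped into a periodic container, and replica-exchange swap
schedules that record the exact lineage of every frame so demultiplexing
can be verified against ground truth.

All randomness flows through one named generator seeded explicitly in
every operation signature; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boxes import BoxDescriptor, wrap_coordinates
from .db import Store
from .deposition import (deposit_snapshot, open_or_create_ensemble,
                         pack_coordinates, register_simulation)
from .records import NIL_REF, AtomRecord, LineageRef

__all__ = [
    "make_toy_system", "random_walk_trajectory", "replica_exchange_schedule",
    "SwapSchedule", "deposit_random_walk", "deposit_replica_exchange",
]

# bead-chain residue vocabulary; 3 backbone analogs per residue
_RESNAMES = ("ALA", "GLY", "SER", "VAL", "THR")
_ATOM_TEMPLATE = (  # (name, mass, biotype)
    ("N", 14.007, 1),
    ("CA", 12.011, 2),
    ("C", 12.011, 3),
)
_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def make_toy_system(n_chains: int, chain_length: int, seed: int
                    ) -> tuple[list[AtomRecord], list[str]]:
    """A linear bead-chain system: 3 atoms (N/CA/C analogs) per residue.

    Bonds run N-CA-C within a residue and C-N across consecutive residues
    of a chain; bound_partners are symmetric and the Z-matrix references
    only earlier atoms.  Deterministic for a given seed.
    """
    if n_chains < 1 or chain_length < 1:
        raise ValueError("n_chains and chain_length must be >= 1")
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    residues: list[str] = []
    seq = 0
    for chain in range(n_chains):
        chain_id = _CHAIN_IDS[chain % len(_CHAIN_IDS)]
        for res in range(chain_length):
            resname = _RESNAMES[int(rng.integers(len(_RESNAMES)))]
            residues.append(resname)
            for name, mass, biotype in _ATOM_TEMPLATE:
                seq += 1
                atoms.append(AtomRecord(
                    ens_id=0, atom_id=0, atom_seq=seq, sys_seq=seq,
                    atom_name=name,
                    resid_seq=chain * chain_length + res + 1,
                    resid_name=resname, chain_seq=chain_id, keyword="ATOM",
                    occupancy=1.0,
                    tempfactor=float(np.round(rng.uniform(0, 50), 2)),
                    biotype=biotype, molecule_id=chain + 1, mass=mass,
                    partial_charge=float(np.round(rng.uniform(-0.5, 0.5), 4)),
                    formal_charge=0,
                    charge_group_id=chain * chain_length + res + 1,
                    rfos_contribution=float(np.round(rng.uniform(-3, 1), 4)),
                    solvation_group_id=chain * chain_length + res + 1,
                ))
    # covalent bonds within each chain: backbone chain of 3L atoms
    for chain in range(n_chains):
        base = chain * chain_length * 3
        for i in range(chain_length * 3 - 1):
            a, b = atoms[base + i], atoms[base + i + 1]
            _add_bond(a, b)
    # Z-matrix: each atom references its up-to-three predecessors in-chain
    for chain in range(n_chains):
        base = chain * chain_length * 3
        for i in range(chain_length * 3):
            a = atoms[base + i]
            refs = [atoms[base + i - k].atom_seq if i - k >= 0 else 0
                    for k in (1, 2, 3)]
            a.zmatrix_references = refs + [0]  # chirality 0: dihedral form
            bond = 1.45 if a.atom_name == "CA" else 1.33 if a.atom_name == "N" else 1.52
            a.zmatrix_values = [
                bond if refs[0] else 0.0,
                110.0 if refs[1] else 0.0,
                float(np.round(rng.uniform(-180, 180), 3)) if refs[2] else 0.0,
            ]
    return atoms, residues


def _add_bond(a: AtomRecord, b: AtomRecord) -> None:
    for rec, other in ((a, b), (b, a)):
        if other.atom_seq in rec.bound_partners:
            continue
        try:
            slot = rec.bound_partners.index(0)
        except ValueError:
            raise ValueError(
                f"atom_seq {rec.atom_seq} already has 5 bound partners"
            ) from None
        rec.bound_partners[slot] = other.atom_seq


def random_walk_trajectory(system: tuple[list[AtomRecord], list[str]],
                           n_frames: int, box: BoxDescriptor,
                           step_sigma: float, seed: int,
                           snap_interval: int = 100
                           ) -> list[tuple[np.ndarray, int]]:
    """Gaussian random-walk frames wrapped into *box*.

    Returns ``[(coords (n_atoms, 3), sim_step), ...]`` with
    ``sim_step = frame_index * snap_interval``; deterministic per seed.
    ``step_sigma`` (Angstrom) of 0 freezes the walk at frame 1.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if step_sigma < 0:
        raise ValueError("step_sigma must be >= 0")
    atoms, _ = system
    n = len(atoms)
    rng = np.random.default_rng(seed)
    if box.shape_code in (1, 4):
        frac = rng.uniform(0.2, 0.8, size=(n, 3))
        coords = frac @ box.vectors + box.origin
    else:
        coords = box.origin + rng.uniform(-0.4, 0.4, size=(n, 3)) * box.radius
    frames = []
    for i in range(1, n_frames + 1):
        if i > 1 and step_sigma > 0:
            coords = coords + rng.normal(0.0, step_sigma, size=(n, 3))
        coords = wrap_coordinates(coords, box)
        frames.append((coords.copy(), i * snap_interval))
    return frames


# ---------------------------------------------------------------------------
# replica exchange
# ---------------------------------------------------------------------------

@dataclass
class SwapSchedule:
    """A replica-exchange swap history with ground-truth lineage.

    ``parent_replica[t][r]`` is the replica whose frame ``t-1`` is the
    geometric parent of replica *r*'s frame *t* (frames 1-based; frame 1
    has no parent).  ``swaps[t]`` lists the neighbor pairs exchanged when
    producing frame *t*.
    """

    n_replicas: int
    n_frames: int
    parent_replica: dict[int, list[int]]
    swaps: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    def lineage(self, replica: int, frame: int) -> list[tuple[int, int]]:
        """Ground-truth lineage of (replica, frame), oldest first."""
        chain = []
        r, t = replica, frame
        while t >= 1:
            chain.append((r, t))
            if t == 1:
                break
            r = self.parent_replica[t][r]
            t -= 1
        chain.reverse()
        return chain


def replica_exchange_schedule(n_replicas: int, n_frames: int,
                              swap_every: int, seed: int,
                              swap_probability: float = 0.5) -> SwapSchedule:
    """Generate a seeded swap history for a replica-exchange run.

    Every *swap_every*-th frame, a random set of disjoint neighbor pairs
    (each attempted with *swap_probability*) exchanges conformations, so
    the conformation that was in replica a continues in replica b.  The
    exchange at each swap step is a permutation of the replicas.
    """
    if n_replicas < 2:
        raise ValueError("n_replicas must be >= 2")
    if swap_every < 1:
        raise ValueError("swap_every must be >= 1")
    rng = np.random.default_rng(seed)
    parent_replica: dict[int, list[int]] = {}
    swaps: dict[int, list[tuple[int, int]]] = {}
    for t in range(2, n_frames + 1):
        mapping = list(range(n_replicas))
        if (t - 1) % swap_every == 0:
            chosen = []
            r = 0
            while r < n_replicas - 1:
                if rng.uniform() < swap_probability:
                    chosen.append((r, r + 1))
                    mapping[r], mapping[r + 1] = r + 1, r
                    r += 2  # pairs must be disjoint
                else:
                    r += 1
            swaps[t] = chosen
        parent_replica[t] = mapping
    return SwapSchedule(n_replicas=n_replicas, n_frames=n_frames,
                        parent_replica=parent_replica, swaps=swaps)


# ---------------------------------------------------------------------------
# deposition drivers (fixture stream -> live database)
# ---------------------------------------------------------------------------

_DEFAULT_META = dict(
    sim_summary="synthetic random-walk fixture",
    sim_software="trajstore-fixtures",
    snap_interval=100,
    box_shape=1, box_periodicity=7, ensemble_type=1, sampler_type=2,
    parallel_mode=0, united_atom_model=0, deposit_mode=2,
)


def deposit_random_walk(store: Store, key: str, n_chains: int = 1,
                        chain_length: int = 5, n_frames: int = 20,
                        box: BoxDescriptor | None = None,
                        step_sigma: float = 0.3, seed: int = 0,
                        meta: dict | None = None
                        ) -> tuple[int, tuple[int, int]]:
    """Generate and deposit one plain random-walk trajectory.

    Returns (ens_id, (sim_id, sim_rank)).
    """
    box = box or BoxDescriptor.cuboid((20.0, 20.0, 20.0))
    system = make_toy_system(n_chains, chain_length, seed)
    atoms, residues = system
    ens_id = open_or_create_ensemble(store, key, atoms, residues)
    m = dict(_DEFAULT_META)
    m.update(meta or {})
    m["sim_summary"] = m.get("sim_summary", "") or _DEFAULT_META["sim_summary"]
    pair = register_simulation(store, ens_id, m, n_replicas=1)[0]
    seqs = list(range(1, len(atoms) + 1))
    for coords, step in random_walk_trajectory(
            system, n_frames, box, step_sigma, seed + 1,
            snap_interval=m["snap_interval"]):
        deposit_snapshot(store, pair, pack_coordinates(seqs, coords), box,
                         sim_step=step)
    store.flush()
    return ens_id, pair


def deposit_replica_exchange(store: Store, key: str, n_replicas: int = 4,
                             n_frames: int = 50, swap_every: int = 10,
                             n_chains: int = 1, chain_length: int = 3,
                             seed: int = 0,
                             swap_probability: float = 0.5
                             ) -> tuple[int, list[tuple[int, int]], SwapSchedule]:
    """Generate and deposit a full synthetic replica-exchange ensemble.

    Per-replica random walks evolve independently; at swap steps the
    backward-connectivity triple of each frame points at the partner
    replica's previous frame, exactly as recorded in the returned
    :class:`SwapSchedule` ground truth.
    """
    box = BoxDescriptor.cuboid((25.0, 25.0, 25.0))
    system = make_toy_system(n_chains, chain_length, seed)
    atoms, residues = system
    ens_id = open_or_create_ensemble(store, key, atoms, residues)
    meta = dict(_DEFAULT_META)
    meta.update(sim_summary="synthetic replica-exchange fixture",
                parallel_mode=1)
    pairs = register_simulation(store, ens_id, meta, n_replicas=n_replicas)
    schedule = replica_exchange_schedule(n_replicas, n_frames, swap_every,
                                         seed + 1, swap_probability)
    walks = [random_walk_trajectory(system, n_frames, box, 0.3,
                                    seed + 2 + r,
                                    snap_interval=meta["snap_interval"])
             for r in range(n_replicas)]
    seqs = list(range(1, len(atoms) + 1))
    for t in range(1, n_frames + 1):
        for r, pair in enumerate(pairs):
            coords, step = walks[r][t - 1]
            if t == 1:
                parent = None
            else:
                pr = schedule.parent_replica[t][r]
                parent = LineageRef(pairs[pr][0], pairs[pr][1], t - 1)
            deposit_snapshot(store, pair, pack_coordinates(seqs, coords),
                             box, sim_step=step, parent=parent)
    store.flush()
    return ens_id, pairs, schedule
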