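"""In-memory record types mirroring the four storage tiers."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence


@dataclass(frozen=True)
class LineageRef:
    """Address of a snapshot: the unit of backward-connectivity traversal.

    The nil reference (no geometric parent) is ``(0, 0, 0)``.
    """

    sim_id: int
    sim_rank: int
    snap_id: int

    def is_nil(self) -> bool:
        return self.sim_id == 0 and self.sim_rank == 0 and self.snap_id == 0


NIL_REF = LineageRef(0, 0, 0)


@dataclass
class EnsembleRecord:
    """One row of the ensemble tier (the mapping table linking all tiers)."""

    ens_id: int
    ens_key: str
    nratoms: int
    residues: list[str]
    timestamp: str


@dataclass
class SimulationRecord:
    """One row of the simulation tier: all 16 metadata attributes.

    Integer-coded fields take their values from
    :data:`trajstore.codebooks.CODE_BOOKS`.
    """

    ens_id: int
    sim_id: int
    sim_rank: int
    sim_parent: int
    sim_summary: str
    sim_software: str
    nratoms: int
    equilibration_steps: int
    snap_interval: int
    box_shape: int
    box_periodicity: int
    ensemble_type: int
    sampler_type: int
    parallel_mode: int
    united_atom_model: int
    deposit_mode: int

    def metadata_fields(self) -> dict:
        """The fields that must agree when appending to an existing run."""
        d = asdict(self)
        for k in ("ens_id", "sim_id", "sim_rank", "sim_parent"):
            d.pop(k)
        return d


@dataclass
class AtomRecord:
    """One row of the atoms tier: identity, polymer role, topology, parameters.

    ``bound_partners`` holds the atom_seq of up to five covalent neighbours
    (0-padded).  ``zmatrix_references`` holds the bond/angle/torsion reference
    atom_seq values (0 if absent) plus a chirality indicator in {-1, 0, 1};
    0 means the third internal coordinate is a dihedral angle.
    ``zmatrix_values`` are the bond length (Angstrom), bond angle (deg) and
    dihedral or second bond angle (deg).
    """

    ens_id: int
    atom_id: int
    atom_seq: int
    sys_seq: int
    atom_name: str
    resid_seq: int
    resid_name: str
    chain_seq: str
    keyword: str
    occupancy: float
    tempfactor: float
    biotype: int
    molecule_id: int
    mass: float
    partial_charge: float
    formal_charge: int
    charge_group_id: int
    rfos_contribution: float
    solvation_group_id: int
    bound_partners: list[int] = field(default_factory=lambda: [0] * 5)
    zmatrix_references: list[int] = field(default_factory=lambda: [0] * 4)
    zmatrix_values: list[float] = field(default_factory=lambda: [0.0] * 3)

    #: fields compared when deciding whether two deposited systems are identical
    IDENTITY_FIELDS = (
        "atom_seq", "sys_seq", "atom_name", "resid_seq", "resid_name",
        "chain_seq", "keyword", "occupancy", "tempfactor", "biotype",
        "molecule_id", "mass", "partial_charge", "formal_charge",
        "charge_group_id", "rfos_contribution", "solvation_group_id",
        "bound_partners", "zmatrix_references", "zmatrix_values",
    )

    def identity(self) -> tuple:
        vals = []
        for f in self.IDENTITY_FIELDS:
            v = getattr(self, f)
            vals.append(tuple(v) if isinstance(v, list) else v)
        return tuple(vals)


@dataclass
class SnapshotRecord:
    """One row of a coordinate-tier (snapshot) table.

    ``trajectories`` is an ordered list of ``(atom_seq, x, y, z)`` 4-tuples
    with atom_seq starting at 1, aligned with the atoms tier; ``box`` is the
    12-element container descriptor (three box vectors then the origin).
    """

    ens_id: int
    snap_id: int
    sim_step: int
    previous_id: int
    previous_rank: int
    previous_snap: int
    sampler_id: int
    trajectories: Sequence[tuple[int, float, float, float]]
    box: Sequence[float]

    def parent_ref(self) -> LineageRef:
        return LineageRef(self.previous_id, self.previous_rank, self.previous_snap)
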