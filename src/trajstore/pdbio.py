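"""Reading annotated templates and trajectories from multi-model PDB files.

PDB is the mandatory interchange format for deposition: an annotated
single-model template defines the system (atoms tier), and a multi-model
PDB supplies frames.  Parsing goes through biotite's PDB reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from biotite.structure.io.pdb import PDBFile

from .errors import ValidationError
from .records import AtomRecord

__all__ = ["read_template", "read_frames"]


def read_template(path: str | Path) -> tuple[list[AtomRecord], list[str]]:
    """Build atoms-tier records and a residues list from a PDB template.

    Bond topology and Z-matrix data are not inferable from a plain PDB
    file (no chemical perception is attempted); those fields stay at the
    0 sentinel.
    """
    pdb = PDBFile.read(str(path))
    structure = pdb.get_structure(model=1)
    if structure.array_length() == 0:
        raise ValidationError(f"{path}: no atoms in first model")
    atoms: list[AtomRecord] = []
    residues: list[str] = []
    last_res = None
    chain_ids = sorted(set(structure.chain_id))
    mol_by_chain = {c: i + 1 for i, c in enumerate(chain_ids)}
    masses = _masses(structure)
    for i in range(structure.array_length()):
        res_key = (structure.chain_id[i], int(structure.res_id[i]))
        if res_key != last_res:
            residues.append(str(structure.res_name[i]))
            last_res = res_key
        atoms.append(AtomRecord(
            ens_id=0, atom_id=0, atom_seq=i + 1, sys_seq=i + 1,
            atom_name=str(structure.atom_name[i]),
            resid_seq=int(structure.res_id[i]),
            resid_name=str(structure.res_name[i]),
            chain_seq=str(structure.chain_id[i])[:2],
            keyword="HETATM" if structure.hetero[i] else "ATOM",
            occupancy=1.0,
            tempfactor=float(structure.b_factor[i])
            if "b_factor" in structure.get_annotation_categories() else 0.0,
            biotype=0,
            molecule_id=mol_by_chain[structure.chain_id[i]],
            mass=float(masses[i]),
            partial_charge=0.0,
            formal_charge=int(structure.charge[i])
            if "charge" in structure.get_annotation_categories() else 0,
            charge_group_id=0, rfos_contribution=0.0, solvation_group_id=0,
        ))
    return atoms, residues


def _masses(structure) -> np.ndarray:
    from biotite.structure.info import mass

    out = np.zeros(structure.array_length())
    for i, el in enumerate(structure.element):
        try:
            out[i] = mass(str(el).capitalize()) or 0.0
        except Exception:
            out[i] = 0.0
    return out


def read_frames(path: str | Path) -> list[np.ndarray]:
    """All models of a multi-model PDB as a list of (n_atoms, 3) arrays."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    return [np.asarray(stack.coord[m], dtype=float)
            for m in range(stack.stack_depth())]
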