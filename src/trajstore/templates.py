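"""Annotated structure templates generated from the atoms and ensemble tiers.

The atoms tier stores everything needed to reconstruct an annotated
structure file: an ATOM/HETATM line combines the stored keyword, atom_seq,
atom_name, resid_name, chain_seq and resid_seq with coordinates from one
snapshot, a constant occupancy of 1.00, a selectable temperature-factor
source, an element symbol derived from mass or name, and a net-charge
indicator from formal_charge.  Because the database deals with exactly
defined structures, insertion codes and alternate-location identifiers are
never emitted.

Template generation is strictly read-only.
"""

from __future__ import annotations

import warnings
from typing import Sequence

from .db import Store
from .errors import IntegrityError, ValidationError
from .records import AtomRecord
from .retrieval import fetch_atoms, fetch_ensemble

__all__ = ["pdb_template", "derive_element", "zmatrix_template",
           "sequence_template", "multimodel_pdb"]

# standard atomic weights (a.m.u.), common elements in simulated systems
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "D": 2.014, "He": 4.0026,
    "Li": 6.94, "Be": 9.0122, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "K": 39.098, "Ca": 40.078, "Ti": 47.867, "Cr": 51.996, "Mn": 54.938,
    "Fe": 55.845, "Co": 58.933, "Ni": 58.693, "Cu": 63.546, "Zn": 65.38,
    "Se": 78.971, "Br": 79.904, "Kr": 83.798, "Rb": 85.468, "Sr": 87.62,
    "Mo": 95.95, "Ag": 107.87, "Cd": 112.41, "I": 126.90, "Xe": 131.29,
    "Cs": 132.91, "Ba": 137.33, "Pt": 195.08, "Au": 196.97, "Hg": 200.59,
}

#: a mass this close (a.m.u.) to the runner-up weight counts as a near-tie,
#: letting the atom name arbitrate (e.g. coarse-grained particles)
_TIE_WINDOW = 0.5


class ElementError(ValidationError):
    """Mass and name jointly fail to identify an element."""


def _symbol_from_name(atom_name: str) -> str | None:
    stripped = "".join(c for c in atom_name if c.isalpha())
    if not stripped:
        return None
    two = stripped[:2].capitalize()
    if two in ATOMIC_WEIGHTS:
        return two
    one = stripped[0].upper()
    return one if one in ATOMIC_WEIGHTS else None


def derive_element(mass: float, atom_name: str = "") -> str:
    """Derive the element symbol from mass, with the name breaking near-ties.

    The element whose standard atomic weight is nearest to *mass* wins;
    the atom name arbitrates only when the two best candidates are within
    the tie window (so "CA" with mass 40.08 is calcium, not carbon).  When
    the mass is unusable the name alone is consulted.
    """
    if mass is None or mass <= 0:
        sym = _symbol_from_name(atom_name)
        if sym is None:
            raise ElementError(
                f"cannot classify element from mass {mass!r} and "
                f"name {atom_name!r}"
            )
        return sym
    ranked = sorted(ATOMIC_WEIGHTS.items(), key=lambda kv: abs(kv[1] - mass))
    best_sym, best_w = ranked[0]
    near = [s for s, w in ranked if abs(w - mass) <= abs(best_w - mass) + _TIE_WINDOW]
    if len(near) > 1:
        hint = _symbol_from_name(atom_name)
        if hint in near:
            return hint
    return best_sym


# ---------------------------------------------------------------------------
# PDB records
# ---------------------------------------------------------------------------

def _pdb_atom_name_field(name: str, element: str) -> str:
    """Columns 13-16: names shorter than 4 chars start at column 14 when the
    element symbol is a single character (PDB alignment convention)."""
    name = name.strip()[:4]
    if len(name) < 4 and len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _pdb_line(a: AtomRecord, x: float, y: float, z: float,
              bfactor: float) -> str:
    element = derive_element(a.mass, a.atom_name.strip())
    keyword = (a.keyword or "ATOM").strip().upper()
    if keyword not in ("ATOM", "HETATM"):
        keyword = "HETATM"
    chain = (a.chain_seq or " ").strip()
    if len(chain) > 1:
        warnings.warn(
            f"chain_seq {a.chain_seq!r} truncated to {chain[0]!r} for the "
            f"single-character PDB chain column", stacklevel=3,
        )
    chain_char = chain[0] if chain else " "
    charge = ""
    if a.formal_charge:
        sign = "+" if a.formal_charge > 0 else "-"
        charge = f"{abs(int(a.formal_charge))}{sign}"
    return (
        f"{keyword:<6s}"                       # 1-6  record name
        f"{a.atom_seq:>5d} "                   # 7-11 serial, 12 blank
        f"{_pdb_atom_name_field(a.atom_name, element)}"  # 13-16
        f" "                                   # 17   altLoc: never emitted
        f"{(a.resid_name or '').strip()[:3]:>3s}"        # 18-20
        f" {chain_char}"                       # 21 blank, 22 chain
        f"{a.resid_seq:>4d}"                   # 23-26
        f"    "                                # 27 iCode (never) + 28-30
        f"{x:>8.3f}{y:>8.3f}{z:>8.3f}"         # 31-54
        f"{1.0:>6.2f}"                         # 55-60 occupancy, always 1.00
        f"{bfactor:>6.2f}"                     # 61-66
        f"          "                          # 67-76
        f"{element:>2s}"                       # 77-78
        f"{charge:<2s}"                        # 79-80
    )


def pdb_template(store: Store, ens_id: int,
                 coords: Sequence[Sequence[float]],
                 bfactor_source: str = "tempfactor") -> str:
    """Render one frame as fixed-width PDB ATOM/HETATM records.

    *coords* is a packed frame of (atom_seq, x, y, z) rows covering any
    subset of the ensemble's atoms.  The temperature-factor column is
    filled from *bfactor_source* (any real-valued atoms-tier column, e.g.
    ``"partial_charge"``).  TER records separate molecules.
    """
    atoms = {a.atom_seq: a for a in fetch_atoms(store, ens_id)}
    if not atoms:
        raise ValidationError(f"ensemble {ens_id} has no atoms")
    lines = []
    last_mol = None
    last_atom = None
    for row in coords:
        seq = int(row[0])
        a = atoms.get(seq)
        if a is None:
            raise ValidationError(
                f"atom_seq {seq} is not part of ensemble {ens_id}"
            )
        try:
            bfac = float(getattr(a, bfactor_source))
        except AttributeError:
            raise ValidationError(
                f"unknown temperature-factor source {bfactor_source!r}"
            ) from None
        if last_mol is not None and a.molecule_id != last_mol:
            lines.append(_ter_line(last_atom))
        lines.append(_pdb_line(a, float(row[1]), float(row[2]), float(row[3]),
                               bfac))
        last_mol = a.molecule_id
        last_atom = a
    if last_atom is not None:
        lines.append(_ter_line(last_atom))
    return "\n".join(lines) + "\n"


def _ter_line(a: AtomRecord) -> str:
    chain = (a.chain_seq or " ").strip()[:1] or " "
    return (f"TER   {a.atom_seq + 1:>5d}      "
            f"{(a.resid_name or '').strip()[:3]:>3s} {chain}"
            f"{a.resid_seq:>4d}")


def multimodel_pdb(store: Store, ens_id: int,
                   frames: Sequence[Sequence[Sequence[float]]],
                   bfactor_source: str = "tempfactor") -> str:
    """Render several frames as a MODEL/ENDMDL multi-model PDB file."""
    parts = []
    for i, frame in enumerate(frames, start=1):
        parts.append(f"MODEL {i:>8d}")
        parts.append(pdb_template(store, ens_id, frame, bfactor_source).rstrip("\n"))
        parts.append("ENDMDL")
    parts.append("END")
    return "\n".join(parts) + "\n"


# ---------------------------------------------------------------------------
# Z-matrix and sequence listings
# ---------------------------------------------------------------------------

def zmatrix_template(store: Store, ens_id: int) -> str:
    """Z-matrix listing from the atoms tier alone, one line per atom.

    Each line gives the atom_seq, the three reference indices (0 for
    absent ancestors), the chirality indicator (-1/0/1; 0 means the third
    internal coordinate is a dihedral), then bond length (Angstrom), bond
    angle (deg) and dihedral-or-second-angle (deg).
    """
    atoms = fetch_atoms(store, ens_id)
    if not atoms:
        raise ValidationError(f"ensemble {ens_id} has no atoms")
    lines = []
    for a in atoms:
        refs = list(a.zmatrix_references)
        for r in refs[:3]:
            if r >= a.atom_seq and r != 0:
                raise IntegrityError(
                    f"atom_seq {a.atom_seq}: Z-matrix reference {r} is a "
                    f"forward reference"
                )
        bl, ang, tor = a.zmatrix_values
        lines.append(
            f"{a.atom_seq:>6d} {refs[0]:>6d} {refs[1]:>6d} {refs[2]:>6d} "
            f"{refs[3]:>2d} {bl:>10.4f} {ang:>10.4f} {tor:>10.4f}"
        )
    return "\n".join(lines) + "\n"


def sequence_template(store: Store, ens_id: int) -> str:
    """The ensemble's residues array rendered one token per line."""
    ens = fetch_ensemble(store, ens_id)
    if not ens.residues:
        warnings.warn(
            f"ensemble {ens.ens_key!r} has an empty residues array; "
            f"metadata incomplete", stacklevel=2,
        )
        return ""
    return "\n".join(ens.residues) + "\n"
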