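"""Integer code books of the trajectory-storage standard.

The simulation tier stores categorical metadata as small integers so that
queries are precise and unit/spelling ambiguities ("AMBER" vs "Amber") are
avoided.  This module is the single source of truth for those codes and for
the naming conventions of the ensemble and coordinate tiers.

Labels are matched case-insensitively, with underscores, hyphens and spaces
interchangeable, so ``"grand canonical"`` and ``"Grand_Canonical"`` encode
identically.  The codes themselves are frozen; :func:`register_code` exposes
a controlled extension point without guessing future assignments.
"""

from __future__ import annotations

import re
from typing import Iterable

__all__ = [
    "CODE_BOOKS",
    "CodeBookError",
    "ConsistencyError",
    "KeyValidationError",
    "encode",
    "decode",
    "encode_periodicity",
    "decode_periodicity",
    "periodicity_admissible",
    "register_code",
    "snapshot_table_name",
    "parse_snapshot_table_name",
    "validate_ens_key",
]


class CodeBookError(KeyError):
    """Unknown category, label, or integer code."""


class ConsistencyError(ValueError):
    """Metadata combination forbidden by the standard (e.g. periodic sphere)."""


class KeyValidationError(ValueError):
    """Ensemble key contains characters outside [A-Za-z0-9_-]."""


#: category -> {code: canonical label}
CODE_BOOKS: dict[str, dict[int, str]] = {
    "box_shape": {
        1: "rectangular cuboid",
        2: "sphere",
        3: "cylinder",
        4: "triclinic",
    },
    "box_periodicity": {
        0: "none",
        1: "z",
        2: "y",
        3: "x",
        4: "yz",
        5: "xz",
        6: "xy",
        7: "xyz",
    },
    "ensemble_type": {
        1: "canonical (NVT)",
        2: "microcanonical (NVE)",
        3: "isothermal-isobaric (NPT)",
        5: "semigrand",
        6: "grand canonical",
    },
    "sampler_type": {
        1: "Monte Carlo",
        2: "Newtonian dynamics",
        3: "stochastic dynamics",
        4: "Brownian dynamics",
        5: "hybrid scheme 1",
        6: "hybrid scheme 2",
        7: "hybrid scheme 3",
    },
    "parallel_mode": {
        0: "none",
        1: "replica exchange",
        2: "progress index-guided sampling (PIGS)",
        3: "parallel metadynamics / Wang-Landau",
        4: "parallel simulated annealing",
        5: "other adaptive sampling",
        6: "reservoir / library-based sampling",
    },
    "united_atom_model": {
        0: "all hydrogens",
        1: "no aliphatic hydrogens",
        2: "only polar hydrogens",
        3: "other coarse-grained",
    },
    "deposit_mode": {
        1: "deposited while running",
        2: "not deposited while running",
    },
}

#: extra accepted spellings, per category, mapping normalized alias -> code
_ALIASES: dict[str, dict[str, int]] = {
    "box_shape": {"cuboid": 1, "rectangular": 1, "box": 1, "orthorhombic": 1},
    "ensemble_type": {
        "nvt": 1,
        "canonical": 1,
        "nve": 2,
        "microcanonical": 2,
        "npt": 3,
        "isothermal isobaric": 3,
        "uvt": 6,
        "muvt": 6,
    },
    "sampler_type": {
        "mc": 1,
        "monte carlo": 1,
        "newtonian": 2,
        "md": 2,
        "molecular dynamics": 2,
        "stochastic": 3,
        "langevin": 3,
        "brownian": 4,
        "bd": 4,
        "hybrid": 5,
    },
    "parallel_mode": {
        "re": 1,
        "remd": 1,
        "pigs": 2,
        "progress index guided sampling": 2,
        "metadynamics": 3,
        "wang landau": 3,
        "simulated annealing": 4,
        "adaptive": 5,
        "reservoir": 6,
        "library": 6,
    },
    "united_atom_model": {
        "all h": 0,
        "united aliphatic": 1,
        "polar h only": 2,
        "coarse grained": 3,
    },
    "deposit_mode": {"live": 1, "running": 1, "post hoc": 2, "not running": 2},
}


def _normalize(label: str) -> str:
    # underscores/hyphens/spaces interchangeable, case-insensitive,
    # parenthesised qualifiers ignored
    s = re.sub(r"\([^)]*\)", " ", label.lower())
    s = re.sub(r"[-_/]+", " ", s)
    return " ".join(s.split())


def _lookup_tables(category: str) -> tuple[dict[int, str], dict[str, int]]:
    try:
        book = CODE_BOOKS[category]
    except KeyError:
        raise CodeBookError(
            f"unknown code category {category!r}; valid categories: "
            f"{sorted(CODE_BOOKS)}"
        ) from None
    rev = {_normalize(lbl): code for code, lbl in book.items()}
    for alias, code in _ALIASES.get(category, {}).items():
        rev.setdefault(_normalize(alias), code)
    return book, rev


def encode(category: str, label: str) -> int:
    """Return the standard's integer code for *label* in *category*."""
    book, rev = _lookup_tables(category)
    code = rev.get(_normalize(label))
    if code is None:
        raise CodeBookError(
            f"unknown {category} label {label!r}; valid labels: "
            f"{sorted(book.values())}"
        )
    return code


def decode(category: str, code: int) -> str:
    """Return the canonical label for an integer *code* in *category*."""
    book, _ = _lookup_tables(category)
    try:
        return book[int(code)]
    except (KeyError, TypeError):
        raise CodeBookError(
            f"unknown {category} code {code!r}; valid codes: {sorted(book)}"
        ) from None


def is_valid_code(category: str, code: int) -> bool:
    book, _ = _lookup_tables(category)
    return code in book


def register_code(category: str, code: int, label: str) -> None:
    """Register an extension code.

    The codes printed by the standard are frozen; attempts to redefine them
    are rejected.  New codes extend the book for forward compatibility.
    """
    book, rev = _lookup_tables(category)
    if code in book:
        raise CodeBookError(f"{category} code {code} is already assigned")
    if _normalize(label) in rev:
        raise CodeBookError(f"{category} label {label!r} is already assigned")
    book[int(code)] = label


# ---------------------------------------------------------------------------
# periodicity encoding
# ---------------------------------------------------------------------------

# codes 1..6 follow the fixed order z, y, x, yz, xz, xy; 7 is fully periodic
_PERIODICITY_CODES: dict[frozenset[str], int] = {
    frozenset(): 0,
    frozenset("z"): 1,
    frozenset("y"): 2,
    frozenset("x"): 3,
    frozenset("yz"): 4,
    frozenset("xz"): 5,
    frozenset("xy"): 6,
    frozenset("xyz"): 7,
}
_PERIODICITY_DIMS = {v: k for k, v in _PERIODICITY_CODES.items()}


def encode_periodicity(periodic_dims: Iterable[str], shape_code: int) -> int:
    """Encode the set of periodic dimensions as the standard's 0-7 code.

    For triclinic cells the labels x/y/z refer to box-vector order rather
    than Cartesian axes.  Spheres must be aperiodic; cylinders admit at most
    one periodic dimension.
    """
    if shape_code not in CODE_BOOKS["box_shape"]:
        raise CodeBookError(f"unknown box_shape code {shape_code!r}")
    dims = frozenset(d.lower() for d in periodic_dims)
    bad = dims - frozenset("xyz")
    if bad:
        raise ConsistencyError(f"unknown dimension labels {sorted(bad)}")
    if shape_code == 2 and dims:
        raise ConsistencyError("spheres must be aperiodic")
    if shape_code == 3 and len(dims) > 1:
        raise ConsistencyError(
            "cylinders admit at most one periodic dimension (along the axis)"
        )
    return _PERIODICITY_CODES[dims]


def decode_periodicity(code: int) -> frozenset[str]:
    """Inverse of :func:`encode_periodicity` (shape-independent)."""
    try:
        return _PERIODICITY_DIMS[int(code)]
    except (KeyError, TypeError):
        raise CodeBookError(f"unknown box_periodicity code {code!r}") from None


def periodicity_admissible(shape_code: int, periodicity_code: int) -> bool:
    """Whether a (shape, periodicity) pair is allowed by the standard."""
    if shape_code not in CODE_BOOKS["box_shape"]:
        return False
    if periodicity_code not in _PERIODICITY_DIMS:
        return False
    dims = _PERIODICITY_DIMS[periodicity_code]
    if shape_code == 2:
        return not dims
    if shape_code == 3:
        return len(dims) <= 1
    return True


# ---------------------------------------------------------------------------
# naming conventions
# ---------------------------------------------------------------------------

_ENS_KEY_RE = re.compile(r"[A-Za-z0-9_-]+\Z")
_TABLE_RE = re.compile(r"snapshots_(\d+)_(\d+)\Z")


def validate_ens_key(key: str) -> str:
    """Return *key* unchanged iff it is a legal ensemble key.

    Keys are limited to alphanumerics, underscores and hyphens so that they
    remain safe in file names, URLs and SQL string literals.
    """
    if not key:
        raise KeyValidationError("ensemble key must be nonempty")
    if not _ENS_KEY_RE.match(key):
        offender = next(c for c in key if not re.match(r"[A-Za-z0-9_-]", c))
        raise KeyValidationError(
            f"ensemble key {key!r} contains forbidden character {offender!r}"
        )
    return key


def snapshot_table_name(sim_id: int, sim_rank: int) -> str:
    """Coordinate-tier table name ``snapshots_<sim_id>_<sim_rank>``."""
    if sim_id < 1:
        raise ValueError(f"sim_id must be >= 1, got {sim_id}")
    if sim_rank < 0:
        raise ValueError(f"sim_rank must be >= 0, got {sim_rank}")
    return f"snapshots_{sim_id:d}_{sim_rank:d}"


def parse_snapshot_table_name(name: str) -> tuple[int, int]:
    """Inverse of :func:`snapshot_table_name`."""
    m = _TABLE_RE.match(name)
    if not m:
        raise ValueError(f"{name!r} is not a snapshot table name")
    return int(m.group(1)), int(m.group(2))
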