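"""Simulation-container descriptors and their 12-element encoding.

Every snapshot stores its container as 12 reals: box vector 1 (xyz), box
vectors 2 and 3, and finally the origin.  The shape and periodicity codes
live in the simulation tier and must be cross-referenced to interpret the
12-vector.

For curved containers the 12-vector layout is this package's own
convention (it is NOT interoperable with CAMPARI's):

* sphere:   element 1 = radius, elements 2-9 = 0, elements 10-12 = center
* cylinder: element 1 = radius, element 2 = height, element 3 = axis index
  (1 = x, 2 = y, 3 = z), elements 4-9 = 0, elements 10-12 = center
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codebooks import ConsistencyError, periodicity_admissible, decode_periodicity

__all__ = ["BoxDescriptor", "encode_box", "decode_box", "wrap_coordinates",
           "box_extent"]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class BoxDescriptor:
    """A simulation container: shape, periodicity, geometry.

    ``vectors`` (3x3, Angstrom, rows = box vectors) applies to cuboid and
    triclinic cells; ``radius``/``height``/``axis`` apply to curved
    containers.  ``origin`` is the formal origin (cell corner, or center of
    a curved container).
    """

    shape_code: int
    periodicity_code: int
    vectors: np.ndarray | None = None
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = 0.0
    height: float = 0.0
    axis: str = "z"

    def __post_init__(self) -> None:
        if not periodicity_admissible(self.shape_code, self.periodicity_code):
            raise ConsistencyError(
                f"box_shape {self.shape_code} with box_periodicity "
                f"{self.periodicity_code} is not admissible"
            )
        self.origin = np.asarray(self.origin, dtype=float)
        if self.shape_code in (1, 4):
            if self.vectors is None:
                raise ValueError("cell containers require 3x3 box vectors")
            self.vectors = np.asarray(self.vectors, dtype=float).reshape(3, 3)
        elif self.shape_code == 2:
            if self.radius <= 0:
                raise ValueError("sphere requires a positive radius")
        elif self.shape_code == 3:
            if self.radius <= 0 or self.height <= 0:
                raise ValueError("cylinder requires positive radius and height")
            if self.axis not in _AXES:
                raise ValueError(f"cylinder axis must be x/y/z, got {self.axis!r}")

    @classmethod
    def cuboid(cls, lengths, origin=(0.0, 0.0, 0.0),
               periodicity_code: int = 7) -> "BoxDescriptor":
        """Rectangular cuboid with edge lengths (Lx, Ly, Lz)."""
        return cls(1, periodicity_code, vectors=np.diag(np.asarray(lengths, float)),
                   origin=np.asarray(origin, float))

    def periodic_dims(self) -> frozenset[str]:
        return decode_periodicity(self.periodicity_code)


def box_extent(box: BoxDescriptor) -> float:
    """Largest linear extent of the container (Angstrom)."""
    if box.shape_code == 2:
        return 2.0 * box.radius
    if box.shape_code == 3:
        return max(2.0 * box.radius, box.height)
    return float(max(np.linalg.norm(box.vectors, axis=1)))


def encode_box(box: BoxDescriptor) -> list[float]:
    """Encode a container as the standard's 12-vector."""
    out = np.zeros(12)
    if box.shape_code in (1, 4):
        out[0:9] = box.vectors.reshape(9)
    elif box.shape_code == 2:
        out[0] = box.radius
    else:  # cylinder
        out[0] = box.radius
        out[1] = box.height
        out[2] = float(_AXES[box.axis] + 1)
    out[9:12] = box.origin
    return [float(v) for v in out]


def decode_box(vec, shape_code: int, periodicity_code: int = 0) -> BoxDescriptor:
    """Exact inverse of :func:`encode_box` given the simulation-tier codes."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (12,):
        raise ValueError(f"box vector must have 12 elements, got {vec.shape}")
    origin = vec[9:12]
    if shape_code in (1, 4):
        return BoxDescriptor(shape_code, periodicity_code,
                             vectors=vec[0:9].reshape(3, 3), origin=origin)
    if shape_code == 2:
        return BoxDescriptor(2, periodicity_code, radius=float(vec[0]),
                             origin=origin)
    if shape_code == 3:
        axis = {1: "x", 2: "y", 3: "z"}[int(round(vec[2]))]
        return BoxDescriptor(3, periodicity_code, radius=float(vec[0]),
                             height=float(vec[1]), axis=axis, origin=origin)
    raise ValueError(f"unknown box_shape code {shape_code!r}")


def wrap_coordinates(coords: np.ndarray, box: BoxDescriptor) -> np.ndarray:
    """Wrap Cartesian coordinates into the primary cell along periodic dims.

    Only cell containers (cuboid/triclinic) are wrapped; curved containers
    are aperiodic (or axis-periodic cylinders, wrapped along the axis for
    the axis-aligned case).
    """
    coords = np.asarray(coords, dtype=float)
    dims = box.periodic_dims()
    if not dims:
        return coords.copy()
    rel = coords - box.origin
    if box.shape_code == 1:
        lengths = np.diag(box.vectors)
        out = rel.copy()
        for d in dims:
            i = _AXES[d]
            out[:, i] = np.mod(out[:, i], lengths[i])
        return out + box.origin
    if box.shape_code == 4:
        # fractional-coordinate wrap; dim labels refer to box-vector order
        frac = rel @ np.linalg.inv(box.vectors)
        for d in dims:
            i = _AXES[d]
            frac[:, i] = np.mod(frac[:, i], 1.0)
        return frac @ box.vectors + box.origin
    if box.shape_code == 3:
        i = _AXES[box.axis]
        out = rel.copy()
        out[:, i] = np.mod(out[:, i] + box.height / 2.0, box.height) - box.height / 2.0
        return out + box.origin
    return coords.copy()
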