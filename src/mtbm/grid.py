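"""Quad-grid surface model for tube-like subcortical structures.

A :class:`SurfaceGrid` stores one nucleus surface as an ``n_rings x n_around``
lattice of 3D vertices (mm).  The lattice is closed in the around-ring
direction (column index wraps modulo ``n_around``) and open at the two end
rings; for volume computation the open ends are capped by implicit triangle
fans to the end-ring centroids, giving a closed tube-with-caps surface.

Two grids are *corresponded* when they share ``(n_rings, n_around)``: vertex
``(i, j)`` on one matches vertex ``(i, j)`` on the other.  All vertex-wise
morphometry in this package relies on that convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateCellError, ValidationError

STRUCTURES = ("putamen", "globus_pallidus", "caudate")
SIDES = ("left", "right")

_EPS_AREA = 1e-12  # mm^2; below this a cell triangle counts as degenerate


@dataclass
class SurfaceGrid:
    """One nucleus surface on a closed-around / open-ends quad lattice.

    Parameters
    ----------
    vertices
        Array of shape ``(n_rings, n_around, 3)``, coordinates in mm.
    structure
        One of ``putamen``, ``globus_pallidus``, ``caudate``.
    side
        ``left`` or ``right``.
    """

    vertices: np.ndarray
    structure: str = "putamen"
    side: str = "left"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 3 or self.vertices.shape[2] != 3:
            raise ValidationError(
                f"vertices must have shape (n_rings, n_around, 3), got {self.vertices.shape}"
            )
        if self.structure not in STRUCTURES:
            raise ValidationError(f"unknown structure {self.structure!r}")
        if self.side not in SIDES:
            raise ValidationError(f"unknown side {self.side!r}")

    @property
    def n_rings(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_around(self) -> int:
        return self.vertices.shape[1]

    @property
    def n_vertices(self) -> int:
        return self.n_rings * self.n_around

    @property
    def label(self) -> str:
        return f"{self.structure}_{self.side}"

    def validate(self) -> "SurfaceGrid":
        """Check all grid invariants; return self for chaining."""
        if self.n_rings < 3 or self.n_around < 3:
            raise ValidationError(
                f"grid must be at least 3x3, got {self.n_rings}x{self.n_around}"
            )
        if not np.isfinite(self.vertices).all():
            raise ValidationError("vertices contain non-finite coordinates")
        areas = cell_areas(self)
        bad = np.argwhere(areas <= _EPS_AREA)
        if bad.size:
            i, j = bad[0]
            raise DegenerateCellError(int(i), int(j), f"area {areas[i, j]:.3e} mm^2")
        return self

    def corresponds_to(self, other: "SurfaceGrid") -> bool:
        return (self.n_rings, self.n_around) == (other.n_rings, other.n_around)

    def copy(self) -> "SurfaceGrid":
        return replace(self, vertices=self.vertices.copy())


@dataclass
class CellFrameField:
    """Orthonormal tangent frames, one per quad cell.

    ``origin``, ``e1``, ``e2`` have shape ``(n_rings - 1, n_around, 3)``.
    ``e1`` is the normalized around-ring mean edge direction, ``e2`` its
    Gram-Schmidt complement in the cell plane, with ``e1 x e2`` aligned with
    the outward surface normal.
    """

    origin: np.ndarray
    e1: np.ndarray
    e2: np.ndarray


def _quad_corners(surface: SurfaceGrid):
    """Corner arrays p00, p01, p11, p10 per cell, shape (R-1, M, 3).

    p00 = v(i, j), p01 = v(i, j+1), p11 = v(i+1, j+1), p10 = v(i+1, j),
    with j+1 taken modulo n_around.
    """
    v = surface.vertices
    vr = np.roll(v, -1, axis=1)  # j+1
    p00 = v[:-1]
    p01 = vr[:-1]
    p11 = vr[1:]
    p10 = v[1:]
    return p00, p01, p11, p10


def cell_areas(surface: SurfaceGrid) -> np.ndarray:
    """Per-cell areas (mm^2) under the (i,j)->(i+1,j+1) diagonal split."""
    p00, p01, p11, p10 = _quad_corners(surface)
    a1 = 0.5 * np.linalg.norm(np.cross(p01 - p00, p11 - p00), axis=-1)
    a2 = 0.5 * np.linalg.norm(np.cross(p11 - p00, p10 - p00), axis=-1)
    return a1 + a2


def _triangles(surface: SurfaceGrid):
    """All triangles of the closed tube-with-caps surface as vertex triples.

    Quads split along the (i,j)->(i+1,j+1) diagonal; caps are centroid fans
    at the two end rings.  Winding is outward for grids whose j index runs
    counterclockwise when seen from the +axis end.
    """
    p00, p01, p11, p10 = _quad_corners(surface)
    tris = [
        (p00, p01, p11),
        (p00, p11, p10),
    ]
    v = surface.vertices
    c0 = v[0].mean(axis=0)
    c1 = v[-1].mean(axis=0)
    ring0 = v[0]
    ring0r = np.roll(ring0, -1, axis=0)
    ring1 = v[-1]
    ring1r = np.roll(ring1, -1, axis=0)
    c0b = np.broadcast_to(c0, ring0.shape)
    c1b = np.broadcast_to(c1, ring1.shape)
    tris.append((c0b, ring0r, ring0))  # bottom cap, reversed traversal
    tris.append((c1b, ring1, ring1r))  # top cap
    return tris


def signed_volume(surface: SurfaceGrid) -> float:
    """Signed enclosed volume (mm^3) via the divergence theorem."""
    total = 0.0
    for a, b, c in _triangles(surface):
        total += np.einsum("...i,...i->...", a, np.cross(b, c)).sum()
    return total / 6.0


def compute_volume(surface: SurfaceGrid) -> float:
    """Enclosed volume in mm^3, positive regardless of stored orientation.

    Inward-oriented grids are handled by sign-flipping with a warning; the
    vertex data itself is never modified.
    """
    surface.validate()
    vol = signed_volume(surface)
    if vol < 0:
        warnings.warn(
            f"{surface.label}: grid is inward-oriented; volume sign corrected",
            stacklevel=2,
        )
        vol = -vol
    return vol


def is_outward(surface: SurfaceGrid) -> bool:
    return signed_volume(surface) >= 0


def cell_frames(surface: SurfaceGrid) -> CellFrameField:
    """Per-cell orthonormal tangent frames.

    e1 follows the around-ring mean edge; e2 completes the frame in the cell
    plane (Gram-Schmidt on the ring-direction mean edge).  The frame
    handedness is normalized so that ``e1 x e2`` points along the outward
    normal even for inward-stored grids, keeping Jacobians reflection-free
    across subjects with differing stored orientation.
    """
    p00, p01, p11, p10 = _quad_corners(surface)
    origin = (p00 + p01 + p11 + p10) / 4.0
    a = 0.5 * ((p01 - p00) + (p11 - p10))  # around-ring mean edge
    b = 0.5 * ((p10 - p00) + (p11 - p01))  # ring-direction mean edge
    na = np.linalg.norm(a, axis=-1)
    scale = max(float(np.max(na)), 1.0)
    bad = np.argwhere(na < 1e-12 * scale)
    if bad.size:
        i, j = bad[0]
        raise DegenerateCellError(int(i), int(j), "zero-length around edge")
    e1 = a / na[..., None]
    b_perp = b - np.einsum("...i,...i->...", b, e1)[..., None] * e1
    nb = np.linalg.norm(b_perp, axis=-1)
    bad = np.argwhere(nb < 1e-12 * scale)
    if bad.size:
        i, j = bad[0]
        raise DegenerateCellError(int(i), int(j), "ring edge collinear with around edge")
    e2 = b_perp / nb[..., None]
    if not is_outward(surface):
        e2 = -e2
    return CellFrameField(origin=origin, e1=e1, e2=e2)
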