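"""Surface tensor-based morphometry: MAD, Jacobians, log tensors, features.

Given a template grid and a corresponded subject grid, each interior quad
cell carries a 2x2 Jacobian J mapping template in-plane edge coordinates to
subject in-plane edge coordinates.  Shape change is summarized by the
deformation tensor S = (J^T J)^(1/2); its matrix logarithm lives in a vector
space (log-Euclidean framework) so ordinary multivariate statistics apply to
the three unique entries (s11, s12, s22).  Together with the medial axial
distance (MAD) — the distance from each vertex to the ring-centroid medial
axis, a thickness measure — they form the per-vertex 4-feature used by the
multivariate group test; det J alone gives the univariate area-change map.

Cell quantities are transferred to vertices by cell-area-weighted averaging
over the (up to four) adjacent valid cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError
from .grid import SurfaceGrid, cell_areas, cell_frames

_COND_LIMIT = 1e12


@dataclass
class JacobianField:
    """Per-cell 2x2 Jacobians from template to subject local frames.

    ``J`` has shape ``(n_rings-1, n_around, 2, 2)``; ``valid`` marks cells
    with det J > 0 (folded cells are excluded downstream); ``template_areas``
    are the template cell areas used as transfer weights.
    """

    J: np.ndarray
    valid: np.ndarray
    template_areas: np.ndarray

    @property
    def det(self) -> np.ndarray:
        return np.linalg.det(self.J)


def compute_mad(surface: SurfaceGrid) -> np.ndarray:
    """Medial axial distance: distance of each vertex to its ring centroid.

    The medial axis is the polyline of ring centroids; MAD(i, j) is the
    Euclidean distance from vertex (i, j) to centroid i, in mm.
    """
    centroids = surface.vertices.mean(axis=1, keepdims=True)
    return np.linalg.norm(surface.vertices - centroids, axis=-1)


def _mean_edges(surface: SurfaceGrid):
    v = surface.vertices
    vr = np.roll(v, -1, axis=1)
    a = 0.5 * ((vr[:-1] - v[:-1]) + (vr[1:] - v[1:]))  # around mean edge
    b = 0.5 * ((v[1:] - v[:-1]) + (vr[1:] - vr[:-1]))  # ring mean edge
    return a, b


def _edges_in_frame(surface: SurfaceGrid):
    """2x2 per-cell edge matrices [a|b] in the cell's orthonormal frame."""
    frames = cell_frames(surface)
    a, b = _mean_edges(surface)
    E = np.empty(a.shape[:2] + (2, 2))
    E[..., 0, 0] = np.einsum("...i,...i->...", a, frames.e1)
    E[..., 1, 0] = np.einsum("...i,...i->...", a, frames.e2)
    E[..., 0, 1] = np.einsum("...i,...i->...", b, frames.e1)
    E[..., 1, 1] = np.einsum("...i,...i->...", b, frames.e2)
    return E


def compute_jacobians(template: SurfaceGrid, subject: SurfaceGrid) -> JacobianField:
    """Per-cell 2x2 maps sending template edge coordinates to subject's.

    Both surfaces' edges are expressed in their own orthonormal cell frames;
    J solves J @ E_template = E_subject exactly (two independent edges).
    Cells with det J <= 0 (folds) are masked, not clamped.
    """
    if not template.corresponds_to(subject):
        raise ValidationError(
            f"grids not corresponded: {template.n_rings}x{template.n_around} "
            f"vs {subject.n_rings}x{subject.n_around}"
        )
    Et = _edges_in_frame(template)
    Es = _edges_in_frame(subject)
    J = Es @ np.linalg.inv(Et)
    # per-cell frames are right-handed by construction, so det J is positive
    # even across a local fold; a fold shows up as the subject cell normal
    # flipping against the corresponding template normal (grids arrive
    # pre-aligned, so normal agreement is the fold criterion)
    at, bt = _mean_edges(template)
    asub, bsub = _mean_edges(subject)
    agree = (
        np.einsum("...i,...i->...", np.cross(at, bt), np.cross(asub, bsub)) > 0
    )
    J[~agree, 1, :] *= -1.0  # reflect: S unchanged, det goes negative
    det = np.linalg.det(J)
    valid = det > 0
    n_bad = int((~valid).sum())
    if n_bad:
        warnings.warn(f"{n_bad} folded cells masked in Jacobian field", stacklevel=2)
    return JacobianField(J=J, valid=valid, template_areas=cell_areas(template))


def log_deformation_tensor(J: np.ndarray) -> np.ndarray:
    """Unique entries (s11, s12, s22) of log S, with S = (J^T J)^(1/2).

    Works on a single 2x2 matrix or a batch (..., 2, 2); returns (..., 3).
    log S = (1/2) log(J^T J), evaluated in the eigenbasis of the symmetric
    positive-definite J^T J.  Rotations map to the zero vector.
    """
    J = np.asarray(J, dtype=float)
    single = J.ndim == 2
    if single:
        J = J[None]
    det = np.linalg.det(J)
    if np.any(det <= 0):
        raise DomainError("log deformation tensor requires det J > 0")
    JtJ = np.swapaxes(J, -1, -2) @ J
    w, V = np.linalg.eigh(JtJ)
    if np.any(w[..., 0] <= 0) or np.any(w[..., 1] / np.maximum(w[..., 0], 1e-300) > _COND_LIMIT):
        raise DomainError("near-singular J^T J (condition number > 1e12)")
    logw = 0.5 * np.log(w)
    L = (V * logw[..., None, :]) @ np.swapaxes(V, -1, -2)
    out = np.stack([L[..., 0, 0], L[..., 0, 1], L[..., 1, 1]], axis=-1)
    return out[0] if single else out


def log_tensor_cells(jac: JacobianField) -> np.ndarray:
    """Per-cell (s11, s12, s22), NaN at masked cells."""
    out = np.full(jac.J.shape[:2] + (3,), np.nan)
    if jac.valid.any():
        out[jac.valid] = log_deformation_tensor(jac.J[jac.valid])
    return out


def cells_to_vertices(cell_values: np.ndarray, jac: JacobianField) -> np.ndarray:
    """Area-weighted transfer of per-cell values to the vertex lattice.

    Vertex (i, j) averages its adjacent valid cells (i-1, j-1), (i-1, j),
    (i, j-1), (i, j) — the j index wrapping, the i index clamped at the end
    rings.  Vertices with no valid adjacent cell come back NaN.
    """
    nc_r, nc_a = jac.valid.shape
    R, M = nc_r + 1, nc_a
    extra = cell_values.shape[2:]
    pad = (None,) * len(extra)
    w = np.where(jac.valid, jac.template_areas, 0.0)
    cvw = np.where(jac.valid[(...,) + pad], cell_values, 0.0) * w[(...,) + pad]
    num = np.zeros((R, M) + extra)
    den = np.zeros((R, M))
    # cell (ci, cj) touches vertices (ci+di, (cj+dj) mod M), di,dj in {0,1}
    for di in (0, 1):
        for dj in (0, 1):
            num[di : di + nc_r] += np.roll(cvw, dj, axis=1)
            den[di : di + nc_r] += np.roll(w, dj, axis=1)
    ok = den > 0
    safe = np.where(ok, den, 1.0)
    out = np.where(ok[(...,) + pad], num / safe[(...,) + pad], np.nan)
    return out


def detj_vertex_field(jac: JacobianField) -> np.ndarray:
    """Per-vertex det J (area-weighted over adjacent valid cells)."""
    return cells_to_vertices(jac.det, jac)


def log_tensor_vertex_field(jac: JacobianField) -> np.ndarray:
    """Per-vertex (s11, s12, s22), transferred like det J."""
    return cells_to_vertices(log_tensor_cells(jac), jac)


def assemble_features(mad: np.ndarray, log_s: np.ndarray) -> np.ndarray:
    """Stack (MAD, s11, s12, s22) into the per-vertex 4-feature array.

    MAD is in mm, the tensor channels dimensionless; shapes must agree on
    the vertex lattice.
    """
    mad = np.asarray(mad, dtype=float)
    log_s = np.asarray(log_s, dtype=float)
    if log_s.shape != mad.shape + (3,):
        raise ValidationError(
            f"shape mismatch: MAD {mad.shape} vs logS {log_s.shape}"
        )
    return np.concatenate([mad[..., None], log_s], axis=-1)


def subject_features(template: SurfaceGrid, subject: SurfaceGrid) -> np.ndarray:
    """Full 4-channel feature field for one subject against a template."""
    jac = compute_jacobians(template, subject)
    mad = compute_mad(subject)
    return assemble_features(mad, log_tensor_vertex_field(jac))
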