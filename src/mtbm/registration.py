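"""Constrained harmonic registration in the shared (ring, around) domain.

Corresponded grids already share a parameter lattice; residual
misparameterization is corrected by solving the discrete Laplace equation
for a reparameterization map on that lattice.  The map is the identity on
the two end rings, periodic in the around direction, and pinned at landmark
pairs (hard Dirichlet constraints).  Being harmonic, it minimizes the
Dirichlet energy among all maps with the same constraint values.  Subject
vertices are then resampled at the mapped parameters by bilinear
interpolation, and morphometry proceeds on the resampled grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConvergenceError, FoldError, ValidationError
from .grid import SurfaceGrid

_DIRECT_LIMIT = 400_000  # unknowns; beyond this fall back to CG


@dataclass
class LandmarkSet:
    """Hard point constraints: template grid index -> subject grid index.

    ``pairs`` is a list of ((i_t, j_t), (i_s, j_s)) tuples; a template vertex
    may appear at most once.
    """

    pairs: list = field(default_factory=list)

    def validate(self, n_rings: int, n_around: int) -> "LandmarkSet":
        seen = set()
        for (it, jt), (isub, jsub) in self.pairs:
            for i, j in ((it, jt), (isub, jsub)):
                if not (0 <= i < n_rings and 0 <= j < n_around):
                    raise ValidationError(f"landmark index ({i}, {j}) out of range")
            if (it, jt) in seen:
                raise ValidationError(f"duplicate template landmark ({it}, {jt})")
            seen.add((it, jt))
        return self

    @classmethod
    def from_csv(cls, path) -> "LandmarkSet":
        raw = np.loadtxt(path, delimiter=",", dtype=int, ndmin=2)
        if raw.shape[1] != 4:
            raise ValidationError("landmark CSV needs 4 columns: i_t,j_t,i_s,j_s")
        return cls([((r[0], r[1]), (r[2], r[3])) for r in raw])


def _wrap_delta(d: float, period: int) -> float:
    """Shift d into (-period/2, period/2]."""
    d = d % period
    if d > period / 2:
        d -= period
    return d


def harmonic_parameter_map(
    n_rings: int,
    n_around: int,
    landmarks: LandmarkSet,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Solve for the harmonic reparameterization map.

    Returns an (n_rings, n_around, 2) array of (ring, around) parameters:
    the identity lattice plus a displacement that is discrete-harmonic
    (5-point Laplacian, periodic around) away from constraints, zero on the
    end rings, and equal to the landmark offsets at landmark vertices.
    """
    R, M = n_rings, n_around
    landmarks.validate(R, M)
    N = R * M
    fixed = np.zeros((R, M), dtype=bool)
    fixed[0] = fixed[-1] = True
    target = np.zeros((R, M, 2))
    for (it, jt), (isub, jsub) in landmarks.pairs:
        if fixed[it, jt] and (it, jt) != (isub, jsub) and it in (0, R - 1):
            raise ValidationError(
                f"landmark on end ring ({it}, {jt}) conflicts with fixed boundary"
            )
        fixed[it, jt] = True
        target[it, jt, 0] = isub - it
        target[it, jt, 1] = _wrap_delta(jsub - jt, M)

    idx = np.arange(N).reshape(R, M)
    rows, cols, vals = [], [], []
    b = np.zeros((N, 2))
    fixed_flat = fixed.ravel()
    for i in range(R):
        for j in range(M):
            n = idx[i, j]
            if fixed_flat[n]:
                rows.append(n)
                cols.append(n)
                vals.append(1.0)
                b[n] = target[i, j]
            else:
                rows.append(n)
                cols.append(n)
                vals.append(4.0)
                for ni, nj in ((i - 1, j), (i + 1, j), (i, (j - 1) % M), (i, (j + 1) % M)):
                    rows.append(n)
                    cols.append(idx[ni, nj])
                    vals.append(-1.0)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(N, N))
    if N <= _DIRECT_LIMIT:
        delta = spla.spsolve(A.tocsc(), b)
    else:
        delta = np.empty_like(b)
        for c in range(2):
            x, info = spla.cg(A, b[:, c], rtol=tol, maxiter=max_iter)
            if info != 0:
                res = float(np.linalg.norm(A @ x - b[:, c]))
                raise ConvergenceError(res, tol)
            delta[:, c] = x
    res = float(np.linalg.norm(A @ delta - b) / max(1.0, np.linalg.norm(b)))
    if res > max(tol, 1e-8):
        raise ConvergenceError(res, tol)
    delta = delta.reshape(R, M, 2)
    ii, jj = np.meshgrid(np.arange(R), np.arange(M), indexing="ij")
    phi = np.stack([ii + delta[..., 0], jj + delta[..., 1]], axis=-1)
    _check_folds(phi, M)
    return phi


def _check_folds(phi: np.ndarray, period: int) -> None:
    """Raise FoldError at the first parameter cell with non-positive area."""
    d_i = phi[1:] - phi[:-1]
    d_j = np.roll(phi, -1, axis=1) - phi
    # around component of the j-difference must unwrap across the seam
    d_j[..., 1] = (d_j[..., 1] + period / 2) % period - period / 2
    d_j = d_j[:-1]
    det = d_i[..., 0] * d_j[..., 1] - d_i[..., 1] * d_j[..., 0]
    bad = np.argwhere(det <= 0)
    if bad.size:
        i, j = bad[0]
        raise FoldError(int(i), int(j), f"parameter-map det {det[i, j]:.3e}")


def harmonic_energy(phi: np.ndarray, period: int | None = None) -> float:
    """Discrete Dirichlet energy of a parameter map (sum over lattice edges)."""
    if period is None:
        period = phi.shape[1]
    d_i = phi[1:] - phi[:-1]
    d_j = np.roll(phi, -1, axis=1) - phi
    d_j[..., 1] = (d_j[..., 1] + period / 2) % period - period / 2
    return float((d_i**2).sum() + (d_j**2).sum())


def resample_grid(subject: SurfaceGrid, phi: np.ndarray) -> SurfaceGrid:
    """Bilinearly sample subject vertices at parameters phi (periodic in j)."""
    R, M = subject.n_rings, subject.n_around
    r = np.clip(phi[..., 0], 0, R - 1)
    a = phi[..., 1] % M
    r0 = np.clip(np.floor(r).astype(int), 0, R - 2)
    fr = r - r0
    a0f = np.floor(a)
    fa = a - a0f
    a0 = a0f.astype(int) % M  # a may round up to exactly M after the modulo
    v = subject.vertices
    v00 = v[r0, a0]
    v01 = v[r0, (a0 + 1) % M]
    v10 = v[r0 + 1, a0]
    v11 = v[r0 + 1, (a0 + 1) % M]
    fr = fr[..., None]
    fa = fa[..., None]
    out = (
        v00 * (1 - fr) * (1 - fa)
        + v01 * (1 - fr) * fa
        + v10 * fr * (1 - fa)
        + v11 * fr * fa
    )
    return SurfaceGrid(out, structure=subject.structure, side=subject.side)


def harmonic_register(
    subject: SurfaceGrid,
    template: SurfaceGrid,
    landmarks: LandmarkSet | None = None,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> SurfaceGrid:
    """Reparameterize a subject grid onto the template's parameter lattice.

    With no landmarks (or self-consistent ones) the harmonic map is the
    identity and the subject is returned unchanged up to resampling
    round-off; landmark constraints bend the interior smoothly while the
    end rings stay fixed.
    """
    if not template.corresponds_to(subject):
        raise ValidationError("subject and template grids must share dimensions")
    landmarks = landmarks or LandmarkSet()
    phi = harmonic_parameter_map(
        template.n_rings, template.n_around, landmarks, tol=tol, max_iter=max_iter
    )
    out = resample_grid(subject, phi)
    return out.validate()


def displacement_field(template: SurfaceGrid, registered: SurfaceGrid) -> np.ndarray:
    """Per-vertex displacement u(i, j) = subject(i, j) - template(i, j), mm."""
    if not template.corresponds_to(registered):
        raise ValidationError("displacement field requires corresponded grids")
    return registered.vertices - template.vertices


def mean_template(surfaces) -> SurfaceGrid:
    """Vertex-wise mean of corresponded grids (the 'intermediate' surface)."""
    surfaces = list(surfaces)
    if not surfaces:
        raise ValidationError("need at least one surface")
    first = surfaces[0]
    for s in surfaces[1:]:
        if not first.corresponds_to(s):
            raise ValidationError("all surfaces must share grid dimensions")
    verts = np.mean([s.vertices for s in surfaces], axis=0)
    return SurfaceGrid(verts, structure=first.structure, side=first.side)
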