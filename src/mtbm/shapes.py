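"""Parametric grid constructors (cylinders, spheres, ellipsoids, boxes).

These produce :class:`~mtbm.grid.SurfaceGrid` objects with the package's
tube-with-caps topology: ring index runs along the long axis, the around
index wraps.  They serve both as test geometry with closed-form volumes and
as base shapes for the synthetic cohort generator.
"""

from __future__ import annotations

import numpy as np

from .grid import SurfaceGrid


def cylinder_grid(
    radius: float = 5.0,
    length: float = 20.0,
    n_rings: int = 40,
    n_around: int = 60,
    structure: str = "putamen",
    side: str = "left",
) -> SurfaceGrid:
    """Circular cylinder along +x; rings are circles of constant x."""
    x = np.linspace(-length / 2, length / 2, n_rings)
    theta = 2 * np.pi * np.arange(n_around) / n_around
    verts = np.empty((n_rings, n_around, 3))
    verts[..., 0] = x[:, None]
    verts[..., 1] = radius * np.cos(theta)[None, :]
    verts[..., 2] = radius * np.sin(theta)[None, :]
    return SurfaceGrid(verts, structure=structure, side=side)


def sphere_grid(
    radius: float = 10.0,
    n_rings: int = 50,
    n_around: int = 100,
    pole_margin: float | None = None,
    structure: str = "putamen",
    side: str = "left",
) -> SurfaceGrid:
    """Sphere with rings at equally spaced polar angles.

    Rings sit at theta_i = m + i * (pi - 2 m) / (n_rings - 1) with margin m
    (default half a ring spacing) so the end rings are genuine circles, not
    degenerate points; the poles are closed by the implicit caps.
    """
    if pole_margin is None:
        pole_margin = 0.5 * np.pi / n_rings
    theta = np.linspace(pole_margin, np.pi - pole_margin, n_rings)
    phi = 2 * np.pi * np.arange(n_around) / n_around
    verts = np.empty((n_rings, n_around, 3))
    verts[..., 0] = radius * np.cos(theta)[:, None]
    verts[..., 1] = radius * (np.sin(theta)[:, None] * np.cos(phi)[None, :])
    verts[..., 2] = radius * (np.sin(theta)[:, None] * np.sin(phi)[None, :])
    # theta decreasing in x: ensure around direction gives outward orientation
    return SurfaceGrid(verts[::-1], structure=structure, side=side)


def ellipsoid_grid(
    semi_axes=(20.0, 8.5, 7.0),
    n_rings: int = 50,
    n_around: int = 100,
    structure: str = "putamen",
    side: str = "left",
) -> SurfaceGrid:
    """Triaxial ellipsoid, long axis = x; rings at constant polar angle."""
    a, b, c = semi_axes
    base = sphere_grid(1.0, n_rings=n_rings, n_around=n_around,
                       structure=structure, side=side)
    verts = base.vertices * np.array([a, b, c])
    return SurfaceGrid(verts, structure=structure, side=side)


def box_grid(
    lx: float = 10.0,
    ly: float = 20.0,
    lz: float = 30.0,
    n_rings: int = 7,
    n_around: int | None = None,
    structure: str = "putamen",
    side: str = "left",
) -> SurfaceGrid:
    """Axis-aligned box as a tube along z with rectangular rings.

    The around index traces the rectangle perimeter with the four corners
    always included as vertices, so the divergence-theorem volume is exactly
    lx * ly * lz.
    """
    if n_around is None:
        n_around = 8
    # perimeter parameter points: corners at 0, lx, lx+ly, 2lx+ly, closing at 2(lx+ly)
    corners = np.array([0.0, lx, lx + ly, 2 * lx + ly])
    perim = 2 * (lx + ly)
    # place n_around points: corners plus equal subdivisions of each side
    per_side = max(1, n_around // 4)
    ts = []
    sides = [(0.0, lx), (lx, lx + ly), (lx + ly, 2 * lx + ly), (2 * lx + ly, perim)]
    for s0, s1 in sides:
        ts.extend(np.linspace(s0, s1, per_side, endpoint=False))
    ts = np.array(ts)
    _ = corners  # corners included by construction (linspace starts at s0)

    def xy(t):
        t = t % perim
        if t < lx:
            return (t - lx / 2, -ly / 2)
        if t < lx + ly:
            return (lx / 2, t - lx - ly / 2)
        if t < 2 * lx + ly:
            return (lx / 2 - (t - lx - ly), ly / 2)
        return (-lx / 2, ly / 2 - (t - 2 * lx - ly))

    ring_xy = np.array([xy(t) for t in ts])
    z = np.linspace(-lz / 2, lz / 2, n_rings)
    n_ar = len(ts)
    verts = np.empty((n_rings, n_ar, 3))
    verts[..., 0] = ring_xy[None, :, 0]
    verts[..., 1] = ring_xy[None, :, 1]
    verts[..., 2] = z[:, None]
    return SurfaceGrid(verts, structure=structure, side=side)
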