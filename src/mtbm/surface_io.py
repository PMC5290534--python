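"""Reading and writing surface grids as VTK legacy ASCII polydata or PLY.

Both formats carry the grid dimensions as metadata so files round-trip to
the exact lattice: VTK stores ``n_rings=<R> n_around=<M>`` (plus structure
and side) as key=value tokens on the title line; PLY stores one
``comment <key> <value>`` line per key.  Coordinates and scalars are written
with 17 significant digits, so ASCII round-trips are bit-exact for doubles.

Per-vertex scalar maps (detJ, p values, correlation r, ...) are stored as
named VTK ``POINT_DATA`` ``SCALARS`` arrays, or as extra vertex properties
in PLY, in the order given.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np

from .errors import FormatError, ValidationError
from .grid import SurfaceGrid

_FMT = "%.17g"

_META_KEYS = ("n_rings", "n_around", "structure", "side")


def _quads(R: int, M: int) -> np.ndarray:
    """Quad connectivity (flattened row-major vertex ids), (R-1)*M x 4."""
    i, j = np.meshgrid(np.arange(R - 1), np.arange(M), indexing="ij")
    jn = (j + 1) % M
    return np.stack(
        [i * M + j, i * M + jn, (i + 1) * M + jn, (i + 1) * M + j], axis=-1
    ).reshape(-1, 4)


def _check_scalars(surface: SurfaceGrid, scalars: Mapping[str, np.ndarray]):
    out = {}
    n = surface.n_vertices
    for name, vals in scalars.items():
        arr = np.asarray(vals, dtype=float).reshape(-1)
        if arr.size != n:
            raise ValidationError(
                f"scalar map {name!r} has {arr.size} values for {n} vertices"
            )
        out[name] = arr
    return out


# ---------------------------------------------------------------- VTK legacy


def _write_vtk(surface: SurfaceGrid, scalars, path):
    R, M = surface.n_rings, surface.n_around
    pts = surface.vertices.reshape(-1, 3)
    quads = _quads(R, M)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(
            f"mtbm surface n_rings={R} n_around={M} "
            f"structure={surface.structure} side={surface.side}\n"
        )
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} double\n")
        np.savetxt(fh, pts, fmt=_FMT)
        fh.write(f"POLYGONS {len(quads)} {len(quads) * 5}\n")
        np.savetxt(fh, np.hstack([np.full((len(quads), 1), 4), quads]), fmt="%d")
        if scalars:
            fh.write(f"POINT_DATA {len(pts)}\n")
            for name, vals in scalars.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, vals, fmt=_FMT)


def _read_vtk(path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 5 or not lines[0].startswith("# vtk"):
        raise FormatError(f"{path}: not a VTK legacy file")
    meta = {}
    for tok in lines[1].split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    if "n_rings" not in meta or "n_around" not in meta:
        raise FormatError(
            f"{path}: title line lacks n_rings/n_around grid metadata"
        )
    R, M = int(meta["n_rings"]), int(meta["n_around"])
    k = 2
    while k < len(lines) and not lines[k].startswith("POINTS"):
        k += 1
    if k == len(lines):
        raise FormatError(f"{path}: no POINTS section")
    n_pts = int(lines[k].split()[1])
    if n_pts != R * M:
        raise FormatError(f"{path}: POINTS count {n_pts} != n_rings*n_around {R * M}")
    vals = []
    k += 1
    while len(vals) < 3 * n_pts:
        vals.extend(float(x) for x in lines[k].split())
        k += 1
    pts = np.array(vals).reshape(n_pts, 3)
    scalars: dict[str, np.ndarray] = {}
    while k < len(lines):
        line = lines[k]
        if line.startswith("SCALARS"):
            name = line.split()[1]
            k += 2  # skip LOOKUP_TABLE line
            svals: list[float] = []
            while len(svals) < n_pts:
                svals.extend(float(x) for x in lines[k].split())
                k += 1
            scalars[name] = np.array(svals)
        else:
            k += 1
    grid = SurfaceGrid(
        pts.reshape(R, M, 3),
        structure=meta.get("structure", "putamen"),
        side=meta.get("side", "left"),
    )
    return grid, scalars


# ------------------------------------------------------------------ PLY


def _write_ply(surface: SurfaceGrid, scalars, path):
    R, M = surface.n_rings, surface.n_around
    pts = surface.vertices.reshape(-1, 3)
    quads = _quads(R, M)
    cols = [pts]
    names = []
    for name, vals in scalars.items():
        cols.append(vals[:, None])
        names.append(name)
    data = np.hstack(cols)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment n_rings {R}\ncomment n_around {M}\n")
        fh.write(f"comment structure {surface.structure}\n")
        fh.write(f"comment side {surface.side}\n")
        fh.write(f"element vertex {len(pts)}\n")
        for prop in ("x", "y", "z", *names):
            fh.write(f"property double {prop}\n")
        fh.write(f"element face {len(quads)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        np.savetxt(fh, data, fmt=_FMT)
        np.savetxt(fh, np.hstack([np.full((len(quads), 1), 4), quads]), fmt="%d")


def _read_ply(path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise FormatError(f"{path}: not a PLY file")
    meta: dict[str, str] = {}
    props: list[str] = []
    n_pts = 0
    k = 1
    in_vertex = False
    while k < len(lines):
        toks = lines[k].split()
        k += 1
        if not toks:
            continue
        if toks[0] == "comment" and len(toks) >= 3:
            meta[toks[1]] = toks[2]
        elif toks[0] == "element":
            in_vertex = toks[1] == "vertex"
            if in_vertex:
                n_pts = int(toks[2])
        elif toks[0] == "property" and in_vertex and toks[1] != "list":
            props.append(toks[2])
        elif toks[0] == "end_header":
            break
    else:
        raise FormatError(f"{path}: missing end_header")
    if "n_rings" not in meta or "n_around" not in meta:
        raise FormatError(f"{path}: header lacks n_rings/n_around comments")
    R, M = int(meta["n_rings"]), int(meta["n_around"])
    if n_pts != R * M:
        raise FormatError(f"{path}: vertex count {n_pts} != n_rings*n_around {R * M}")
    rows = np.array(
        [[float(x) for x in lines[k + r].split()] for r in range(n_pts)]
    )
    if rows.shape[1] != len(props):
        raise FormatError(f"{path}: vertex rows do not match property list")
    pts = rows[:, :3]
    scalars = {name: rows[:, 3 + idx] for idx, name in enumerate(props[3:])}
    grid = SurfaceGrid(
        pts.reshape(R, M, 3),
        structure=meta.get("structure", "putamen"),
        side=meta.get("side", "left"),
    )
    return grid, scalars


# ------------------------------------------------------------------ public


def _infer_format(path, fmt):
    if fmt is not None:
        return fmt
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".vtk", ".ply"):
        return ext[1:]
    raise FormatError(f"cannot infer surface format from {path!r}; pass format=")


def write_surface(surface: SurfaceGrid, path, scalars=None, format=None) -> None:
    """Write a surface (plus optional named per-vertex scalar maps) to disk.

    Scalar maps must supply one value per vertex; their insertion order is
    preserved in the file.
    """
    fmt = _infer_format(path, format)
    surface.validate()
    smaps = _check_scalars(surface, scalars or {})
    if fmt == "vtk":
        _write_vtk(surface, smaps, path)
    elif fmt == "ply":
        _write_ply(surface, smaps, path)
    else:
        raise FormatError(f"unsupported surface format {fmt!r}")


def read_surface(path, format=None) -> SurfaceGrid:
    """Read a surface grid; raises FormatError on missing grid metadata."""
    grid, _ = read_surface_with_scalars(path, format=format)
    return grid


def read_surface_with_scalars(path, format=None):
    """Read a surface grid plus any named per-vertex scalar maps."""
    fmt = _infer_format(path, format)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt == "vtk":
        grid, scalars = _read_vtk(path)
    elif fmt == "ply":
        grid, scalars = _read_ply(path)
    else:
        raise FormatError(f"unsupported surface format {fmt!r}")
    grid.validate()
    return grid, scalars
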