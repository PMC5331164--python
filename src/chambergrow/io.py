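"""Artifact IO: grid container, VTK rectilinear grids, binary STL.

The grid container is a single compressed NumPy ``.npz`` archive holding
the phase and mask arrays plus a JSON metadata record (format version,
spacing, shape) — lossless and readable from any language with a zip +
NPY reader.

VTK output is the legacy ASCII ``RECTILINEAR_GRID`` format with the phase
and any supplied per-element fields as CELL_DATA, loadable in ParaView.

STL output triangulates the exposed voxel faces of one phase (two
triangles per square face, outward-oriented), yielding a watertight
surface whose area is exactly (exposed face count) x spacing^2 — the
natural geometry hand-off to additive manufacturing at powder resolution.
"""

from __future__ import annotations

import json
import struct
import zipfile
from typing import Mapping, Optional

import numpy as np

from .grid import Phase, VoxelGrid

__all__ = [
    "save_grid",
    "load_grid",
    "export_vtk",
    "export_stl",
    "voxel_surface",
    "GridIOError",
]

_FORMAT_NAME = "chambergrow-voxelgrid"
_FORMAT_VERSION = 1


class GridIOError(RuntimeError):
    """Raised for corrupt, truncated or incompatible grid containers."""


def save_grid(grid: VoxelGrid, path) -> None:
    """Write a lossless grid container (compressed .npz)."""
    meta = {
        "format": _FORMAT_NAME,
        "version": _FORMAT_VERSION,
        "spacing": grid.spacing,
        "shape": list(grid.shape),
    }
    np.savez_compressed(
        path,
        phase=grid.phase,
        design_mask=grid.design_mask,
        roi_mask=grid.roi_mask,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_grid(path) -> VoxelGrid:
    """Read a grid container written by :func:`save_grid`."""
    try:
        with np.load(path) as data:
            required = {"phase", "design_mask", "roi_mask", "meta"}
            if not required <= set(data.files):
                raise GridIOError(
                    f"not a grid container: missing {required - set(data.files)}"
                )
            meta = json.loads(bytes(data["meta"]).decode())
            if meta.get("format") != _FORMAT_NAME:
                raise GridIOError(f"unknown container format {meta.get('format')!r}")
            if meta.get("version") != _FORMAT_VERSION:
                raise GridIOError(
                    f"unsupported container version {meta.get('version')!r}"
                )
            grid = VoxelGrid(
                phase=data["phase"],
                spacing=float(meta["spacing"]),
                design_mask=data["design_mask"],
                roi_mask=data["roi_mask"],
            )
    except (OSError, ValueError, KeyError, zipfile.BadZipFile,
            json.JSONDecodeError) as exc:
        raise GridIOError(f"cannot read grid container {path}: {exc}") from exc
    if list(grid.shape) != meta["shape"]:
        raise GridIOError("metadata shape disagrees with stored arrays")
    return grid


# ----------------------------------------------------------------------
# VTK


def export_vtk(
    grid: VoxelGrid,
    path,
    cell_fields: Optional[Mapping[str, np.ndarray]] = None,
) -> None:
    """Write a legacy ASCII VTK rectilinear grid with per-voxel cell data.

    ``cell_fields`` maps field names to 3D arrays of the grid's shape;
    the phase labels and both masks are always included.
    """
    cell_fields = dict(cell_fields or {})
    for name, arr in cell_fields.items():
        if np.asarray(arr).shape != grid.shape:
            raise ValueError(f"cell field {name!r} shape mismatch")
    nx, ny, nz = grid.shape
    h = grid.spacing
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("chambergrow voxel model\n")
        fh.write("ASCII\nDATASET RECTILINEAR_GRID\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        for name, n in (("X", nx), ("Y", ny), ("Z", nz)):
            fh.write(f"{name}_COORDINATES {n + 1} double\n")
            fh.write(" ".join(f"{i * h:.9g}" for i in range(n + 1)) + "\n")
        fh.write(f"CELL_DATA {nx * ny * nz}\n")
        _write_scalar(fh, "phase", grid.phase, "int")
        _write_scalar(fh, "design_mask", grid.design_mask.astype(np.int8), "int")
        _write_scalar(fh, "roi_mask", grid.roi_mask.astype(np.int8), "int")
        for name, arr in cell_fields.items():
            _write_scalar(fh, name, np.asarray(arr, dtype=float), "double")


def _write_scalar(fh, name: str, arr: np.ndarray, vtk_type: str) -> None:
    fh.write(f"SCALARS {name} {vtk_type} 1\nLOOKUP_TABLE default\n")
    # VTK cell ordering is x-fastest, then y, then z
    flat = np.transpose(arr, (2, 1, 0)).ravel()
    if vtk_type == "int":
        fh.write("\n".join(str(int(v)) for v in flat) + "\n")
    else:
        fh.write("\n".join(f"{float(v):.9g}" for v in flat) + "\n")


# ----------------------------------------------------------------------
# STL

# for each face direction: (axis, side) and the 4 corner offsets of the
# face, wound counter-clockwise as seen from outside (outward normal)
_FACE_CORNERS = {
    (0, -1): [(0, 0, 0), (0, 0, 1), (0, 1, 1), (0, 1, 0)],
    (0, +1): [(1, 0, 0), (1, 1, 0), (1, 1, 1), (1, 0, 1)],
    (1, -1): [(0, 0, 0), (1, 0, 0), (1, 0, 1), (0, 0, 1)],
    (1, +1): [(0, 1, 0), (0, 1, 1), (1, 1, 1), (1, 1, 0)],
    (2, -1): [(0, 0, 0), (0, 1, 0), (1, 1, 0), (1, 0, 0)],
    (2, +1): [(0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)],
}


def voxel_surface(grid: VoxelGrid, phase: Phase) -> tuple[np.ndarray, np.ndarray]:
    """Triangulated exposed-face surface of one phase.

    Returns ``(vertices, triangles)``: vertex coordinates in meters and
    integer triangle indices, two triangles per exposed voxel face,
    consistently outward-oriented.  Raises ``ValueError`` if the phase is
    absent.
    """
    mask = grid.phase == phase
    if not mask.any():
        raise ValueError(f"phase {Phase(phase).name} has no voxels")
    h = grid.spacing
    tri_corner_blocks = []
    for (axis, side), corners in _FACE_CORNERS.items():
        exposed = mask.copy()
        shifted = np.zeros_like(mask)
        sl_src = [slice(None)] * 3
        sl_dst = [slice(None)] * 3
        if side < 0:
            sl_dst[axis] = slice(1, None)
            sl_src[axis] = slice(0, -1)
        else:
            sl_dst[axis] = slice(0, -1)
            sl_src[axis] = slice(1, None)
        shifted[tuple(sl_dst)] = mask[tuple(sl_src)]
        exposed &= ~shifted
        ijk = np.argwhere(exposed)
        if len(ijk) == 0:
            continue
        quad = ijk[:, None, :] + np.asarray(corners)[None, :, :]  # (n, 4, 3)
        tris = quad[:, [0, 1, 2, 0, 2, 3], :].reshape(-1, 3, 3)
        tri_corner_blocks.append(tris)
    all_tris = np.concatenate(tri_corner_blocks, axis=0)  # (n_tri, 3, 3) lattice
    verts_flat = all_tris.reshape(-1, 3)
    uniq, inverse = np.unique(verts_flat, axis=0, return_inverse=True)
    triangles = inverse.reshape(-1, 3)
    return uniq.astype(float) * h, triangles


def export_stl(grid: VoxelGrid, phase: Phase, path) -> tuple[int, float]:
    """Write a binary STL of one phase's exposed voxel surface.

    Returns ``(triangle count, total area in m^2)``.
    """
    verts, tris = voxel_surface(grid, phase)
    v = verts[tris]  # (n, 3, 3)
    normals = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    areas = 0.5 * np.linalg.norm(normals, axis=1)
    lens = np.linalg.norm(normals, axis=1)
    lens[lens == 0] = 1.0
    normals = normals / lens[:, None]
    with open(path, "wb") as fh:
        fh.write(b"chambergrow voxel surface".ljust(80, b"\0"))
        fh.write(struct.pack("<I", len(tris)))
        rec = np.empty(
            len(tris),
            dtype=np.dtype(
                [("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]
            ),
        )
        rec["n"] = normals
        rec["v"] = v
        rec["attr"] = 0
        fh.write(rec.tobytes())
    return len(tris), float(areas.sum())
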