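"""Synthetic voxelized implant-in-bone model builder.

A parameterized, axisymmetric stand-in for a threaded cylindrical dental
implant placed in a rectangular bone block: a titanium core with annular
thread rings (helix collapsed to rings at the thread pitch), a cortical
crest layer over a cancellous body, and rectangular circumferential troughs
recessed into the core between adjacent threads.  The troughs start out
filled with cancellous bone and form the healing-chamber design region; a
cylindrical shell around the implant is flagged as the evaluation ROI.

All dimensions are SI lengths and must be positive multiples of the voxel
spacing — every surface is snapped to the voxel lattice; there are no
partial-volume elements.  Voxels are classified by their center point, so a
cylinder of radius r contains exactly the voxels whose center distance from
the axis is <= r.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .grid import MaterialSpec, Phase, VoxelGrid, default_materials

__all__ = ["ImplantModelParams", "build_synthetic_model"]


def _as_voxels(value: float, spacing: float, name: str) -> int:
    """Convert an SI length to a whole voxel count, validating divisibility."""
    n = value / spacing
    n_round = round(n)
    if abs(n - n_round) > 1e-6:
        raise ValueError(
            f"{name} = {value!r} m is not a multiple of the voxel spacing "
            f"{spacing!r} m"
        )
    if n_round < 0:
        raise ValueError(f"{name} must be non-negative")
    return int(n_round)


@dataclass
class ImplantModelParams:
    """Dimensions of the synthetic implant-in-bone model (SI units, m).

    The bone block spans the full x/y extent of the grid; the implant axis
    runs along z through the block center.  The implant is inserted from the
    top: its topmost face is flush with the top of the grid, the abutment
    protrudes ``abutment_height`` above the bone crest, and the embedded
    length is ``implant_length - abutment_height``.

    ``trough_depth`` defaults to half the thread pitch and ``trough_height``
    to the inter-thread gap minus one voxel clearance on each side.
    """

    block_width_x: float = 2.4e-3
    block_width_y: float = 2.4e-3
    block_height: float = 3.0e-3
    cortical_thickness: float = 0.3e-3
    core_radius: float = 0.4e-3
    implant_length: float = 2.8e-3
    abutment_height: float = 0.6e-3
    thread_pitch: float = 0.5e-3
    thread_depth: float = 0.15e-3
    thread_height: float = 0.1e-3
    thread_offset: float = 0.1e-3
    trough_depth: Optional[float] = None  # default: thread_pitch / 2
    trough_height: Optional[float] = None  # default: gap - 2 * spacing
    roi_margin: float = 0.5e-3
    spacing: float = 50e-6

    def __post_init__(self) -> None:
        if self.trough_depth is None:
            self.trough_depth = self.thread_pitch / 2.0
        if self.trough_height is None:
            gap = self.thread_pitch - self.thread_height
            self.trough_height = max(gap - 2.0 * self.spacing, 0.0)

    # ------------------------------------------------------------------
    def in_voxels(self) -> dict[str, int]:
        """All dimensions as whole voxel counts (raises if not multiples)."""
        h = self.spacing
        v = {
            "nx": _as_voxels(self.block_width_x, h, "block_width_x"),
            "ny": _as_voxels(self.block_width_y, h, "block_width_y"),
            "block_height": _as_voxels(self.block_height, h, "block_height"),
            "cortical": _as_voxels(self.cortical_thickness, h, "cortical_thickness"),
            "core_radius": _as_voxels(self.core_radius, h, "core_radius"),
            "implant_length": _as_voxels(self.implant_length, h, "implant_length"),
            "abutment": _as_voxels(self.abutment_height, h, "abutment_height"),
            "pitch": _as_voxels(self.thread_pitch, h, "thread_pitch"),
            "thread_depth": _as_voxels(self.thread_depth, h, "thread_depth"),
            "thread_height": _as_voxels(self.thread_height, h, "thread_height"),
            "thread_offset": _as_voxels(self.thread_offset, h, "thread_offset"),
            "trough_depth": _as_voxels(self.trough_depth, h, "trough_depth"),
            "trough_height": _as_voxels(self.trough_height, h, "trough_height"),
            "roi_margin": _as_voxels(self.roi_margin, h, "roi_margin"),
        }
        v["nz"] = v["block_height"] + v["abutment"]
        return v

    def validate(self) -> dict[str, int]:
        v = self.in_voxels()
        if v["core_radius"] < 1:
            raise ValueError("core_radius must be at least one voxel")
        if v["trough_depth"] >= v["core_radius"]:
            raise ValueError(
                "trough deeper than the implant core allows "
                f"(trough_depth {v['trough_depth']} vx >= core_radius "
                f"{v['core_radius']} vx)"
            )
        if v["implant_length"] <= v["abutment"]:
            raise ValueError("implant_length must exceed abutment_height")
        if v["implant_length"] > v["nz"]:
            raise ValueError("implant longer than the model domain")
        if v["cortical"] >= v["block_height"]:
            raise ValueError("cortical_thickness must be below block_height")
        gap = v["pitch"] - v["thread_height"]
        if v["thread_height"] > 0 and v["trough_height"] > gap:
            raise ValueError(
                f"trough_height ({v['trough_height']} vx) exceeds the "
                f"inter-thread gap ({gap} vx)"
            )
        lateral = 2 * (v["core_radius"] + v["thread_depth"])
        if lateral >= min(v["nx"], v["ny"]):
            raise ValueError("implant (with threads) wider than the bone block")
        return v


def _thread_bands(v: dict[str, int]) -> list[tuple[int, int]]:
    """z index ranges [lo, hi) of the annular thread rings."""
    if v["thread_height"] == 0:
        return []
    tip = v["nz"] - v["implant_length"]
    crest = v["block_height"] - v["cortical"]
    bands = []
    lo = tip + v["thread_offset"]
    while lo + v["thread_height"] <= crest:
        bands.append((lo, lo + v["thread_height"]))
        lo += v["pitch"]
    return bands


def _trough_bands(v: dict[str, int]) -> list[tuple[int, int]]:
    """z index ranges [lo, hi) of the troughs, centered in inter-thread gaps."""
    th = v["trough_height"]
    if th == 0:
        return []
    rings = _thread_bands(v)
    bands = []
    for (lo0, hi0), (lo1, _hi1) in zip(rings, rings[1:]):
        gap = lo1 - hi0
        if th > gap:
            continue
        start = hi0 + (gap - th) // 2
        bands.append((start, start + th))
    return bands


def build_synthetic_model(
    params: ImplantModelParams,
    materials: Optional[dict[Phase, MaterialSpec]] = None,
) -> VoxelGrid:
    """Build the voxelized implant-in-bone model.

    Returns a :class:`VoxelGrid` whose troughs are marked ``design_mask``
    and initially filled with cancellous bone (the healing chamber starts
    fully occupied by bone), and whose ``roi_mask`` is a cylindrical shell
    of radius ``core_radius + thread_depth + roi_margin`` around the implant
    spanning the embedded portion, excluding implant voxels.

    ``materials`` is accepted for interface symmetry (phase coverage is
    checked at assembly time); geometry itself needs no elastic constants.
    """
    del materials  # elastic constants do not influence geometry
    v = params.validate()
    nx, ny, nz = v["nx"], v["ny"], v["nz"]

    # voxel-center coordinates in voxel units; axis through the grid center
    xi = np.arange(nx) + 0.5
    yi = np.arange(ny) + 0.5
    cx, cy = nx / 2.0, ny / 2.0
    r2 = (xi[:, None] - cx) ** 2 + (yi[None, :] - cy) ** 2  # (nx, ny)
    zc = np.arange(nz) + 0.5

    phase = np.full((nx, ny, nz), Phase.VOID, dtype=np.uint8)

    # bone block: cancellous body with a cortical crest layer on top
    in_block = zc < v["block_height"]
    in_cortical = in_block & (zc >= v["block_height"] - v["cortical"])
    phase[:, :, in_block] = Phase.CANCELLOUS
    phase[:, :, in_cortical] = Phase.CORTICAL

    # implant core (cylinder inserted from the top of the grid)
    tip = nz - v["implant_length"]
    in_core = r2 <= v["core_radius"] ** 2
    in_implant_z = zc >= tip
    core3d = in_core[:, :, None] & in_implant_z[None, None, :]
    phase[core3d] = Phase.IMPLANT

    # annular thread rings
    in_ring = r2 <= (v["core_radius"] + v["thread_depth"]) ** 2
    for lo, hi in _thread_bands(v):
        zmask = (zc >= lo) & (zc < hi)
        phase[in_ring[:, :, None] & zmask[None, None, :]] = Phase.IMPLANT

    # circumferential troughs: annular notches recessed into the core,
    # initially cancellous bone, forming the design region
    design = np.zeros_like(phase, dtype=bool)
    notch = (r2 <= v["core_radius"] ** 2) & (
        r2 > (v["core_radius"] - v["trough_depth"]) ** 2
    )
    for lo, hi in _trough_bands(v):
        zmask = (zc >= lo) & (zc < hi)
        band = notch[:, :, None] & zmask[None, None, :]
        phase[band] = Phase.CANCELLOUS
        design |= band

    # cylindrical evaluation ROI around the embedded implant
    roi_r = v["core_radius"] + v["thread_depth"] + v["roi_margin"]
    in_roi_r = r2 <= roi_r**2
    in_roi_z = (zc >= tip) & (zc < v["block_height"])
    roi = in_roi_r[:, :, None] & in_roi_z[None, None, :]
    roi &= phase != Phase.IMPLANT
    roi &= phase != Phase.VOID

    return VoxelGrid(
        phase=phase, spacing=params.spacing, design_mask=design, roi_mask=roi
    )
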