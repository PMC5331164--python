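"""Candidate evaluation: healthy-bone fraction, contact area, ranking.

Healthy bone is bone tissue at equivalent strains typical of normal
physical activity, 400–1500 microstrain (inclusive at both ends).  Each
candidate healing-chamber geometry is scored by the volume fraction of
healthy bone inside the cylindrical ROI around the implant, and by the
bone–implant contact (BIC) area — the total area of voxel faces shared
between a bone voxel and an implant voxel.  The best candidate maximizes
the healthy fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Literal, Union

import numpy as np

from .fem import FieldSolution
from .grid import Phase, VoxelGrid

if TYPE_CHECKING:  # pragma: no cover
    from .design import DesignCandidate, DesignHistory

__all__ = [
    "EvaluationParams",
    "healthy_fraction",
    "contact_area",
    "select_best",
]


@dataclass
class EvaluationParams:
    """Healthy-strain window (microstrain) and fraction denominator.

    ``denominator_mode='bone_in_roi'`` (default) divides the healthy-bone
    voxel count by all bone voxels in the ROI; ``'total_roi'`` divides by
    the full ROI voxel count.
    """

    healthy_low: float = 400.0
    healthy_high: float = 1500.0
    denominator_mode: Literal["bone_in_roi", "total_roi"] = "bone_in_roi"

    def __post_init__(self) -> None:
        if not (0.0 < self.healthy_low < self.healthy_high):
            raise ValueError("need 0 < healthy_low < healthy_high")
        if self.denominator_mode not in ("bone_in_roi", "total_roi"):
            raise ValueError(
                f"unknown denominator_mode {self.denominator_mode!r}"
            )


def _strain_field_microstrain(
    grid: VoxelGrid, solution: Union[FieldSolution, np.ndarray]
) -> np.ndarray:
    if isinstance(solution, FieldSolution):
        return solution.cell_field(solution.equivalent_strain_microstrain)
    field = np.asarray(solution, dtype=float)
    if field.shape != grid.shape:
        raise ValueError("strain field shape does not match the grid")
    return field


def healthy_fraction(
    grid: VoxelGrid,
    solution: Union[FieldSolution, np.ndarray],
    params: EvaluationParams = EvaluationParams(),
) -> float:
    """Volume fraction of healthy bone in the ROI.

    ``solution`` is either a :class:`FieldSolution` or a per-voxel 3D
    equivalent-strain field in microstrain.  Raises ``ValueError`` when
    the ROI contains no bone voxels.
    """
    eps = _strain_field_microstrain(grid, solution)
    roi_bone = grid.roi_mask & grid.bone_mask
    n_bone = int(roi_bone.sum())
    if n_bone == 0:
        raise ValueError("ROI contains no bone voxels")
    healthy = roi_bone & (eps >= params.healthy_low) & (eps <= params.healthy_high)
    if params.denominator_mode == "bone_in_roi":
        denom = n_bone
    else:
        denom = int(grid.roi_mask.sum())
    return float(healthy.sum()) / denom


def contact_area(grid: VoxelGrid) -> float:
    """Bone–implant contact area (m^2): shared faces x spacing^2."""
    bone = grid.bone_mask
    imp = grid.implant_mask
    n = 0
    for ax in range(3):
        b0 = _slab(bone, ax, "lo")
        b1 = _slab(bone, ax, "hi")
        i0 = _slab(imp, ax, "lo")
        i1 = _slab(imp, ax, "hi")
        n += int(np.count_nonzero(b0 & i1)) + int(np.count_nonzero(i0 & b1))
    return n * grid.spacing**2


def _slab(a: np.ndarray, ax: int, part: str) -> np.ndarray:
    sl = [slice(None)] * 3
    sl[ax] = slice(0, -1) if part == "lo" else slice(1, None)
    return a[tuple(sl)]


def select_best(history: "DesignHistory") -> "DesignCandidate":
    """Candidate with the maximal healthy fraction.

    Ties are broken by the earliest iteration, then by the larger contact
    area.  Raises ``ValueError`` on an empty history.
    """
    entries = list(history)
    if not entries:
        raise ValueError("empty design history")
    return min(
        entries,
        key=lambda c: (-c.healthy_fraction, c.iteration, -c.contact_area),
    )
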