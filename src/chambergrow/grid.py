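"""Voxel lattice container and material definitions.

The simulation domain is a regular 3D lattice of cubic voxels (default edge
50 µm, the scale of both trabecular bone packets and the powder used in
metal additive manufacturing).  Each voxel carries a phase label: void,
cancellous bone, cortical bone, or titanium implant.  Two boolean masks ride
along with the phases:

* ``design_mask`` — the healing-chamber design region (circumferential
  troughs between implant threads) where the design loop may swap bone and
  implant voxels; everything outside it is immutable.
* ``roi_mask`` — the cylindrical region of interest around the implant over
  which candidate designs are scored (healthy-bone volume fraction).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "Phase",
    "MaterialSpec",
    "VoxelGrid",
    "default_materials",
    "grids_equal",
]


class Phase(IntEnum):
    """Voxel phase labels."""

    VOID = 0
    CANCELLOUS = 1
    CORTICAL = 2
    IMPLANT = 3


#: Phases that count as bone tissue.
BONE_PHASES = (Phase.CANCELLOUS, Phase.CORTICAL)


@dataclass(frozen=True)
class MaterialSpec:
    """Isotropic linear-elastic constants for one phase.

    Parameters
    ----------
    phase_name:
        Human-readable label ("cortical bone", "Ti6Al4V", ...).
    young_modulus:
        Young's modulus in Pa; must be positive.
    poisson_ratio:
        Poisson ratio; must lie in [0, 0.5).
    """

    phase_name: str
    young_modulus: float
    poisson_ratio: float

    def __post_init__(self) -> None:
        if not self.young_modulus > 0:
            raise ValueError(
                f"young_modulus must be > 0, got {self.young_modulus!r}"
            )
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError(
                f"poisson_ratio must be in [0, 0.5), got {self.poisson_ratio!r}"
            )


def default_materials() -> dict[Phase, MaterialSpec]:
    """Elastic constants for type-IV posterior-jaw bone and Ti6Al4V.

    Cortical bone 13.7 GPa / 0.3, cancellous bone 0.69 GPa / 0.3,
    Ti6Al4V 110 GPa / 0.35.
    """
    return {
        Phase.CORTICAL: MaterialSpec("cortical bone", 13.7e9, 0.30),
        Phase.CANCELLOUS: MaterialSpec("cancellous bone", 0.69e9, 0.30),
        Phase.IMPLANT: MaterialSpec("Ti6Al4V", 110.0e9, 0.35),
    }


@dataclass
class VoxelGrid:
    """Regular voxel lattice with phase labels and design/ROI masks.

    Arrays are indexed ``[i, j, k]`` along x, y, z; z is the implant axis
    and the loading axis.  Voxel ``(i, j, k)`` spans the axis-aligned cube
    ``[i*h, (i+1)*h] x ... `` with ``h = spacing``.

    The linear element index used throughout (solver DOF ordering, the
    deterministic tie-break when the design loop picks an ADD target) is
    x-fastest: ``i + nx*j + nx*ny*k``.
    """

    phase: np.ndarray
    spacing: float = 50e-6
    design_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    roi_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.phase = np.ascontiguousarray(self.phase, dtype=np.uint8)
        if self.phase.ndim != 3:
            raise ValueError("phase must be a 3D array")
        if self.design_mask is None:
            self.design_mask = np.zeros(self.phase.shape, dtype=bool)
        if self.roi_mask is None:
            self.roi_mask = np.zeros(self.phase.shape, dtype=bool)
        self.design_mask = np.ascontiguousarray(self.design_mask, dtype=bool)
        self.roi_mask = np.ascontiguousarray(self.roi_mask, dtype=bool)
        if self.design_mask.shape != self.phase.shape:
            raise ValueError("design_mask shape mismatch")
        if self.roi_mask.shape != self.phase.shape:
            raise ValueError("roi_mask shape mismatch")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        self.validate()

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.phase.shape  # type: ignore[return-value]

    @property
    def bone_mask(self) -> np.ndarray:
        """Boolean mask of bone voxels (cancellous or cortical)."""
        return (self.phase == Phase.CANCELLOUS) | (self.phase == Phase.CORTICAL)

    @property
    def implant_mask(self) -> np.ndarray:
        return self.phase == Phase.IMPLANT

    @property
    def nonvoid_mask(self) -> np.ndarray:
        return self.phase != Phase.VOID

    def phase_counts(self) -> dict[Phase, int]:
        return {p: int(np.count_nonzero(self.phase == p)) for p in Phase}

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        bad = self.design_mask & ~(
            (self.phase == Phase.CANCELLOUS) | (self.phase == Phase.IMPLANT)
        )
        if bad.any():
            raise ValueError(
                "design_mask voxels must be cancellous bone or implant "
                f"({int(bad.sum())} offending voxels)"
            )

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(
            phase=self.phase.copy(),
            spacing=self.spacing,
            design_mask=self.design_mask.copy(),
            roi_mask=self.roi_mask.copy(),
        )


def grids_equal(a: VoxelGrid, b: VoxelGrid) -> bool:
    """Bit-for-bit equality of phases, masks, spacing and shape."""
    return (
        a.shape == b.shape
        and a.spacing == b.spacing
        and np.array_equal(a.phase, b.phase)
        and np.array_equal(a.design_mask, b.design_mask)
        and np.array_equal(a.roi_mask, b.roi_mask)
    )
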