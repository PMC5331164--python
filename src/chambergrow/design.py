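"""Iterative strain-driven design of the healing chamber.

The loop mimics post-implantation bone remodeling, with the twist that
resorbed bone is immediately back-filled by implant material (additive
manufacturing can realize any voxel geometry, and a larger bone–implant
contact area favors osseointegration):

1. solve linear elasticity on the current geometry;
2. for every design-region bone voxel in face contact with the implant,
   evaluate the signed remodeling probability f*(Gamma, eps) from the
   frozen solution and draw an action;
3. REMOVE turns that bone voxel into implant; ADD turns one face-adjacent
   design-region implant voxel back into bone.  Removals are applied
   before additions within a sweep, implant voxels freshly created by a
   removal are ineligible as ADD targets in the same sweep, and the sweep
   is repeated ``n_act`` times (activation frequency) on the frozen
   solution;
4. the updated geometry is solved and recorded as the next candidate with
   its healthy-bone fraction and contact area.

Because the bone inside a deep chamber is stress-shielded, the
uniformity-seeking rule inexorably fills the chamber with implant; the
final geometry is therefore not automatically the best one, and every
iteration is kept as a candidate for ranking by healthy-bone fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from . import fem
from .fem import BoundaryConditions, FieldSolution, StiffnessOperator
from .grid import MaterialSpec, Phase, VoxelGrid
from .metrics import EvaluationParams, contact_area, healthy_fraction
from .remodeling import (
    RemodelingParams,
    decide,
    nonuniformity_field,
    remodeling_probability,
)

__all__ = [
    "DesignCandidate",
    "DesignHistory",
    "interface_bone_elements",
    "apply_remodeling_step",
    "run_design",
]


def interface_bone_elements(grid: VoxelGrid) -> np.ndarray:
    """Mask of design-region bone voxels with a face-adjacent implant voxel.

    Face adjacency is 6-connectivity; diagonal contact does not count.
    """
    imp = grid.implant_mask
    near_imp = np.zeros(grid.shape, dtype=bool)
    for ax in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        near_imp[tuple(lo)] |= imp[tuple(hi)]
        near_imp[tuple(hi)] |= imp[tuple(lo)]
    return grid.design_mask & grid.bone_mask & near_imp


_FACE_OFFSETS = np.array(
    [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)],
    dtype=np.int64,
)


def _linear_index(grid: VoxelGrid, ijk: np.ndarray) -> np.ndarray:
    nx, ny, _ = grid.shape
    return ijk[:, 0] + nx * (ijk[:, 1] + ny * ijk[:, 2])


def apply_remodeling_step(
    grid: VoxelGrid,
    solution: FieldSolution,
    params: RemodelingParams,
    rng: Optional[np.random.Generator] = None,
) -> tuple[VoxelGrid, int]:
    """One remodeling step (``n_act`` decision sweeps) on a frozen solution.

    Returns the updated grid (a copy) and the number of voxel conversions.
    Only elements that were bone when ``solution`` was computed carry a
    stimulus; bone voxels created by an ADD within this step take no
    action until the next mechanical solve.
    """
    if solution.grid_shape != grid.shape:
        raise ValueError("solution does not match the grid shape")
    if rng is None:
        if params.seed is None and params.decision_mode == "stochastic":
            raise ValueError("stochastic mode needs an rng or a seed")
        rng = np.random.default_rng(params.seed)

    eps = solution.cell_field(solution.equivalent_strain_microstrain)
    sigma = solution.cell_field(solution.equivalent_stress)
    frozen_bone = grid.bone_mask  # stimulus support: bone at solve time
    gamma = nonuniformity_field(
        sigma, frozen_bone, grid.spacing, params.sensing_radius
    )

    out = grid.copy()
    nx, ny, nz = grid.shape
    changes = 0
    for _sweep in range(params.n_act):
        iface = interface_bone_elements(out) & frozen_bone
        idx = np.argwhere(iface)
        if len(idx) == 0:
            break
        # fixed deterministic element order: ascending linear index
        order = np.argsort(_linear_index(out, idx), kind="stable")
        idx = idx[order]
        ii, jj, kk = idx[:, 0], idx[:, 1], idx[:, 2]
        f_star = remodeling_probability(
            eps[ii, jj, kk], gamma[ii, jj, kk], params
        )
        actions = decide(f_star, rng=rng, mode=params.decision_mode)

        removed = actions == -1
        out.phase[ii[removed], jj[removed], kk[removed]] = Phase.IMPLANT
        created = np.zeros(grid.shape, dtype=bool)
        created[ii[removed], jj[removed], kk[removed]] = True
        changes += int(removed.sum())

        # additions: convert one eligible face-adjacent implant voxel each,
        # lowest linear index first; freshly created implant is off-limits
        for a in np.nonzero(actions == 1)[0]:
            nbrs = idx[a][None, :] + _FACE_OFFSETS
            ok = np.all((nbrs >= 0) & (nbrs < [nx, ny, nz]), axis=1)
            nbrs = nbrs[ok]
            bi, bj, bk = nbrs[:, 0], nbrs[:, 1], nbrs[:, 2]
            eligible = (
                (out.phase[bi, bj, bk] == Phase.IMPLANT)
                & out.design_mask[bi, bj, bk]
                & ~created[bi, bj, bk]
            )
            if not eligible.any():
                continue
            cand = nbrs[eligible]
            best = cand[np.argmin(_linear_index(out, cand))]
            out.phase[tuple(best)] = Phase.CANCELLOUS
            changes += 1
    return out, changes


@dataclass(frozen=True)
class DesignCandidate:
    """One snapshot of the design loop with its evaluation metrics."""

    iteration: int
    grid: VoxelGrid
    healthy_fraction: float
    contact_area: float  # m^2
    changes: int  # voxel conversions producing this candidate (0 for initial)
    strain_field: np.ndarray  # per-voxel equivalent strain, microstrain

    @property
    def contact_area_mm2(self) -> float:
        return self.contact_area * 1e6


@dataclass
class DesignHistory:
    """Ordered candidate snapshots, iteration 0 being the initial design."""

    candidates: list[DesignCandidate] = field(default_factory=list)
    converged: bool = False

    def __iter__(self) -> Iterator[DesignCandidate]:
        return iter(self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)

    def __getitem__(self, i: int) -> DesignCandidate:
        return self.candidates[i]


class DesignLoopError(RuntimeError):
    """FE failure wrapped with the iteration at which it occurred."""


def _solve_candidate(
    grid: VoxelGrid,
    materials: dict[Phase, MaterialSpec],
    bc_force: float,
    rtol: float,
    x0: Optional[np.ndarray],
    iteration: int,
) -> tuple[FieldSolution, np.ndarray]:
    try:
        op = fem.assemble_stiffness(grid, materials)
        bc = fem.axial_compression_bc(op, bc_force)
        u = fem.solve_elasticity(op, bc, rtol=rtol, x0=x0)
        sol = fem.compute_strains(grid, op, u, materials)
    except (ValueError, fem.SolverError) as exc:
        raise DesignLoopError(f"FE solve failed at iteration {iteration}: {exc}") from exc
    return sol, u


def run_design(
    grid: VoxelGrid,
    materials: dict[Phase, MaterialSpec],
    total_force: float,
    params: RemodelingParams,
    eval_params: EvaluationParams = EvaluationParams(),
    max_iter: int = 12,
    rtol: float = 1e-9,
    rng: Optional[np.random.Generator] = None,
    verbose: bool = False,
) -> DesignHistory:
    """Run the design loop; return the candidate history.

    Stops at ``max_iter`` remodeling steps, when a step makes no change,
    or when the design region is entirely implant.  With ``max_iter=0``
    only the initial design is evaluated.  Identical inputs and seed give
    a bit-identical history.
    """
    if max_iter < 0:
        raise ValueError("max_iter must be >= 0")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    history = DesignHistory()
    g = grid.copy()
    sol, u = _solve_candidate(g, materials, total_force, rtol, None, 0)
    _record(history, 0, g, sol, 0, eval_params, verbose)

    for it in range(1, max_iter + 1):
        g_next, n_changes = apply_remodeling_step(g, sol, params, rng=rng)
        if n_changes == 0:
            history.converged = True
            break
        g = g_next
        sol, u = _solve_candidate(g, materials, total_force, rtol, u, it)
        _record(history, it, g, sol, n_changes, eval_params, verbose)
        design_bone = g.design_mask & g.bone_mask
        if not design_bone.any():
            history.converged = True
            break
    return history


def _record(
    history: DesignHistory,
    iteration: int,
    grid: VoxelGrid,
    sol: FieldSolution,
    changes: int,
    eval_params: EvaluationParams,
    verbose: bool,
) -> None:
    eps_field = sol.cell_field(sol.equivalent_strain_microstrain)
    cand = DesignCandidate(
        iteration=iteration,
        grid=grid.copy(),
        healthy_fraction=healthy_fraction(grid, eps_field, eval_params),
        contact_area=contact_area(grid),
        changes=changes,
        strain_field=eps_field.astype(np.float32),
    )
    history.candidates.append(cand)
    if verbose:
        print(
            f"iter {iteration:3d}  changes {changes:5d}  "
            f"healthy {cand.healthy_fraction:.4f}  "
            f"BIC {cand.contact_area_mm2:.4f} mm^2"
        )
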