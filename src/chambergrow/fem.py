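"""Linear elasticity on the voxel lattice with 8-node trilinear hexahedra.

Every non-void voxel is one cubic element with full 2x2x2 Gauss
integration.  Bone and implant elements share nodes on the conformal voxel
mesh, which realizes a bonded (perfectly osseointegrated) interface exactly
— no contact pairs, no interface stiffness.  Because all elements are
identical cubes, each phase contributes a single precomputed 24x24 element
stiffness scaled into a global sparse matrix.

Solution strategy: sparse Cholesky-free direct factorization (SuperLU)
below a DOF threshold, Jacobi-preconditioned conjugate gradients above it
(relative residual 1e-9 by default), with optional warm starting — the
design loop changes only a thin shell of elements between iterations, so
the previous displacement field is an excellent initial guess.

Strains are evaluated once at the element centroid.  For trilinear cubes
the centroid strain equals the average over the Gauss points for any
linear displacement field, and it is the conventional single reporting
point for voxel models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import MaterialSpec, Phase, VoxelGrid

__all__ = [
    "BoundaryConditions",
    "FieldSolution",
    "StiffnessOperator",
    "element_stiffness",
    "assemble_stiffness",
    "solve_elasticity",
    "compute_strains",
    "axial_compression_bc",
]

# local node offsets (dx, dy, dz); node a of element (i, j, k) sits at
# lattice node (i+dx, j+dy, k+dz).  Natural coordinates are xi = 2*dx - 1.
_NODE_OFFSETS = np.array(
    [
        (0, 0, 0),
        (1, 0, 0),
        (0, 1, 0),
        (1, 1, 0),
        (0, 0, 1),
        (1, 0, 1),
        (0, 1, 1),
        (1, 1, 1),
    ],
    dtype=np.int64,
)
_XI = 2.0 * _NODE_OFFSETS - 1.0  # (8, 3) corner signs


def elastic_matrix(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix, Voigt order (xx, yy, zz, xy, yz, zx)
    with engineering shear strains."""
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.diag_indices(3)] = lam + 2.0 * mu
    C[3, 3] = C[4, 4] = C[5, 5] = mu
    return C


def _shape_gradients(xi: np.ndarray, h: float) -> np.ndarray:
    """dN/dx (8, 3) of the trilinear shape functions at natural point xi,
    for a cube of edge h (Jacobian is diag(h/2))."""
    g = np.empty((8, 3))
    for a in range(8):
        sa = _XI[a]
        g[a, 0] = sa[0] * (1 + sa[1] * xi[1]) * (1 + sa[2] * xi[2]) / 8.0
        g[a, 1] = (1 + sa[0] * xi[0]) * sa[1] * (1 + sa[2] * xi[2]) / 8.0
        g[a, 2] = (1 + sa[0] * xi[0]) * (1 + sa[1] * xi[1]) * sa[2] / 8.0
    return g * (2.0 / h)


def _b_matrix(dndx: np.ndarray) -> np.ndarray:
    """6x24 strain-displacement matrix from shape gradients (8, 3)."""
    B = np.zeros((6, 24))
    for a in range(8):
        bx, by, bz = dndx[a]
        c = 3 * a
        B[0, c] = bx
        B[1, c + 1] = by
        B[2, c + 2] = bz
        B[3, c] = by
        B[3, c + 1] = bx
        B[4, c + 1] = bz
        B[4, c + 2] = by
        B[5, c] = bz
        B[5, c + 2] = bx
    return B


def element_stiffness(E: float, nu: float, h: float) -> np.ndarray:
    """24x24 stiffness of a cubic trilinear hexahedron, 2x2x2 Gauss."""
    C = elastic_matrix(E, nu)
    g = 1.0 / np.sqrt(3.0)
    detJ = (h / 2.0) ** 3
    ke = np.zeros((24, 24))
    for sx in (-g, g):
        for sy in (-g, g):
            for sz in (-g, g):
                B = _b_matrix(_shape_gradients(np.array([sx, sy, sz]), h))
                ke += B.T @ C @ B * detJ
    return 0.5 * (ke + ke.T)


def centroid_b_matrix(h: float) -> np.ndarray:
    """6x24 strain-displacement matrix at the element centroid."""
    return _b_matrix(_shape_gradients(np.zeros(3), h))


# ----------------------------------------------------------------------
# mesh bookkeeping


@dataclass
class StiffnessOperator:
    """Assembled global stiffness with the active-node bookkeeping.

    ``K`` is symmetric positive-semidefinite over 3 DOFs per active node
    (nodes attached to at least one non-void element); DOF ``3*n + ax`` is
    axis ``ax`` of active node ``n``.
    """

    K: sp.csr_matrix
    grid: VoxelGrid
    element_ids: np.ndarray  # linear indices (x-fastest) of non-void voxels
    conn: np.ndarray  # (n_elem, 8) active-node indices
    active_nodes: np.ndarray  # sorted global lattice-node ids
    node_map: np.ndarray  # global node id -> active index (-1 if inactive)

    @property
    def n_dof(self) -> int:
        return 3 * len(self.active_nodes)

    def node_coords(self) -> np.ndarray:
        """(n_active, 3) lattice coordinates (in voxel units) of active nodes."""
        nx, ny, _ = self.grid.shape
        g = self.active_nodes
        k, rem = np.divmod(g, (nx + 1) * (ny + 1))
        j, i = np.divmod(rem, nx + 1)
        return np.stack([i, j, k], axis=1)


def _connectivity(grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray]:
    """(element linear ids, global node connectivity) for non-void voxels."""
    nx, ny, nz = grid.shape
    nonvoid = grid.nonvoid_mask
    ii, jj, kk = np.nonzero(nonvoid)
    elem_ids = ii + nx * (jj + ny * kk)
    order = np.argsort(elem_ids, kind="stable")
    ii, jj, kk = ii[order], jj[order], kk[order]
    elem_ids = elem_ids[order]
    nnx, nny = nx + 1, ny + 1
    conn = np.empty((len(ii), 8), dtype=np.int64)
    for a, (dx, dy, dz) in enumerate(_NODE_OFFSETS):
        conn[:, a] = (ii + dx) + nnx * ((jj + dy) + nny * (kk + dz))
    return elem_ids, conn


def assemble_stiffness(
    grid: VoxelGrid, materials: dict[Phase, MaterialSpec]
) -> StiffnessOperator:
    """Assemble the global sparse stiffness matrix of all non-void voxels.

    Raises ``ValueError`` if a present non-void phase has no material, or
    if the grid is entirely void.
    """
    present = {Phase(p) for p in np.unique(grid.phase) if p != Phase.VOID}
    if not present:
        raise ValueError("grid contains no non-void voxels")
    missing = [p.name for p in present if p not in materials]
    if missing:
        raise ValueError(f"missing material for phase(s): {', '.join(missing)}")

    elem_ids, conn_global = _connectivity(grid)
    active_nodes = np.unique(conn_global)
    node_map = np.full((grid.shape[0] + 1) * (grid.shape[1] + 1)
                       * (grid.shape[2] + 1), -1, dtype=np.int64)
    node_map[active_nodes] = np.arange(len(active_nodes))
    conn = node_map[conn_global]

    h = grid.spacing
    ke_by_phase = {
        p: element_stiffness(materials[p].young_modulus,
                             materials[p].poisson_ratio, h)
        for p in present
    }

    phase_flat = grid.phase[grid.nonvoid_mask]
    # phase label per row of conn (same ordering as elem_ids)
    nx, ny, nz = grid.shape
    kkk, rem = np.divmod(elem_ids, nx * ny)
    jjj, iii = np.divmod(rem, nx)
    phase_per_elem = grid.phase[iii, jjj, kkk]

    n_dof = 3 * len(active_nodes)
    edof = (
        3 * conn[:, :, None] + np.arange(3)[None, None, :]
    ).reshape(-1, 24).astype(np.int32)

    # one COO pass: per-element 24x24 blocks gathered from the per-phase
    # element stiffness, summed into CSR in a single conversion
    ke_lookup = np.zeros((4, 576))
    for p in present:
        ke_lookup[int(p)] = ke_by_phase[p].ravel()
    data = ke_lookup[phase_per_elem.astype(np.int64)].ravel()
    rows = np.repeat(edof, 24, axis=1).ravel()
    cols = np.tile(edof, (1, 24)).ravel()
    K = sp.coo_matrix((data, (rows, cols)), shape=(n_dof, n_dof)).tocsr()
    K.sum_duplicates()

    return StiffnessOperator(
        K=K,
        grid=grid,
        element_ids=elem_ids,
        conn=conn,
        active_nodes=active_nodes,
        node_map=node_map,
    )


# ----------------------------------------------------------------------
# boundary conditions


@dataclass
class BoundaryConditions:
    """Dirichlet constraints plus a total force spread over loaded nodes.

    ``fixed`` is a list of ``(global_node_ids, axes, values)`` triples:
    the listed displacement components are prescribed (``values`` may be a
    scalar, usually 0, or an array broadcastable to ``(n_nodes, n_axes)``).
    The applied force is ``total_load`` (a 3-vector, N) distributed over
    ``load_nodes`` with ``load_weights`` (normalized internally).
    """

    fixed: list[tuple[np.ndarray, tuple[int, ...], np.ndarray | float]]
    load_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    load_weights: Optional[np.ndarray] = None
    total_load: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.total_load = np.asarray(self.total_load, dtype=float)
        if self.total_load.shape != (3,):
            raise ValueError("total_load must be a 3-vector")
        if not self.fixed or all(len(f[0]) == 0 for f in self.fixed):
            raise ValueError("at least one fixed node set is required")


def _boundary_plane_nodes(
    op: StiffnessOperator, axis: int, side: Literal["low", "high"]
) -> np.ndarray:
    coords = op.node_coords()
    extent = op.grid.shape[axis]
    target = 0 if side == "low" else extent
    sel = coords[:, axis] == target
    return op.active_nodes[sel]


def axial_compression_bc(
    op: StiffnessOperator,
    total_force: float,
    load_distribution: Literal["uniform", "consistent"] = "uniform",
) -> BoundaryConditions:
    """Standard implant load case: mesial/distal (+/- y) bone faces fully
    constrained, a compressive axial force on the implant top face.

    ``load_distribution='uniform'`` divides the force evenly over the
    loaded nodes; ``'consistent'`` weights nodes by attached loaded-face
    area (the consistent nodal loads of a constant pressure on bilinear
    faces), which reproduces a uniform traction exactly.
    """
    grid = op.grid
    nx, ny, nz = grid.shape
    fixed_nodes = np.union1d(
        _boundary_plane_nodes(op, 1, "low"), _boundary_plane_nodes(op, 1, "high")
    )
    if len(fixed_nodes) == 0:
        raise ValueError("no active nodes on the mesial/distal faces")

    # implant voxels whose top face is on the top of the grid
    top = grid.phase[:, :, nz - 1] == Phase.IMPLANT
    if not top.any():
        raise ValueError("no implant voxels reach the top of the grid")
    ii, jj = np.nonzero(top)
    nnx, nny = nx + 1, ny + 1
    face_nodes = np.concatenate(
        [
            (ii + dx) + nnx * ((jj + dy) + nny * nz)
            for dx in (0, 1)
            for dy in (0, 1)
        ]
    )
    if load_distribution == "uniform":
        load_nodes = np.unique(face_nodes)
        weights = np.full(len(load_nodes), 1.0 / len(load_nodes))
    else:
        load_nodes, counts = np.unique(face_nodes, return_counts=True)
        weights = counts / counts.sum()
    return BoundaryConditions(
        fixed=[(fixed_nodes, (0, 1, 2), 0.0)],
        load_nodes=load_nodes,
        load_weights=weights,
        total_load=np.array([0.0, 0.0, -abs(total_force)]),
    )


# ----------------------------------------------------------------------
# solve


def _constraint_arrays(
    op: StiffnessOperator, bc: BoundaryConditions
) -> tuple[np.ndarray, np.ndarray]:
    """(fixed_dof_indices, prescribed_values) in active-DOF numbering."""
    dofs: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for nodes, axes, values in bc.fixed:
        nodes = np.asarray(nodes, dtype=np.int64)
        act = op.node_map[nodes]
        if (act < 0).any():
            raise ValueError("fixed node set references inactive (void) nodes")
        axes = tuple(axes)
        vv = np.broadcast_to(np.asarray(values, dtype=float),
                             (len(nodes), len(axes)))
        for m, ax in enumerate(axes):
            dofs.append(3 * act + ax)
            vals.append(vv[:, m])
    d = np.concatenate(dofs)
    v = np.concatenate(vals)
    # later entries win on duplicates
    order = np.arange(len(d))
    uniq, first = np.unique(d[::-1], return_index=True)
    v = v[::-1][first]
    return uniq, v


def load_vector(op: StiffnessOperator, bc: BoundaryConditions) -> np.ndarray:
    f = np.zeros(op.n_dof)
    if len(bc.load_nodes) == 0:
        return f
    act = op.node_map[np.asarray(bc.load_nodes, dtype=np.int64)]
    if (act < 0).any():
        raise ValueError("load node set references inactive (void) nodes")
    w = bc.load_weights
    if w is None:
        w = np.full(len(act), 1.0 / len(act))
    w = np.asarray(w, dtype=float)
    w = w / w.sum()
    for ax in range(3):
        np.add.at(f, 3 * act + ax, w * bc.total_load[ax])
    return f


class SolverError(RuntimeError):
    pass


def solve_elasticity(
    op: StiffnessOperator,
    bc: BoundaryConditions,
    rtol: float = 1e-9,
    method: Literal["auto", "direct", "cg"] = "auto",
    x0: Optional[np.ndarray] = None,
    direct_dof_limit: int = 6_000,
    maxiter: int = 50_000,
) -> np.ndarray:
    """Solve the constrained equilibrium problem; return (n_active, 3)
    nodal displacements (m).

    Raises :class:`SolverError` on singular systems (under-constrained /
    disconnected loaded components) or non-convergence.
    """
    fixed_dofs, fixed_vals = _constraint_arrays(op, bc)
    f = load_vector(op, bc)

    n = op.n_dof
    free = np.ones(n, dtype=bool)
    free[fixed_dofs] = False
    u = np.zeros(n)
    u[fixed_dofs] = fixed_vals

    K = op.K
    rhs = f[free]
    if np.any(fixed_vals != 0.0):
        rhs = rhs - K[free][:, fixed_dofs] @ fixed_vals
    Kff = K[free][:, free].tocsc()

    nfree = int(free.sum())
    if nfree == 0:
        return u.reshape(-1, 3)
    bnorm = np.linalg.norm(rhs)
    if bnorm == 0.0:
        return u.reshape(-1, 3)

    if method == "direct" or (method == "auto" and nfree <= direct_dof_limit):
        try:
            lu = spla.splu(Kff, permc_spec="MMD_AT_PLUS_A",
                           options={"SymmetricMode": True})
        except RuntimeError as exc:  # singular factorization
            raise SolverError(f"direct factorization failed: {exc}") from exc
        uf = lu.solve(rhs)
        if not np.all(np.isfinite(uf)):
            raise SolverError("singular system: non-finite direct solution")
    else:
        diag = Kff.diagonal()
        if np.any(diag <= 0):
            raise SolverError("non-positive diagonal: system is singular "
                              "(free DOFs not attached to stiffness)")
        M = sp.diags(1.0 / diag)
        x0f = None
        if x0 is not None:
            x0f = np.asarray(x0, dtype=float).reshape(-1)[free]
        uf, info = spla.cg(Kff, rhs, x0=x0f, M=M, rtol=rtol, atol=0.0,
                           maxiter=maxiter)
        if info != 0:
            raise SolverError(f"CG failed to converge (info={info})")
    resid = np.linalg.norm(Kff @ uf - rhs) / bnorm
    if not resid < max(1e-6, 10 * rtol):
        raise SolverError(f"equilibrium residual too large: {resid:.3e}")
    u[free] = uf
    return u.reshape(-1, 3)


# ----------------------------------------------------------------------
# post-processing


@dataclass
class FieldSolution:
    """Per-node displacements and per-element strain/stress measures.

    Element arrays are aligned with ``element_ids`` (linear x-fastest
    indices of the non-void voxels).  ``equivalent_strain`` is the von
    Mises-type strain invariant

        eps_eq = 1/(1+nu') * sqrt(((e1-e2)^2 + (e2-e3)^2 + (e3-e1)^2) / 2)

    with principal strains e_i and nu' the element's material Poisson
    ratio (or 0.5, the incompressible convention, if requested);
    ``equivalent_stress`` is the von Mises stress.
    """

    displacement: np.ndarray  # (n_active_nodes, 3), m
    element_ids: np.ndarray  # linear indices of non-void voxels
    strain_tensor: np.ndarray  # (n_elem, 6) Voigt, engineering shear
    equivalent_strain: np.ndarray  # (n_elem,), dimensionless
    equivalent_stress: np.ndarray  # (n_elem,), Pa
    grid_shape: tuple[int, int, int]

    @property
    def equivalent_strain_microstrain(self) -> np.ndarray:
        return self.equivalent_strain * 1e6

    def cell_field(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-element array onto the full 3D grid."""
        nx, ny, nz = self.grid_shape
        out = np.full(nx * ny * nz, fill, dtype=float)
        out[self.element_ids] = values
        return out.reshape((nz, ny, nx)).transpose(2, 1, 0)


def compute_strains(
    grid: VoxelGrid,
    op: StiffnessOperator,
    displacement: np.ndarray,
    materials: dict[Phase, MaterialSpec],
    nu_prime: Literal["material", "incompressible"] = "material",
) -> FieldSolution:
    """Element-centroid small strains, equivalent strain and von Mises
    stress from a solved displacement field."""
    h = grid.spacing
    B0 = centroid_b_matrix(h)  # (6, 24)
    u_e = displacement.reshape(-1)[
        (3 * op.conn[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)
    ]
    strain = u_e @ B0.T  # (n_elem, 6)

    nx, ny, _ = grid.shape
    kkk, rem = np.divmod(op.element_ids, nx * ny)
    jjj, iii = np.divmod(rem, nx)
    phase_per_elem = grid.phase[iii, jjj, kkk]

    # principal strains from the symmetric tensor (engineering -> tensor shear)
    T = np.zeros((strain.shape[0], 3, 3))
    T[:, 0, 0] = strain[:, 0]
    T[:, 1, 1] = strain[:, 1]
    T[:, 2, 2] = strain[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = 0.5 * strain[:, 3]
    T[:, 1, 2] = T[:, 2, 1] = 0.5 * strain[:, 4]
    T[:, 0, 2] = T[:, 2, 0] = 0.5 * strain[:, 5]
    principal = np.linalg.eigvalsh(T)  # ascending, (n_elem, 3)
    e1, e2, e3 = principal[:, 2], principal[:, 1], principal[:, 0]
    dev = np.sqrt(
        ((e1 - e2) ** 2 + (e2 - e3) ** 2 + (e3 - e1) ** 2) / 2.0
    )

    nu_e = np.empty(strain.shape[0])
    sigma = np.empty_like(strain)
    for p in {Phase(v) for v in np.unique(phase_per_elem)}:
        sel = phase_per_elem == p
        mat = materials[p]
        nu_e[sel] = mat.poisson_ratio
        sigma[sel] = strain[sel] @ elastic_matrix(
            mat.young_modulus, mat.poisson_ratio
        ).T
    if nu_prime == "incompressible":
        nu_e[:] = 0.5
    eps_eq = dev / (1.0 + nu_e)

    s = sigma
    svm = np.sqrt(
        0.5
        * (
            (s[:, 0] - s[:, 1]) ** 2
            + (s[:, 1] - s[:, 2]) ** 2
            + (s[:, 2] - s[:, 0]) ** 2
            + 6.0 * (s[:, 3] ** 2 + s[:, 4] ** 2 + s[:, 5] ** 2)
        )
    )
    return FieldSolution(
        displacement=displacement,
        element_ids=op.element_ids,
        strain_tensor=strain,
        equivalent_strain=eps_eq,
        equivalent_stress=svm,
        grid_shape=grid.shape,
    )
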