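"""Voxel FE: element oracle, analytic solutions, dense-solve equivalence.

The independent oracles here share no code with the implementation: the
element stiffness is re-derived with 3x3x3 Gauss quadrature and
finite-difference shape-function gradients, and the reference solver
assembles a dense matrix element by element in plain Python loops.
"""

from __future__ import annotations

import numpy as np
import pytest
import scipy.linalg

from chambergrow import (
    BoundaryConditions,
    MaterialSpec,
    Phase,
    VoxelGrid,
    assemble_stiffness,
    compute_strains,
    solve_elasticity,
)
from chambergrow.fem import _NODE_OFFSETS, SolverError, load_vector

# ----------------------------------------------------------------------
# independent single-element oracle


def _shape_value(a: int, xi: np.ndarray) -> float:
    s = 2.0 * _NODE_OFFSETS[a] - 1.0
    return float(np.prod(1.0 + s * xi) / 8.0)


def oracle_element_stiffness(E: float, nu: float, h: float) -> np.ndarray:
    """Dense hex8 stiffness via 3-point Gauss and FD shape gradients."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.array(
        [
            [lam + 2 * mu, lam, lam, 0, 0, 0],
            [lam, lam + 2 * mu, lam, 0, 0, 0],
            [lam, lam, lam + 2 * mu, 0, 0, 0],
            [0, 0, 0, mu, 0, 0],
            [0, 0, 0, 0, mu, 0],
            [0, 0, 0, 0, 0, mu],
        ]
    )
    gp = np.array([-np.sqrt(3.0 / 5.0), 0.0, np.sqrt(3.0 / 5.0)])
    gw = np.array([5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0])
    delta = 1e-6
    ke = np.zeros((24, 24))
    for ix, wx in zip(gp, gw):
        for iy, wy in zip(gp, gw):
            for iz, wz in zip(gp, gw):
                xi = np.array([ix, iy, iz])
                dndx = np.zeros((8, 3))
                for a in range(8):
                    for d in range(3):
                        xp, xm = xi.copy(), xi.copy()
                        xp[d] += delta
                        xm[d] -= delta
                        # d/dx = d/dxi * 2/h on a cube of edge h
                        dndx[a, d] = (
                            (_shape_value(a, xp) - _shape_value(a, xm))
                            / (2 * delta)
                            * 2.0
                            / h
                        )
                B = np.zeros((6, 24))
                for a in range(8):
                    bx, by, bz = dndx[a]
                    B[0, 3 * a] = bx
                    B[1, 3 * a + 1] = by
                    B[2, 3 * a + 2] = bz
                    B[3, 3 * a] = by
                    B[3, 3 * a + 1] = bx
                    B[4, 3 * a + 1] = bz
                    B[4, 3 * a + 2] = by
                    B[5, 3 * a] = bz
                    B[5, 3 * a + 2] = bx
                ke += wx * wy * wz * (h / 2.0) ** 3 * (B.T @ C @ B)
    return ke


def single_voxel_grid(phase=Phase.CANCELLOUS, h=50e-6) -> VoxelGrid:
    return VoxelGrid(phase=np.full((1, 1, 1), phase, dtype=np.uint8), spacing=h)


def test_single_element_stiffness_matches_quadrature_oracle(materials):
    """The assembled one-voxel matrix equals an independently integrated
    hex8 stiffness (3x3x3 Gauss, FD gradients)."""
    for phase in (Phase.CANCELLOUS, Phase.IMPLANT):
        grid = single_voxel_grid(phase)
        op = assemble_stiffness(grid, materials)
        mat = materials[phase]
        ke_ref = oracle_element_stiffness(
            mat.young_modulus, mat.poisson_ratio, grid.spacing
        )
        K = op.K.toarray()
        assert np.allclose(K, ke_ref, rtol=1e-7, atol=1e-7 * np.abs(ke_ref).max())


def test_stiffness_is_symmetric(small_grid, materials):
    K = assemble_stiffness(small_grid, materials).K
    # symmetric to round-off (summation order differs across the diagonal)
    assert abs(K - K.T).max() <= 1e-12 * abs(K).max()


def test_floating_body_has_six_rigid_modes(materials):
    """An unconstrained connected block has exactly 6 zero-energy modes."""
    grid = VoxelGrid(
        phase=np.full((2, 2, 2), Phase.CANCELLOUS, dtype=np.uint8)
    )
    K = assemble_stiffness(grid, materials).K.toarray()
    w = scipy.linalg.eigvalsh(K)
    scale = w[-1]
    assert np.all(np.abs(w[:6]) < 1e-9 * scale)
    assert w[6] > 1e-6 * scale


def test_missing_material_raises(small_grid):
    with pytest.raises(ValueError, match="missing material"):
        assemble_stiffness(small_grid, {})


# ----------------------------------------------------------------------
# block helpers


def block_grid(n=(4, 4, 4), phase=Phase.CANCELLOUS, h=50e-6) -> VoxelGrid:
    return VoxelGrid(phase=np.full(n, phase, dtype=np.uint8), spacing=h)


def plane_nodes(op, axis, value):
    coords = op.node_coords()
    return op.active_nodes[coords[:, axis] == value]


def uniaxial_bc(op, grid, pressure):
    """Frictionless uniaxial compression: bottom fixed in z, consistent
    (face-area-weighted) pressure load on the top face, rigid lateral
    motion pinned at two bottom corner nodes."""
    nx, ny, nz = grid.shape
    bottom = plane_nodes(op, 2, 0)
    top = plane_nodes(op, 2, nz)
    coords = op.node_coords()
    origin = op.active_nodes[np.all(coords == 0, axis=1)]
    xcorner = op.active_nodes[
        (coords[:, 0] == nx) & (coords[:, 1] == 0) & (coords[:, 2] == 0)
    ]
    # consistent weights: interior nodes touch 4 loaded faces, edges 2, corners 1
    tc = coords[np.isin(op.active_nodes, top)]
    w = np.ones(len(top))
    for ax, n in ((0, nx), (1, ny)):
        w *= np.where((tc[:, ax] == 0) | (tc[:, ax] == n), 1.0, 2.0)
    area = nx * ny * grid.spacing**2
    return BoundaryConditions(
        fixed=[
            (bottom, (2,), 0.0),
            (origin, (0, 1), 0.0),
            (xcorner, (1,), 0.0),
        ],
        load_nodes=top,
        load_weights=w / w.sum(),
        total_load=np.array([0.0, 0.0, -pressure * area]),
    )


def test_zero_load_gives_zero_displacement(small_grid, materials):
    op = assemble_stiffness(small_grid, materials)
    bc = BoundaryConditions(
        fixed=[(plane_nodes(op, 2, 0), (0, 1, 2), 0.0)],
        total_load=np.zeros(3),
    )
    u = solve_elasticity(op, bc)
    assert np.all(u == 0.0)


def test_uniaxial_block_matches_hookes_law(materials):
    """sigma*L/E end shortening and eps_eq = sigma/E on a uniform block."""
    grid = block_grid((5, 5, 6))
    op = assemble_stiffness(grid, materials)
    sigma = 1e6  # 1 MPa
    bc = uniaxial_bc(op, grid, sigma)
    u = solve_elasticity(op, bc)
    E = materials[Phase.CANCELLOUS].young_modulus
    L = grid.shape[2] * grid.spacing
    top = np.isin(op.active_nodes, plane_nodes(op, 2, grid.shape[2]))
    mean_uz = u[top, 2].mean()
    assert mean_uz == pytest.approx(-sigma * L / E, rel=1e-6)

    sol = compute_strains(grid, op, u, materials)
    # the (1 + nu) factors cancel: eps_eq = sigma / E for uniaxial stress
    np.testing.assert_allclose(
        sol.equivalent_strain, sigma / E, rtol=1e-6
    )
    # 1 MPa on cancellous bone (0.69 GPa) is ~1449 microstrain
    assert sol.equivalent_strain_microstrain[0] == pytest.approx(1449.3, abs=0.5)


def test_patch_test_reproduces_linear_field_exactly(materials):
    """Boundary-imposed linear displacement gives constant strain to
    round-off and is reproduced at interior nodes."""
    grid = block_grid((3, 3, 3))
    op = assemble_stiffness(grid, materials)
    A = np.array([[2e-4, 1e-4, 0.0], [1e-4, -1e-4, 5e-5], [0.0, 5e-5, 3e-4]])
    b = np.array([1e-6, -2e-6, 0.5e-6])
    coords = op.node_coords() * grid.spacing
    u_exact = coords @ A.T + b
    boundary = np.any((op.node_coords() == 0) | (op.node_coords() == 3), axis=1)
    bc = BoundaryConditions(
        fixed=[(op.active_nodes[boundary], (0, 1, 2), u_exact[boundary])],
        total_load=np.zeros(3),
    )
    u = solve_elasticity(op, bc)
    np.testing.assert_allclose(u, u_exact, atol=1e-12 * np.abs(u_exact).max())
    sol = compute_strains(grid, op, u, materials)
    sym = 0.5 * (A + A.T)
    expected = np.array(
        [sym[0, 0], sym[1, 1], sym[2, 2], 2 * sym[0, 1], 2 * sym[1, 2], 2 * sym[0, 2]]
    )
    np.testing.assert_allclose(
        sol.strain_tensor, np.tile(expected, (sol.strain_tensor.shape[0], 1)),
        atol=1e-10 * np.abs(expected).max(),
    )


def dense_reference_solution(grid, materials, bc, op):
    """Dense assembly (python loops over elements) + numpy solve."""
    ke_cache = {
        p: oracle_element_stiffness(
            materials[p].young_modulus, materials[p].poisson_ratio, grid.spacing
        )
        for p in (Phase.CANCELLOUS, Phase.CORTICAL, Phase.IMPLANT)
    }
    n = op.n_dof
    K = np.zeros((n, n))
    nx, ny, nz = grid.shape
    for e in range(op.conn.shape[0]):
        lin = op.element_ids[e]
        k, rem = divmod(lin, nx * ny)
        j, i = divmod(rem, nx)
        ke = ke_cache[Phase(grid.phase[i, j, k])]
        dofs = (3 * op.conn[e][:, None] + np.arange(3)).ravel()
        K[np.ix_(dofs, dofs)] += ke
    f = load_vector(op, bc)
    fixed = []
    vals = []
    for nodes, axes, values in bc.fixed:
        act = op.node_map[nodes]
        vv = np.broadcast_to(np.asarray(values, float), (len(nodes), len(axes)))
        for m, ax in enumerate(axes):
            fixed.extend(3 * act + ax)
            vals.extend(vv[:, m])
    fixed = np.asarray(fixed)
    vals = np.asarray(vals)
    free = np.setdiff1d(np.arange(n), fixed)
    u = np.zeros(n)
    u[fixed] = vals
    rhs = f[free] - K[np.ix_(free, fixed)] @ vals
    u[free] = np.linalg.solve(K[np.ix_(free, free)], rhs)
    return u.reshape(-1, 3)


@pytest.mark.parametrize("shape", [(2, 2, 2), (3, 3, 3), (4, 3, 2), (4, 4, 4)])
def test_mixed_phase_grids_match_dense_oracle(shape, materials):
    """Sparse solution equals an independent dense assembly/solve on
    random mixed-phase grids."""
    rng = np.random.default_rng(12345)
    phase = rng.choice(
        [Phase.CANCELLOUS, Phase.CORTICAL, Phase.IMPLANT], size=shape
    ).astype(np.uint8)
    grid = VoxelGrid(phase=phase)
    op = assemble_stiffness(grid, materials)
    bottom = plane_nodes(op, 2, 0)
    top = plane_nodes(op, 2, shape[2])
    bc = BoundaryConditions(
        fixed=[(bottom, (0, 1, 2), 0.0)],
        load_nodes=top,
        load_weights=np.full(len(top), 1.0 / len(top)),
        total_load=np.array([0.3, -0.1, -1.0]),
    )
    u = solve_elasticity(op, bc)
    u_ref = dense_reference_solution(grid, materials, bc, op)
    assert np.abs(u - u_ref).max() <= 1e-8 * max(np.abs(u_ref).max(), 1e-30)


def test_energy_consistency(small_grid, materials):
    """External work equals stored strain energy: f.u = u^T K u."""
    from chambergrow import axial_compression_bc

    op = assemble_stiffness(small_grid, materials)
    bc = axial_compression_bc(op, 0.3)
    u = solve_elasticity(op, bc)
    f = load_vector(op, bc)
    uu = u.reshape(-1)
    work = f @ uu
    energy = uu @ (op.K @ uu)
    assert energy == pytest.approx(work, rel=1e-8)


def test_rigid_translation_has_zero_strain(small_grid, materials):
    op = assemble_stiffness(small_grid, materials)
    u = np.tile([1e-6, -2e-6, 3e-6], (len(op.active_nodes), 1))
    sol = compute_strains(small_grid, op, u, materials)
    assert np.abs(sol.strain_tensor).max() < 1e-12
    assert np.abs(sol.equivalent_strain).max() < 1e-12


def test_hydrostatic_strain_has_zero_equivalent_strain(materials):
    """A pure volumetric field is deviatoric-free: eps_eq = 0."""
    grid = block_grid((3, 3, 3))
    op = assemble_stiffness(grid, materials)
    c = 1e-4
    u = op.node_coords() * grid.spacing * c
    sol = compute_strains(grid, op, u, materials)
    assert np.abs(sol.equivalent_strain).max() < 1e-12
    # but the von Mises *stress* of a hydrostatic state is also zero
    assert np.abs(sol.equivalent_stress).max() < 1e-3


def test_under_constrained_system_raises(small_grid, materials):
    """A load on a floating body must fail loudly, not return garbage."""
    op = assemble_stiffness(small_grid, materials)
    coords = op.node_coords()
    one = op.active_nodes[:1]
    top = plane_nodes(op, 2, small_grid.shape[2])
    bc = BoundaryConditions(
        fixed=[(one, (0,), 0.0)],
        load_nodes=top,
        load_weights=np.full(len(top), 1.0 / len(top)),
        total_load=np.array([0.0, 0.0, -1.0]),
    )
    with pytest.raises(SolverError):
        solve_elasticity(op, bc, method="direct")
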