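"""Mesh generation and the 3D/1D Biot finite element discretizations."""

import numpy as np
import pytest

from porocirc.coupling import CouplingSpec, VariantOperator
from porocirc.poroelastic import (
    Biot1D,
    BiotBox3D,
    BiotFields,
    ForcingData,
    Geometry,
    PoroParams,
    assemble_biot,
    assemble_biot_1d,
    build_mesh_box,
    eval_stress,
    eval_velocity,
)
from porocirc.timeloop import TimeGrid, run_operator_splitting
from porocirc.verification import oned_conducive_setup


# -- parameters and geometry -------------------------------------------------


def test_param_validation():
    with pytest.raises(ValueError):
        PoroParams(lam=0.5, mu=0.0, k=1.0)
    with pytest.raises(ValueError):
        PoroParams(lam=-0.1, mu=0.25, k=1.0)
    with pytest.raises(ValueError):
        PoroParams(lam=0.5, mu=0.25, k=-1.0)
    p = PoroParams(lam=0.5, mu=0.25, k=1.0)
    assert p.H_A == pytest.approx(1.0)
    assert p.alpha == 1.0 and p.c0 == 0.0


def test_geometry_interface_must_be_xplus():
    with pytest.raises(ValueError):
        Geometry(c=1, a=1, b=1, face_labels={
            "x-": "interface", "x+": "neumann", "y-": "slip", "y+": "slip",
            "z-": "slip", "z+": "slip",
        })


# -- mesh --------------------------------------------------------------------


def test_unit_cube_tetrahedralization():
    g = Geometry(c=1.0, a=1.0, b=1.0)
    mesh = build_mesh_box(g, 1, cell_type="tetra")
    assert mesh.cells.shape == (6, 4)
    assert mesh.cell_volumes().sum() == pytest.approx(1.0, rel=1e-14)


def test_sigma_face_area(ref_geometry):
    mesh = build_mesh_box(ref_geometry, (5, 2, 3))
    hy = ref_geometry.a / 2
    hz = ref_geometry.b / 3
    assert mesh.face_quads["x+"].shape[0] * hy * hz == pytest.approx(0.01)


def test_boundary_faces_partition(small_mesh):
    m = small_mesh
    total = sum(m.face_quads[f].shape[0] for f in m.face_quads)
    nx, ny, nz = m.nx, m.ny, m.nz
    assert total == 2 * (ny * nz + nx * nz + nx * ny)
    # quad sets are disjoint (a boundary quad belongs to exactly one face)
    seen = set()
    for f, quads in m.face_quads.items():
        for q in quads:
            key = tuple(sorted(q))
            assert key not in seen
            seen.add(key)


def test_hex_mesh_volume(small_mesh):
    g = small_mesh.geometry
    assert small_mesh.cell_volumes().sum() == pytest.approx(g.c * g.a * g.b, rel=1e-13)


# -- derived fields ----------------------------------------------------------


def test_velocity_of_linear_pressure(small_fe):
    p = small_fe.mesh.points[:, 0].copy()  # p = x
    fields = BiotFields(fe=small_fe, u=np.zeros(small_fe.ndof_u), p=p)
    v = eval_velocity(fields, small_fe.params)
    np.testing.assert_allclose(v, np.tile([-1.0, 0.0, 0.0], (v.shape[0], 1)), atol=1e-13)


def test_stress_of_uniform_pressure(small_fe):
    p0 = 2.5
    fields = BiotFields(fe=small_fe, u=np.zeros(small_fe.ndof_u), p=np.full(small_fe.ndof_p, p0))
    T = eval_stress(fields, small_fe.params)
    np.testing.assert_allclose(T, np.tile(-p0 * np.eye(3), (T.shape[0], 1, 1)), atol=1e-13)


def test_stress_1d_constant_strain(ref_geometry):
    params = PoroParams(lam=0.5, mu=0.25, k=1.0)  # H_A = 1
    fe = Biot1D(ref_geometry, params, 8)
    u = 2.0 * fe.x  # du/dx = 2
    p = np.ones(fe.ndof_p)
    T = eval_stress(BiotFields(fe=fe, u=u, p=p), params)
    np.testing.assert_allclose(T, 1.0, atol=1e-13)


def test_elastic_energy_of_uniform_strain(small_fe):
    # u = (x - c) e_x has unit strain: E = (lam/2 + mu) |Omega|
    g = small_fe.geometry
    pts = small_fe.mesh.points
    u = np.zeros((small_fe.n_nodes, 3))
    u[:, 0] = pts[:, 0] - g.c
    E = 0.5 * float(u.ravel() @ (small_fe.A_e @ u.ravel()))
    vol = g.c * g.a * g.b
    lam, mu = small_fe.params.lam, small_fe.params.mu
    assert E == pytest.approx((lam / 2 + mu) * vol, rel=1e-12)


def test_elastic_energy_vanishes_for_rigid_translation(small_fe):
    u = np.tile([0.3, -0.2, 0.7], small_fe.n_nodes)
    assert abs(u @ (small_fe.A_e @ u)) <= 1e-12 * np.abs(small_fe.A_e).sum()


# -- one-step systems --------------------------------------------------------


def test_zero_data_zero_solution_3d(small_fe):
    spec = CouplingSpec("ipc", 1.0, 0.1, small_fe.m_sigma)
    sys = assemble_biot(small_fe, ForcingData(), t=0.02, dt=0.02, u_prev=np.zeros(small_fe.ndof_u))
    op = VariantOperator(small_fe, spec, 0.02, variant="ipc")
    sol = op.step(sys.rhs, 0.0)
    assert np.abs(sol.u).max() == 0.0 and np.abs(sol.p).max() == 0.0
    assert sol.P == 0.0 and sol.Q == 0.0


def test_zero_data_zero_solution_1d(fe_1d):
    spec = CouplingSpec("ppc", 1.0, 0.1, fe_1d.m_sigma)
    sys = assemble_biot_1d(fe_1d, ForcingData(), t=0.02, dt=0.02, u_prev=np.zeros(fe_1d.ndof_u))
    op = VariantOperator(fe_1d, spec, 0.02, variant="ppc")
    sol = op.step(sys.rhs, 0.0)
    assert np.abs(sol.u).max() == 0.0 and np.abs(sol.p).max() == 0.0


def test_3d_solution_is_exactly_1d_under_x_only_forcing():
    setup = oned_conducive_setup(resolution=(8, 3, 3), dt=0.02, t_end=1.0)
    tr = run_operator_splitting(setup.problem, "ipc", setup.grid)
    u = tr.u_final.reshape(-1, 3)
    ux = np.abs(u[:, 0]).max()
    assert np.abs(u[:, 1]).max() <= 1e-10 * ux
    assert np.abs(u[:, 2]).max() <= 1e-10 * ux
    # and the pressure trace on the interface is uniform to roundoff
    assert np.nanmax(tr.p_sigma_max - tr.p_sigma_min) <= 1e-13 * np.nanmax(np.abs(tr.P))


def test_3d_matches_1d_profiles():
    setup = oned_conducive_setup(resolution=(10, 4, 4), dt=0.02, t_end=2.0)
    tr3 = run_operator_splitting(setup.problem, "ipc", setup.grid)
    tr1 = run_operator_splitting(setup.problem_1d, "ipc", setup.grid)
    x3 = setup.problem.fe.mesh.points[:, 0]
    p1 = np.interp(x3, setup.problem_1d.fe.x, tr1.p_final)
    scale = np.abs(tr1.p_final).max()
    assert np.abs(tr3.p_final - p1).max() <= 5e-4 * scale  # within discretization error
    assert np.nanmax(np.abs(tr3.P - tr1.P)) <= 5e-4 * scale


def test_discrete_mass_budget():
    """d/dt int div u + int_bdry v.n = int S, tested as the exact row-sum identity."""
    setup = oned_conducive_setup(resolution=(6, 3, 3), dt=0.02, t_end=0.2)
    fe = setup.problem.fe
    spec = setup.problem.coupling
    op = VariantOperator(fe, spec, setup.grid.dt, variant="ipc")
    u = np.zeros(fe.ndof_u)
    pi = 0.0
    dt = setup.grid.dt
    ones = np.ones(fe.ndof_p)
    for n in range(1, setup.grid.n_steps + 1):
        loads = fe.loads(setup.problem.forcing, n * dt)
        rhs = np.concatenate([
            loads["f_F"] + loads["f_g"],
            fe.Dmat @ u + dt * loads["f_S"] - dt * loads["f_psi"],
        ])
        sol = op.step(rhs, pi)
        div_rate = float(ones @ (fe.Dmat @ (sol.u - u))) / dt
        source = float(ones @ loads["f_S"]) - float(ones @ loads["f_psi"])
        assert abs(div_rate + sol.Q - source) <= 1e-12 * max(1.0, abs(sol.Q))
        u, pi = sol.u, sol.pi


def test_1d_manufactured_solution_spatial_convergence(ref_geometry):
    """Steady manufactured (u*, p*) recovered at second order in h (sealed column)."""
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    params = PoroParams(lam=0.5, mu=0.25, k=1.0)
    c = ref_geometry.c
    u_star = lambda x: np.sin(np.pi * (c - x) / (2 * c))
    p_star = lambda x: np.cos(np.pi * x / (2 * c))  # p'(0) = 0, p(c) = 0
    w = np.pi / (2 * c)
    # stationary sources: f = -H_A u'' + p', S = -k p''
    f_fn = lambda pts, t: np.stack(
        [params.H_A * w**2 * u_star(pts[:, 0]) - w * np.sin(w * pts[:, 0]),
         np.zeros(pts.shape[0]), np.zeros(pts.shape[0])], axis=1)
    S_fn = lambda pts, t: params.k * w**2 * p_star(pts[:, 0])

    errs = []
    for n in (8, 16, 32):
        fe = Biot1D(ref_geometry, params, n, sealed=True)
        # T(0) = H_A u*'(0) - p*(0)
        du0 = -w * np.cos(np.pi * (c - 0) / (2 * c))  # u*'(x) = -w cos(pi (c-x)/(2c))
        gval = params.H_A * du0 - p_star(0.0)
        forcing = ForcingData(F=f_fn, S=S_fn, g=lambda t: gval)
        dt = 0.1
        A = sp.bmat([[fe.A_e, -fe.Dmat.T], [fe.Dmat, dt * fe.k_eff * fe.K_p]], format="csr")
        free = np.concatenate([fe.u_free, fe.ndof_u + fe.p_free])
        lu = spla.splu(A[free][:, free].tocsc())
        u = np.zeros(fe.ndof_u)
        p = np.zeros(fe.ndof_p)
        for i in range(400):  # march to the discrete steady state
            loads = fe.loads(forcing, (i + 1) * dt)
            rhs = np.concatenate([
                loads["f_F"] + loads["f_g"],
                fe.Dmat @ u + dt * loads["f_S"] - dt * loads["f_psi"],
            ])
            x = lu.solve(rhs[free])
            full = np.zeros(fe.ndof_u + fe.ndof_p)
            full[free] = x
            u, p = full[: fe.ndof_u], full[fe.ndof_u :]
        err = np.abs(u - u_star(fe.x)).max() + np.abs(p - p_star(fe.x)).max()
        errs.append(err)
    rate1 = np.log2(errs[0] / errs[1])
    rate2 = np.log2(errs[1] / errs[2])
    assert rate1 > 1.7 and rate2 > 1.7
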