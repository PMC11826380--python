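"""Oracles and preconfigured study cases.

* the stationary solution of the 1D-0D coupled column (closed form plus an
  independent brute-force solve of the stationary linear system),
* the printed truly-3D boundary forcing used for the interface-contrast
  study, and
* ready-to-run problem setups: the 1D-conducive 3D box (``test71``), the
  truly 3D forcing case (``test72``) and the constant-forcing steady case.

All presets use the reference parameter set: permeability k = 1, aggregate
modulus H_A = 1 (split lam = 0.5, mu = 0.25), resistances 1, capacitances
0.1, inductance 1, box 0.5 x 0.1 x 0.1 m, dt = 0.02 s, final time 10 s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .circuit import CircuitModel, assemble_example_circuit
from .coupling import CouplingSpec
from .poroelastic import Biot1D, BiotBox3D, ForcingData, Geometry, PoroParams, build_mesh_box
from .timeloop import CoupledProblem, TimeGrid, run_operator_splitting

__all__ = [
    "SteadyState1D0D",
    "steady_state_1d0d",
    "steady_state_brute_force",
    "forcing_test72",
    "Test72Forcing",
    "reference_params",
    "reference_geometry",
    "reference_circuit",
    "make_problem_1d",
    "oned_conducive_setup",
    "test72_setup",
    "steady_setup_1d",
]

# reference parameter table used throughout the studies
REF = {
    "k": 1.0, "H_A": 1.0, "lam": 0.5, "mu": 0.25,
    "R": 1.0, "C": 0.1, "R_bar": 1.0, "R1": 1.0, "C1": 0.1, "L1": 1.0,
    "c": 0.5, "a": 0.1, "b": 0.1, "dt": 0.02, "t_end": 10.0,
}


def reference_params() -> PoroParams:
    return PoroParams(lam=REF["lam"], mu=REF["mu"], k=REF["k"])


def reference_geometry(face_labels=None) -> Geometry:
    kw = {} if face_labels is None else {"face_labels": face_labels}
    return Geometry(c=REF["c"], a=REF["a"], b=REF["b"], **kw)


def reference_circuit(p_bar=0.0) -> CircuitModel:
    return assemble_example_circuit(
        R_bar=REF["R_bar"], R1=REF["R1"], C=REF["C"], C1=REF["C1"], L1=REF["L1"], p_bar=p_bar
    )


# ---------------------------------------------------------------------------
# Stationary 1D-0D solution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SteadyState1D0D:
    """Stationary state of the coupled column under constant (g, p_bar).

    At rest the discharge velocity vanishes, so the pore pressure is
    uniform and equal to the circuit source: p = pi = pi_1 = p_bar, Q =
    Q_1 = 0; the stress is uniform T = g and the displacement is the linear
    profile u(x) = (g + p_bar)/H_A * (x - c).
    """

    p_inf: float
    pi_inf: float
    pi1_inf: float
    Q1_inf: float
    T_inf: float
    strain_inf: float
    c: float

    def u_inf(self, x: np.ndarray) -> np.ndarray:
        return self.strain_inf * (np.asarray(x) - self.c)


def steady_state_1d0d(params: PoroParams, g: float, p_bar: float, geometry: Geometry) -> SteadyState1D0D:
    """Closed-form stationary state; see ``steady_state_brute_force`` for an
    independent numerical confirmation."""
    return SteadyState1D0D(
        p_inf=p_bar,
        pi_inf=p_bar,
        pi1_inf=p_bar,
        Q1_inf=0.0,
        T_inf=g,
        strain_inf=(g + p_bar) / params.H_A,
        c=geometry.c,
    )


def steady_state_brute_force(
    params: PoroParams,
    g: float,
    p_bar: float,
    geometry: Geometry,
    circuit: CircuitModel | None = None,
    spec: CouplingSpec | None = None,
    n_cells: int = 16,
) -> dict:
    """Solve the stationary coupled 1D-0D linear system directly.

    Assembles the full set of stationary equations (finite element Biot
    column with all time derivatives dropped, interface conditions, Ohm's
    law, circuit equilibrium A y + s + b Q = 0) into one dense linear system
    and solves it.  Used as the independent oracle for the closed form.
    """
    circuit = circuit if circuit is not None else reference_circuit(p_bar=p_bar)
    fe = Biot1D(geometry, params, n_cells)
    spec = spec if spec is not None else CouplingSpec("ipc", REF["R"], REF["C"], geometry.m_sigma)
    n = fe.n_nodes
    d = circuit.d
    # unknowns: u (n), p (n), y (d), P, Q
    m = 2 * n + d + 2
    A = np.zeros((m, m))
    b = np.zeros(m)
    iu, ip = np.arange(n), n + np.arange(n)
    iy = 2 * n + np.arange(d)
    iP, iQ = 2 * n + d, 2 * n + d + 1

    Ae = fe.A_e.toarray()
    D = fe.Dmat.toarray()
    Kp = params.k * fe.K_p.toarray()
    forcing = ForcingData(g=lambda t: g)
    loads = fe.loads(forcing, 0.0)
    # momentum at free u dofs; u = 0 at the interface node
    A[np.ix_(iu[fe.u_free], iu)] = Ae[fe.u_free]
    A[np.ix_(iu[fe.u_free], ip)] = -D.T[fe.u_free]
    b[iu[fe.u_free]] = loads["f_g"][fe.u_free]
    fixed = np.where(fe.u_fixed)[0]
    A[iu[fixed], iu[fixed]] = 1.0
    # stationary mass: k K_p p + Q at the interface test function = 0
    A[np.ix_(ip, ip)] = Kp
    A[ip[-1], iQ] = 1.0
    # interface: P = p(c); Ohm: Q = (P - pi)/R
    A[iP, iP] = 1.0
    A[iP, ip[-1]] = -1.0
    A[iQ, iQ] = spec.R
    A[iQ, iP] = -1.0
    A[iQ, iy[0]] = 1.0
    # circuit equilibrium: A y + s + b Q = 0
    A[np.ix_(iy, iy)] = circuit.A
    A[iy[0], iQ] = 1.0 / circuit.connection_capacitance
    b[iy] = -circuit.s(0.0)
    x = np.linalg.solve(A, b)
    return {
        "u": x[iu], "p": x[ip], "y": x[iy], "P": float(x[iP]), "Q": float(x[iQ]), "x": fe.x,
    }


# ---------------------------------------------------------------------------
# Printed truly-3D forcing
# ---------------------------------------------------------------------------


def forcing_test72(points: np.ndarray, t: float, face: str) -> np.ndarray:
    """Prescribed normal discharge psi on the two forced faces.

    face "x-" (x = 0):   -0.2 cos(10 pi y) cos(10 pi z) (1 + 0.5 cos(0.2 pi t))
    face "y-" (y=-0.05):  0.2 exp(-1000((x-0.45)^2 + z^2)) (1 - 0.5 sin(0.3 pi t))
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    if face == "x-":
        if not np.allclose(x, 0.0, atol=1e-12):
            raise ValueError("points are not on the face x = 0")
        return -0.2 * np.cos(10 * np.pi * y) * np.cos(10 * np.pi * z) * (1 + 0.5 * np.cos(0.2 * np.pi * t))
    if face == "y-":
        if not np.allclose(y, -0.05, atol=1e-12):
            raise ValueError("points are not on the face y = -0.05")
        return 0.2 * np.exp(-1000.0 * ((x - 0.45) ** 2 + z**2)) * (1 - 0.5 * np.sin(0.3 * np.pi * t))
    raise ValueError("face must be 'x-' or 'y-'")


@dataclass(frozen=True)
class Test72Forcing:
    """The two printed discharge profiles with their temporal periods (s)."""

    __test__ = False  # not a test case, despite the study's name

    period_x0: float = 10.0
    period_ym: float = 20.0 / 3.0

    def psi_x0(self, points, t):
        return forcing_test72(points, t, "x-")

    def psi_ym(self, points, t):
        return forcing_test72(points, t, "y-")


# ---------------------------------------------------------------------------
# Problem setups
# ---------------------------------------------------------------------------


def make_problem_1d(
    variant: str = "ipc",
    p_bar: Callable[[float], float] | float = 0.0,
    g: Callable[[float], float] | None = None,
    n_cells: int = 64,
    u0=None,
    y0=None,
) -> CoupledProblem:
    """Coupled 1D-0D column with the reference parameter set."""
    geo = reference_geometry()
    params = reference_params()
    fe = Biot1D(geo, params, n_cells)
    circuit = reference_circuit(p_bar=p_bar)
    spec = CouplingSpec(variant, REF["R"], REF["C"], geo.m_sigma)
    forcing = ForcingData(g=g, u0=u0, y0=y0)
    return CoupledProblem(fe=fe, circuit=circuit, coupling=spec, forcing=forcing)


@dataclass
class StudySetup:
    problem: CoupledProblem
    grid: TimeGrid
    amplitude: float = 1.0
    problem_1d: CoupledProblem | None = None


def oned_conducive_setup(
    target_pressure_scale: float = 0.1,
    resolution=(20, 6, 6),
    n_cells_1d: int = 64,
    dt: float | None = None,
    t_end: float | None = None,
) -> StudySetup:
    """The 1D-conducive 3D-0D study: x-only forcing on the reference box.

    The circuit source is the sinusoid p_bar(t) = A sin(0.2 pi t); the
    amplitude A is auto-scaled (by linearity, from one cheap 1D-0D run at
    unit amplitude) so that the peak interface pressure is approximately
    ``target_pressure_scale`` (default 0.1 Pa).
    """
    if target_pressure_scale <= 0.0:
        raise ValueError("target_pressure_scale must be positive")
    dt = REF["dt"] if dt is None else dt
    t_end = REF["t_end"] if t_end is None else t_end
    grid = TimeGrid(dt=dt, t_end=t_end)

    probe = make_problem_1d(variant="ipc", p_bar=lambda t: np.sin(0.2 * np.pi * t), n_cells=n_cells_1d)
    tr = run_operator_splitting(probe, "ipc", grid)
    peak = np.nanmax(np.abs(tr.P))
    amp = target_pressure_scale / peak

    def p_bar(t, _a=amp):
        return _a * np.sin(0.2 * np.pi * t)

    geo = reference_geometry()
    params = reference_params()
    mesh = build_mesh_box(geo, resolution)
    fe3 = BiotBox3D(mesh, params)
    circuit = reference_circuit(p_bar=p_bar)
    spec = CouplingSpec("ipc", REF["R"], REF["C"], geo.m_sigma)
    problem3d = CoupledProblem(fe=fe3, circuit=circuit, coupling=spec, forcing=ForcingData())
    problem1d = make_problem_1d(variant="ipc", p_bar=p_bar, n_cells=n_cells_1d)
    return StudySetup(problem=problem3d, grid=grid, amplitude=amp, problem_1d=problem1d)


def test72_setup(resolution=(24, 8, 8), dt: float | None = None, t_end: float | None = None) -> StudySetup:
    """The truly 3D study: printed discharge forcing on two faces.

    The forced faces x = 0 and y = -0.05 carry u = 0 and v.n = psi; the
    remaining lateral faces are free-slip/impermeable; the interface stays
    at x = 0.5.  The circuit is the reference one with no pressure source.
    """
    dt = REF["dt"] if dt is None else dt
    t_end = REF["t_end"] if t_end is None else t_end
    grid = TimeGrid(dt=dt, t_end=t_end)
    labels = {
        "x-": "dirichlet_v", "x+": "interface",
        "y-": "dirichlet_v", "y+": "slip", "z-": "slip", "z+": "slip",
    }
    geo = reference_geometry(face_labels=labels)
    params = reference_params()
    mesh = build_mesh_box(geo, resolution)
    fe = BiotBox3D(mesh, params)
    circuit = reference_circuit()
    spec = CouplingSpec("ipc", REF["R"], REF["C"], geo.m_sigma)
    f72 = Test72Forcing()
    forcing = ForcingData(psi={"x-": f72.psi_x0, "y-": f72.psi_ym})
    problem = CoupledProblem(fe=fe, circuit=circuit, coupling=spec, forcing=forcing)
    return StudySetup(problem=problem, grid=grid)


def steady_setup_1d(g: float = 0.0, p_bar: float = 1.0, n_cells: int = 64) -> CoupledProblem:
    """Constant-forcing 1D-0D column converging to the stationary oracle."""
    return make_problem_1d(variant="ipc", p_bar=float(p_bar), g=(lambda t: g), n_cells=n_cells)
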