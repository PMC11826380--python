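"""Time integration drivers: energy-stable operator splitting and PQP iteration.

The operator splitting advances each backward Euler step in two substeps
that communicate only through initial conditions:

  Step 1  Biot + connection: solve the poroelastic system together with the
          interface conditions and the backward Euler discretization of the
          connecting-node ODE pi' = Q/C; this updates (u, p), the interface
          scalars (P, Q) and pi, while the internal circuit states are
          frozen.
  Step 2  Internal circuit: advance the full circuit ODE y' = A y + s(t)
          (no interface term) from the half-updated state.

No sub-iterations are performed; the scheme is unconditionally stable in dt
because each substep dissipates the respective physical energy.  The order
of the substeps may be swapped (circuit first) without losing stability.

The PQP fixed-point alternative decouples the systems within each time
step: solve Biot with a prescribed interface pressure P_j (full-trace
Dirichlet), extract the flow rate Q_{j+1}, feed it to the circuit, and
update P_{j+1} = pi_{j+1} + R Q_{j+1}; iterate to convergence.  The map
P -> P_{j+1} is affine; its empirical contraction factor
gamma2_hat = |P_{j+2} - P_{j+1}| / |P_{j+1} - P_j| grows without bound as
dt -> 0 in stiff parameter regimes (large connection resistance, etc.), so
the iteration can diverge with a blow-up of the iterates even though the
underlying problem is perfectly well posed -- the pathology the splitting
scheme avoids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit import CircuitModel, circuit_dissipation, circuit_energy, step_circuit_be
from .coupling import (
    DirichletInterfaceOperator,
    StepSolution,
    VariantOperator,
    consistent_interface_flux,
)
from .energy import connection_dissipation, step1_identity_residual
from .poroelastic import BiotFields, ForcingData

__all__ = [
    "TimeGrid",
    "CoupledProblem",
    "Trajectory",
    "PQPDiagnostics",
    "run_operator_splitting",
    "step1_order_swap",
    "run_pqp",
]


@dataclass(frozen=True)
class TimeGrid:
    """Uniform grid t_n = n dt covering [0, t_end]."""

    dt: float
    t_end: float

    def __post_init__(self) -> None:
        if self.dt <= 0.0 or self.t_end <= 0.0:
            raise ValueError("dt and t_end must be positive")
        n = round(self.t_end / self.dt)
        if n < 1 or abs(n * self.dt - self.t_end) > 1e-9 * max(1.0, self.t_end):
            raise ValueError("t_end must be an integer multiple of dt")

    @property
    def n_steps(self) -> int:
        return round(self.t_end / self.dt)

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.n_steps + 1)


@dataclass
class CoupledProblem:
    """A Biot discretization, a lumped circuit, their connection, and forcing."""

    fe: object
    circuit: CircuitModel
    coupling: CouplingSpec
    forcing: ForcingData = field(default_factory=ForcingData)

    def __post_init__(self) -> None:
        if self.fe.has_interface and not np.isclose(
            self.coupling.m_sigma, self.fe.m_sigma, rtol=1e-12
        ):
            raise ValueError("coupling.m_sigma does not match the mesh interface area")
        if not np.isclose(self.coupling.C, self.circuit.connection_capacitance, rtol=1e-12):
            raise ValueError("coupling.C must equal the circuit connection capacitance")

    def initial_state(self) -> tuple[np.ndarray, np.ndarray]:
        u0 = self.fe.interpolate_u0(self.forcing.u0)
        if self.forcing.u0 is None and self.forcing.chi is not None and self.fe.dim == 1:
            u0 = self.fe.u0_from_chi(self.forcing.chi)
            u0[self.fe.u_fixed] = 0.0
        y0 = (
            np.zeros(self.circuit.d)
            if self.forcing.y0 is None
            else np.asarray(self.forcing.y0, dtype=float).copy()
        )
        if y0.shape != (self.circuit.d,):
            raise ValueError("y0 has wrong dimension")
        return u0, y0


@dataclass
class Trajectory:
    """Per-step scalar time series of a coupled run (index 0 = initial data).

    ``P``, ``Q``, work terms and residuals are undefined at the initial
    instant and stored as NaN there.
    """

    t: np.ndarray
    y: np.ndarray                 # (n+1, d) circuit state after the full step
    y_half: np.ndarray            # (n+1, d) circuit state after Step 1
    P: np.ndarray
    Q: np.ndarray
    pi: np.ndarray
    p_sigma_max: np.ndarray
    p_sigma_min: np.ndarray
    E_omega: np.ndarray
    E_circ: np.ndarray
    D_omega: np.ndarray
    D_circ: np.ndarray
    D_lambda: np.ndarray
    work_omega: np.ndarray
    work_boundary: np.ndarray
    work_circuit: np.ndarray
    step1_residual: np.ndarray
    ohm_residual: np.ndarray
    u_final: np.ndarray
    p_final: np.ndarray
    variant: str
    dt: float
    fields: list | None = None    # optional per-step (u, p) snapshots

    @property
    def E_total(self) -> np.ndarray:
        return self.E_omega + self.E_circ

    def to_frame(self) -> pd.DataFrame:
        d = self.y.shape[1]
        cols = {
            "t": self.t,
            "pi": self.pi,
            "P": self.P,
            "Q": self.Q,
            "p_sigma_max": self.p_sigma_max,
            "p_sigma_min": self.p_sigma_min,
            "E_omega": self.E_omega,
            "E_circ": self.E_circ,
            "D_omega": self.D_omega,
            "D_circ": self.D_circ,
            "D_lambda": self.D_lambda,
            "F_omega": self.work_omega,
            "F_boundary": self.work_boundary,
            "F_circ": self.work_circuit,
            "step1_residual": self.step1_residual,
            "ohm_residual": self.ohm_residual,
        }
        for j in range(1, d):
            cols[f"y{j}"] = self.y[:, j]
        return pd.DataFrame(cols)


@dataclass
class PQPDiagnostics:
    """Fixed-point diagnostics: per accepted step, the iterate history."""

    iterations: list = field(default_factory=list)      # iteration count per step
    gamma2: list = field(default_factory=list)          # per-step empirical factors
    converged: list = field(default_factory=list)
    blow_up: bool = False
    blow_up_step: int | None = None

    @property
    def gamma2_last(self) -> float:
        g = [g[-1] for g in self.gamma2 if len(g)]
        return float(g[-1]) if g else np.nan


def _alloc(n: int) -> np.ndarray:
    a = np.full(n, np.nan)
    return a


def _new_trajectory(n_steps: int, d: int, variant: str, dt: float, store_fields: bool) -> Trajectory:
    n = n_steps + 1
    return Trajectory(
        t=np.zeros(n), y=np.zeros((n, d)), y_half=np.zeros((n, d)),
        P=_alloc(n), Q=_alloc(n), pi=np.zeros(n),
        p_sigma_max=_alloc(n), p_sigma_min=_alloc(n),
        E_omega=np.zeros(n), E_circ=np.zeros(n),
        D_omega=_alloc(n), D_circ=_alloc(n), D_lambda=_alloc(n),
        work_omega=_alloc(n), work_boundary=_alloc(n), work_circuit=_alloc(n),
        step1_residual=_alloc(n), ohm_residual=_alloc(n),
        u_final=np.array([]), p_final=np.array([]),
        variant=variant, dt=dt, fields=[] if store_fields else None,
    )


def _record_initial(tr: Trajectory, problem: CoupledProblem, u0, y0) -> None:
    fe = problem.fe
    tr.t[0] = 0.0
    tr.y[0] = y0
    tr.y_half[0] = y0
    tr.pi[0] = y0[0]
    tr.E_omega[0] = 0.5 * float(u0 @ (fe.A_e @ u0))
    tr.E_circ[0] = circuit_energy(problem.circuit.U, y0)


def run_operator_splitting(
    problem: CoupledProblem,
    variant: str,
    grid: TimeGrid,
    *,
    order: str = "biot_first",
    store_fields: bool = False,
) -> Trajectory:
    """Advance the coupled problem with the two-substep splitting scheme."""
    if order not in ("biot_first", "circuit_first"):
        raise ValueError("order must be 'biot_first' or 'circuit_first'")
    fe = problem.fe
    circuit = problem.circuit
    spec = problem.coupling
    dt = grid.dt
    op = VariantOperator(fe, spec, dt, variant=variant)

    u, y = problem.initial_state()
    tr = _new_trajectory(grid.n_steps, circuit.d, variant, dt, store_fields)
    _record_initial(tr, problem, u, y)

    for n in range(1, grid.n_steps + 1):
        t1 = n * dt
        if order == "circuit_first":
            y = step_circuit_be(circuit, y, 0.0, dt, t1)
        loads = fe.loads(problem.forcing, t1)
        rhs = np.concatenate(
            [
                loads["f_F"] + loads["f_g"],
                fe.Dmat @ u + dt * loads["f_S"] - dt * loads["f_psi"],
            ]
        )
        pi_seed = y[0]
        sol = op.step(rhs, pi_seed)
        y_half = y.copy()
        y_half[0] = sol.pi
        y1 = step_circuit_be(circuit, y_half, 0.0, dt, t1) if order == "biot_first" else y_half
        _record_step_with_pi0(tr, problem, variant, n, t1, sol, y1, u, loads, dt, pi_seed)
        Q_flux = consistent_interface_flux(op, rhs, sol.u, sol.p)
        tr.ohm_residual[n] = abs(Q_flux - (sol.P - sol.pi) / spec.R)
        u, y = sol.u, y1
        p_last = sol.p
    tr.u_final, tr.p_final = u, p_last
    return tr


def _record_step_with_pi0(tr, problem, variant, n, t1, sol, y1, u_prev, loads, dt, pi0) -> None:
    fe = problem.fe
    circuit = problem.circuit
    spec = problem.coupling
    tr.t[n] = t1
    tr.y[n] = y1
    tr.y_half[n] = np.concatenate([[sol.pi], tr.y[n - 1][1:]])
    tr.P[n] = sol.P
    tr.Q[n] = sol.Q
    tr.pi[n] = y1[0]
    sig = fe.sigma_p_nodes
    tr.p_sigma_max[n] = sol.p[sig].max()
    tr.p_sigma_min[n] = sol.p[sig].min()
    tr.E_omega[n] = 0.5 * float(sol.u @ (fe.A_e @ sol.u))
    tr.E_circ[n] = circuit_energy(circuit.U, y1)
    tr.D_omega[n] = fe.k_eff * float(sol.p @ (fe.K_p @ sol.p))
    tr.D_circ[n] = circuit_dissipation(circuit.B, y1)
    fields = BiotFields(fe=fe, u=sol.u, p=sol.p, t=t1)
    tr.D_lambda[n] = connection_dissipation(variant, fields, sol.pi, spec, Q=sol.Q)
    du = (sol.u - u_prev) / dt
    tr.work_omega[n] = float(loads["f_F"] @ du) + float(loads["f_S"] @ sol.p)
    tr.work_boundary[n] = float(loads["f_g"] @ du) - float(loads["f_psi"] @ sol.p)
    tr.work_circuit[n] = float(y1 @ (circuit.U @ circuit.s(t1)))
    tr.step1_residual[n] = step1_identity_residual(
        fe, spec, variant, dt, u_prev, sol.u, sol.p, pi0, sol.pi, sol.P, sol.Q, loads
    )
    if tr.fields is not None:
        tr.fields.append((sol.u.copy(), sol.p.copy()))


def step1_order_swap(problem: CoupledProblem, variant: str, grid: TimeGrid, **kw) -> Trajectory:
    """Splitting with the substeps reversed: internal circuit first."""
    return run_operator_splitting(problem, variant, grid, order="circuit_first", **kw)


def run_pqp(
    problem: CoupledProblem,
    grid: TimeGrid,
    tol: float = 1e-10,
    max_iter: int = 100,
    guard: float = 1e12,
    store_fields: bool = False,
) -> tuple[Trajectory, PQPDiagnostics]:
    """Partitioned fixed-point (PQP) time stepping with divergence diagnostics.

    Non-convergence within ``max_iter`` is reported through the diagnostics,
    not raised; iterate blow-up beyond ``guard`` aborts the run, returning
    the trajectory computed so far.
    """
    if tol <= 0.0:
        raise ValueError("tol must be positive")
    fe = problem.fe
    circuit = problem.circuit
    spec = problem.coupling
    dt = grid.dt
    dop = DirichletInterfaceOperator(fe, dt)

    u, y = problem.initial_state()
    tr = _new_trajectory(grid.n_steps, circuit.d, "pqp", dt, store_fields)
    _record_initial(tr, problem, u, y)
    diag = PQPDiagnostics()

    P_j = y[0]
    p_last = np.zeros(fe.ndof_p)
    for n in range(1, grid.n_steps + 1):
        t1 = n * dt
        loads = fe.loads(problem.forcing, t1)
        rhs = np.concatenate(
            [
                loads["f_F"] + loads["f_g"],
                fe.Dmat @ u + dt * loads["f_S"] - dt * loads["f_psi"],
            ]
        )
        diffs: list[float] = []
        gammas: list[float] = []
        converged = False
        for j in range(max_iter):
            u_j, p_j, Q_j = dop.solve(rhs, P_j)
            y_j = step_circuit_be(circuit, y, Q_j, dt, t1)
            P_next = y_j[0] + spec.R * Q_j
            diffs.append(abs(P_next - P_j))
            if len(diffs) >= 2 and diffs[-2] > 0.0:
                gammas.append(diffs[-1] / diffs[-2])
            P_j = P_next
            if abs(P_j) > guard or not np.isfinite(P_j):
                diag.blow_up = True
                diag.blow_up_step = n
                break
            if diffs[-1] <= tol * max(1.0, abs(P_next)):
                converged = True
                break
        diag.iterations.append(len(diffs))
        diag.gamma2.append(np.array(gammas))
        diag.converged.append(converged)
        if diag.blow_up:
            break
        sol = StepSolution(u=u_j, p=p_j, P=P_j, pi=y_j[0], Q=Q_j)
        _record_step_with_pi0(tr, problem, "ppc", n, t1, sol, y_j, u, loads, dt, y[0])
        tr.ohm_residual[n] = abs(Q_j - (P_j - y_j[0]) / spec.R)
        u, y, p_last = u_j, y_j, p_j
    tr.u_final, tr.p_final = u, p_last
    return tr, diag
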