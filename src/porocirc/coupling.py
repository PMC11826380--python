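"""Interface conditions on Sigma coupling the Biot box to the circuit.

Two variants connect the pore pressure on the interface Sigma (the face
x = c) to the pressure ``P`` at the tissue end of the connecting resistor R
and to the connecting-node pressure ``pi`` (grounded through the connection
capacitor C); the flow through the resistor obeys Poiseuille/Ohm's law
Q = (P - pi)/R.

PPC (pointwise pressure condition)
    p = P on all of Sigma (a single scalar unknown), with the nonlocal flux
    constraint Q = int_Sigma v.n.  Enforced by static condensation: every
    Sigma pressure dof is identified with the scalar P, and the condensed
    test function (= 1 on Sigma) turns the natural boundary term into Q.

IPC (integral pressure condition)
    K v.n = p - pi pointwise with K = R * m_Sigma, and P defined as the
    Sigma-mean of p.  The backward Euler elimination of the pi-ODE
    (pi' = Q/C) yields the Robin-type condition

        K v.n - p + [dt/(RC+dt)] (1/m_Sigma) int_Sigma p = -[RC/(RC+dt)] pi_n

    implemented as a Robin boundary term plus a rank-one nonlocal mean term,
    handled as a bordered system with the single extra unknown P.

Both variants clamp the solid at the interface (u = 0 on Sigma).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .poroelastic import BiotFields, BiotStepSystem

__all__ = [
    "CouplingSpec",
    "InterfaceTrace",
    "IPCCoefficients",
    "ipc_robin_coefficients",
    "VariantOperator",
    "DirichletInterfaceOperator",
    "apply_ipc",
    "apply_ppc",
    "interface_statistics",
    "consistent_interface_flux",
]


@dataclass(frozen=True)
class CouplingSpec:
    """Connection parameters: variant tag, resistance R, capacitance C.

    K = R * m_Sigma is derived, never set independently.
    """

    variant: Literal["ppc", "ipc"]
    R: float
    C: float
    m_sigma: float

    def __post_init__(self) -> None:
        if self.variant not in ("ppc", "ipc"):
            raise ValueError("variant must be 'ppc' or 'ipc'")
        if self.R <= 0.0 or self.C <= 0.0 or self.m_sigma <= 0.0:
            raise ValueError("R, C and m_sigma must be positive")

    @property
    def K(self) -> float:
        return self.R * self.m_sigma


@dataclass(frozen=True)
class InterfaceTrace:
    """Interface scalars at one accepted time level."""

    t: float
    P: float          # interface pressure (Pa)
    Q: float          # flow through the connecting resistor (m^3/s)
    pi: float         # connecting-node pressure (Pa)
    p_max: float
    p_min: float
    p_mean: float


@dataclass(frozen=True)
class IPCCoefficients:
    """Coefficients of the discrete Robin-type IPC condition.

    K v.n + coef_p * p + coef_mean * (1/m_Sigma) int_Sigma p = rhs,
    with coef_flux = K, coef_p = -1, coef_mean = dt/(RC+dt) and
    rhs = -RC/(RC+dt) * pi_n; the circuit node recovers as
    pi_{n+1} = (RC pi_n + dt P_{n+1}) / (RC + dt).
    """

    coef_flux: float
    coef_p: float
    coef_mean: float
    rhs: float
    R: float
    C: float
    dt: float
    pi_n: float

    def recover_pi(self, P_next: float) -> float:
        RC = self.R * self.C
        return (RC * self.pi_n + self.dt * P_next) / (RC + self.dt)


def ipc_robin_coefficients(R: float, C: float, K: float, dt: float, pi_n: float) -> IPCCoefficients:
    """Backward Euler elimination of the pi-ODE into a Robin condition."""
    if min(R, C, K, dt) <= 0.0:
        raise ValueError("R, C, K and dt must be positive")
    RC = R * C
    return IPCCoefficients(
        coef_flux=K,
        coef_p=-1.0,
        coef_mean=dt / (RC + dt),
        rhs=-RC / (RC + dt) * pi_n,
        R=R,
        C=C,
        dt=dt,
        pi_n=pi_n,
    )


@dataclass(frozen=True)
class StepSolution:
    u: np.ndarray
    p: np.ndarray
    P: float
    pi: float
    Q: float


def _selection(n, idx):
    m = len(idx)
    return sp.csr_matrix((np.ones(m), (idx, np.arange(m))), shape=(n, m))


class VariantOperator:
    """Reduced one-step operator for a fixed (fe, spec, dt, variant).

    Holds the constraint/condensation map Z, the reduced matrix and its LU
    factorization; per time step only the right-hand side changes.
    """

    def __init__(self, fe, spec: CouplingSpec, dt: float, variant: str | None = None):
        if not fe.has_interface:
            raise ValueError("geometry has no interface face Sigma")
        self.fe = fe
        self.spec = spec
        self.dt = float(dt)
        self.variant = variant or spec.variant
        if self.variant not in ("ppc", "ipc"):
            raise ValueError("variant must be 'ppc' or 'ipc'")

        nu, npp = fe.ndof_u, fe.ndof_p
        self.nu, self.np = nu, npp
        ndof = nu + npp
        A = sp.bmat([[fe.A_e, -fe.Dmat.T], [fe.Dmat, dt * fe.k_eff * fe.K_p]], format="csr")

        sig = np.asarray(fe.sigma_p_nodes)
        sig_free = sig[fe.p_free_mask[sig]]
        self.sigma_nodes = sig_free
        R, C, K = spec.R, spec.C, spec.K
        RC = R * C

        if self.variant == "ipc":
            beta = dt / (RC + dt)
            self.beta = beta
            # Robin term dt*(1/K)*M_sigma on the pressure block
            Arob = sp.bmat(
                [[sp.csr_matrix((nu, nu)), None], [None, (dt / K) * fe.M_sigma]], format="csr"
            )
            col = np.zeros(ndof)
            col[nu:] = -(dt * beta / K) * fe.w_sigma
            border_row = np.zeros(ndof)
            border_row[nu:] = -fe.w_sigma
            A_aug = sp.bmat(
                [
                    [A + Arob, sp.csr_matrix(col[:, None])],
                    [sp.csr_matrix(border_row[None, :]), sp.csr_matrix([[fe.m_sigma]])],
                ],
                format="csr",
            )
            free = np.concatenate([fe.u_free, nu + fe.p_free, [ndof]])
            self._free = free
            self.iP = free.size - 1
            self.Z = _selection(ndof + 1, free)
            self.A_red = (A_aug[free][:, free]).tocsc()
        else:  # ppc
            # condense Sigma pressure dofs into the single scalar P
            keep_p = np.setdiff1d(fe.p_free, sig_free)
            nred = fe.u_free.size + keep_p.size + 1
            rows = np.concatenate([fe.u_free, nu + keep_p, nu + sig_free])
            cols = np.concatenate(
                [
                    np.arange(fe.u_free.size),
                    fe.u_free.size + np.arange(keep_p.size),
                    np.full(sig_free.size, nred - 1),
                ]
            )
            self.Z = sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(ndof, nred))
            self.iP = nred - 1
            self.cQ = 1.0 / (R + dt / C)
            A_red = (self.Z.T @ A @ self.Z).tolil()
            A_red[self.iP, self.iP] += dt * self.cQ
            self.A_red = A_red.tocsc()
        self._lu = None
        self._A_plain = A  # uncoupled system, for consistent flux evaluation

    @property
    def lu(self):
        if self._lu is None:
            self._lu = spla.splu(self.A_red)
        return self._lu

    def reduce_rhs(self, rhs_full: np.ndarray, pi_n: float) -> np.ndarray:
        fe, spec, dt = self.fe, self.spec, self.dt
        if self.variant == "ipc":
            r = np.concatenate([rhs_full, [0.0]])
            r[self.nu : self.nu + self.np] += (
                dt * (1.0 - self.beta) / spec.K * pi_n
            ) * fe.w_sigma
            return r[self._free]
        b = self.Z.T @ rhs_full
        b[self.iP] += dt * self.cQ * pi_n
        return b

    def expand(self, x_red: np.ndarray, pi_n: float) -> StepSolution:
        fe, spec = self.fe, self.spec
        full = self.Z @ x_red
        u = full[: self.nu]
        p = full[self.nu : self.nu + self.np]
        P = float(x_red[self.iP])
        if self.variant == "ipc":
            RC = spec.R * spec.C
            pi1 = (RC * pi_n + self.dt * P) / (RC + self.dt)
        else:
            Q = self.cQ * (P - pi_n)
            pi1 = pi_n + self.dt * Q / spec.C
        Q = (P - pi1) / spec.R
        return StepSolution(u=u, p=p, P=P, pi=pi1, Q=Q)

    def step(self, rhs_full: np.ndarray, pi_n: float) -> StepSolution:
        b = self.reduce_rhs(rhs_full, pi_n)
        return self.expand(self.lu.solve(b), pi_n)


class DirichletInterfaceOperator:
    """Inner solve of the PQP iteration: full-trace Dirichlet p = P_j on Sigma.

    The reduced operator is factorized once; each fixed-point iterate only
    shifts the right-hand side affinely in P_j.
    """

    def __init__(self, fe, dt: float):
        self.fe = fe
        self.dt = float(dt)
        nu, npp = fe.ndof_u, fe.ndof_p
        self.nu, self.np = nu, npp
        ndof = nu + npp
        A = sp.bmat([[fe.A_e, -fe.Dmat.T], [fe.Dmat, dt * fe.k_eff * fe.K_p]], format="csr")
        sig = np.asarray(fe.sigma_p_nodes)
        self.sigma_nodes = sig[fe.p_free_mask[sig]]
        keep_p = np.setdiff1d(fe.p_free, self.sigma_nodes)
        self.keep_p = keep_p
        free = np.concatenate([fe.u_free, nu + keep_p])
        self._free = free
        self.A_red = (A[free][:, free]).tocsc()
        ind = np.zeros(ndof)
        ind[nu + self.sigma_nodes] = 1.0
        self._ind = ind
        self._A_ind_free = np.asarray((A @ ind))[free]
        self._A_plain = A
        self._lu = None

    @property
    def lu(self):
        if self._lu is None:
            self._lu = spla.splu(self.A_red)
        return self._lu

    def solve(self, rhs_full: np.ndarray, P_j: float) -> tuple[np.ndarray, np.ndarray, float]:
        """Solve with p|Sigma = P_j; return (u, p, Q) with the consistent flux."""
        b = rhs_full[self._free] - P_j * self._A_ind_free
        x = self.lu.solve(b)
        nu = self.nu
        full = np.zeros(nu + self.np)
        full[self._free] = x
        full += P_j * self._ind
        u, p = full[:nu], full[nu:]
        res = self._A_plain @ full - rhs_full
        Q = -float(res[nu + self.sigma_nodes].sum()) / self.dt
        return u, p, Q


@dataclass
class CoupledStepSystem:
    """A Biot one-step system with the interface variant applied."""

    op: VariantOperator
    rhs_red: np.ndarray
    pi_n: float

    def solve(self) -> StepSolution:
        return self.op.expand(self.op.lu.solve(self.rhs_red), self.pi_n)


def apply_ipc(system: BiotStepSystem, spec: CouplingSpec, pi_n: float) -> CoupledStepSystem:
    """Apply the IPC Robin + rank-one mean coupling to a one-step system."""
    op = VariantOperator(system.fe, spec, system.dt, variant="ipc")
    return CoupledStepSystem(op=op, rhs_red=op.reduce_rhs(system.rhs, pi_n), pi_n=pi_n)


def apply_ppc(system: BiotStepSystem, spec: CouplingSpec, pi_n: float) -> CoupledStepSystem:
    """Apply the PPC constant-pressure condensation to a one-step system."""
    op = VariantOperator(system.fe, spec, system.dt, variant="ppc")
    return CoupledStepSystem(op=op, rhs_red=op.reduce_rhs(system.rhs, pi_n), pi_n=pi_n)


def consistent_interface_flux(op, system_rhs: np.ndarray, u: np.ndarray, p: np.ndarray) -> float:
    """int_Sigma v.n recovered from the residual of the uncoupled mass rows.

    The Sigma-trace test functions of the uncoupled system see exactly
    -dt * int_Sigma v.n q; summing them (q = 1 on Sigma) yields the
    discretely consistent boundary flux, an arithmetic path independent of
    the Ohm-law recovery used by the steppers.
    """
    full = np.concatenate([u, p])
    res = op._A_plain @ full - system_rhs
    return -float(res[op.nu + op.sigma_nodes].sum()) / op.dt


def interface_statistics(fields: BiotFields) -> InterfaceTrace:
    """Boundary-quadrature statistics of the interface pressure and flux.

    The flux is evaluated by direct quadrature of v.n = -k dp/dx on the
    Sigma faces (first-order accurate; the steppers' own flux is the
    consistent one).
    """
    fe = fields.fe
    if not fe.has_interface:
        raise ValueError("no interface face")
    p = fields.p
    w = fe.w_sigma
    m = fe.m_sigma
    p_mean = float(w @ p) / m
    sig = fe.sigma_p_nodes
    p_sig = p[sig]
    k = fe.params.k
    if fe.dim == 1:
        v_c = -k * (p[-1] - p[-2]) / fe.hx
        Q = v_c * fe.area
    else:
        mesh = fe.mesh
        xmax = mesh.points[:, 0].max()
        hx, hy, hz = mesh.h
        cells = mesh.cells
        on_face = np.isclose(mesh.points[cells[:, 1], 0], xmax)
        face_cells = cells[on_face]
        from .poroelastic import _shape_q1

        _, dNr = _shape_q1(np.array([[1.0, 0.5, 0.5]]))
        G = dNr[0] / np.array([hx, hy, hz])
        dpdx = np.einsum("ca,a->c", p[face_cells], G[:, 0])
        Q = float((-k * dpdx).sum() * hy * hz)
    return InterfaceTrace(
        t=fields.t, P=p_mean, Q=Q, pi=np.nan,
        p_max=float(p_sig.max()), p_min=float(p_sig.min()), p_mean=p_mean,
    )
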