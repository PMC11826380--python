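"""Energy and dissipation functionals and the discrete energy audit.

The coupled tissue/circuit system carries the balance

    d/dt (E_Omega + E_Upsilon) + D_Omega + D_Upsilon + D_Lambda
        = F_Omega + F_boundary + F_Upsilon,

with the elastic energy E_Omega = lam/2 ||div u||^2 + mu ||E(u)||^2, the
circuit energy E_Upsilon = 1/2 y^T U y, the Darcy dissipation
D_Omega = ||k^{1/2} grad p||^2, the circuit dissipation y^T B y and the
connection dissipation D_Lambda (R Q^2 for the pointwise variant,
(1/K) int_Sigma (p - pi)^2 for the integral one).  All dissipations are
nonnegative; the connection acts as a damping mechanism for both interface
variants.

The discrete audit uses backward differences matched to the backward Euler
stepping and reports the defect

    residual_n = F_n - (E_n - E_{n-1})/dt - (D_Omega + D_Upsilon + D_Lambda)_n,

which equals the (nonnegative, O(dt)) numerical dissipation introduced by
the implicit stepping and the operator splitting; it vanishes on the zero
trajectory and shrinks at first order under dt-refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coupling import CouplingSpec
from .poroelastic import BiotFields

__all__ = [
    "EnergyReport",
    "elastic_energy",
    "darcy_dissipation",
    "connection_dissipation",
    "ipc_connection_identity_gap",
    "step1_identity_residual",
    "audit_energy_identity",
    "energy_report",
]


@dataclass(frozen=True)
class EnergyReport:
    """All energy, dissipation and work terms at one accepted time level.

    Energies in J; dissipations and work rates in W.  ``residual`` is the
    defect of the total balance at this step (NaN at the initial instant,
    where no step has been taken).
    """

    t: float
    E_omega: float
    E_circ: float
    D_omega: float
    D_circ: float
    D_lambda: float
    work_omega: float
    work_boundary: float
    work_circuit: float
    residual: float

    def __post_init__(self) -> None:
        for name in ("E_omega", "E_circ", "D_omega", "D_circ", "D_lambda"):
            v = getattr(self, name)
            if np.isfinite(v) and v < -1e-12 * max(1.0, abs(v)):
                raise ValueError(f"{name} must be nonnegative, got {v}")

    @property
    def E_total(self) -> float:
        return self.E_omega + self.E_circ


def energy_report(trajectory, n: int) -> EnergyReport:
    """Extract the energy bookkeeping of step ``n`` of a trajectory."""
    tr = trajectory
    res = np.nan
    if n >= 1:
        dt = tr.t[n] - tr.t[n - 1]
        E1 = tr.E_omega[n] + tr.E_circ[n]
        E0 = tr.E_omega[n - 1] + tr.E_circ[n - 1]
        F = tr.work_omega[n] + tr.work_boundary[n] + tr.work_circuit[n]
        D = tr.D_omega[n] + tr.D_circ[n] + tr.D_lambda[n]
        res = F - (E1 - E0) / dt - D
    return EnergyReport(
        t=float(tr.t[n]),
        E_omega=float(tr.E_omega[n]),
        E_circ=float(tr.E_circ[n]),
        D_omega=float(tr.D_omega[n]),
        D_circ=float(tr.D_circ[n]),
        D_lambda=float(tr.D_lambda[n]),
        work_omega=float(tr.work_omega[n]),
        work_boundary=float(tr.work_boundary[n]),
        work_circuit=float(tr.work_circuit[n]),
        residual=float(res),
    )


def elastic_energy(fields: BiotFields) -> float:
    """E_Omega(u) = lam/2 ||div u||^2 + mu ||E(u)||^2 = 1/2 u^T A_e u."""
    u = fields.u
    return 0.5 * float(u @ (fields.fe.A_e @ u))


def darcy_dissipation(fields: BiotFields) -> float:
    """D_Omega(p) = ||k^{1/2} grad p||^2 (with the effective permeability)."""
    p = fields.p
    fe = fields.fe
    return fe.k_eff * float(p @ (fe.K_p @ p))


def connection_dissipation(
    variant: str,
    fields: BiotFields | None,
    pi: float,
    spec: CouplingSpec,
    Q: float | None = None,
) -> float:
    """Dissipation in the connecting resistor.

    ppc: R Q^2;  ipc: (1/K) int_Sigma (p - pi)^2 dSigma.
    """
    if variant == "ppc":
        if Q is None:
            raise ValueError("ppc connection dissipation needs Q")
        return spec.R * Q * Q
    if variant == "ipc":
        if fields is None:
            raise ValueError("ipc connection dissipation needs the pressure trace")
        fe = fields.fe
        p = fields.p
        return (
            float(p @ (fe.M_sigma @ p)) - 2.0 * pi * float(fe.w_sigma @ p) + pi * pi * fe.m_sigma
        ) / spec.K
    raise ValueError(f"unknown variant {variant!r}")


def ipc_connection_identity_gap(fe, p: np.ndarray, pi: float, spec: CouplingSpec) -> float:
    """Gap between the two algebraic forms of the integral-variant D_Lambda.

    (1/R) pi^2 + (1/K) ||p||^2_Sigma - 2 P pi / R  ==  (1/K) int_Sigma (p-pi)^2
    whenever P is the Sigma-mean of p; returns the difference (0 to roundoff).
    """
    P = float(fe.w_sigma @ p) / fe.m_sigma
    lhs = pi * pi / spec.R + float(p @ (fe.M_sigma @ p)) / spec.K - 2.0 * P * pi / spec.R
    rhs = (
        float(p @ (fe.M_sigma @ p)) - 2.0 * pi * float(fe.w_sigma @ p) + pi * pi * fe.m_sigma
    ) / spec.K
    return lhs - rhs


def step1_identity_residual(
    fe,
    spec: CouplingSpec,
    variant: str,
    dt: float,
    u0: np.ndarray,
    u1: np.ndarray,
    p1: np.ndarray,
    pi0: float,
    pi1: float,
    P: float,
    Q: float,
    loads: dict,
) -> float:
    """Exact discrete energy identity of the Biot + connection substep.

    With the backward Euler defects written out, the substep satisfies

      [E_Omega(u1) + C/2 pi1^2 - E_Omega(u0) - C/2 pi0^2]/dt
        + 1/(2 dt) (u1-u0)^T A_e (u1-u0) + C/(2 dt) (pi1-pi0)^2
        + D_Omega(p1) + D_Lambda - F(g, psi, F, S; du/dt, p1)  =  0

    to linear-solver tolerance; the returned value is the left-hand side.
    """
    du = u1 - u0
    dE = 0.5 * (u1 @ (fe.A_e @ u1)) - 0.5 * (u0 @ (fe.A_e @ u0))
    dE += 0.5 * spec.C * (pi1 * pi1 - pi0 * pi0)
    defect = 0.5 * (du @ (fe.A_e @ du)) + 0.5 * spec.C * (pi1 - pi0) ** 2
    d_omega = fe.k_eff * float(p1 @ (fe.K_p @ p1))
    fields = BiotFields(fe=fe, u=u1, p=p1)
    d_lambda = connection_dissipation(variant, fields, pi1, spec, Q=Q)
    work = float((loads["f_F"] + loads["f_g"]) @ du) / dt
    work += float((loads["f_S"] - loads["f_psi"]) @ p1)
    return (dE + defect) / dt + d_omega + d_lambda - work


def audit_energy_identity(trajectory) -> np.ndarray:
    """Per-step defect of the total discrete energy balance.

    residual_n = F_n - (E_n - E_{n-1})/dt - D_n  (n >= 1); nonnegative up to
    roundoff for the unforced splitting scheme, O(dt) for smooth forcing.
    """
    tr = trajectory
    dt = np.diff(tr.t)
    E = tr.E_omega + tr.E_circ
    D = tr.D_omega[1:] + tr.D_circ[1:] + tr.D_lambda[1:]
    F = tr.work_omega[1:] + tr.work_boundary[1:] + tr.work_circuit[1:]
    return F - np.diff(E) / dt - D
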