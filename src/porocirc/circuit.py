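"""Lumped (0D) hydraulic circuit: state-space model, energetics, and time stepping.

A hydraulic network of linear, time-invariant resistors, capacitors and
inductors is described -- by analogy with electrical circuits -- through the
state vector

    y(t) = (pi, Pi_1 .. Pi_nC, Q_1 .. Q_nL)  in  R^d,  d = 1 + nC + nL,

where ``pi`` is the pressure at the node connecting the internal circuit to
the poroelastic interface, ``Pi_j`` are capacitor pressure differences (Pa)
and ``Q_i`` are inductor flow rates (m^3/s).  The dynamics are the linear ODE

    dy/dt = A y + s(t) + b Q(t),        b = e_1 / C,

where ``Q(t)`` is the volumetric flow rate entering through the connecting
resistor and ``s(t)`` collects the pressure/flow sources of the internal
circuit.  The diagonal matrix ``U = diag(C, C_1, .., L_1, ..)`` of
capacitances and inductances defines the stored energy ``1/2 y^T U y`` and
the dissipation quadratic form ``y^T B y`` with ``B = -U A`` (passivity:
the symmetric part of B is positive semidefinite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "CircuitModel",
    "CircuitState",
    "assemble_example_circuit",
    "circuit_energy",
    "circuit_dissipation",
    "passivity_margin",
    "solve_circuit_exact",
    "step_circuit_be",
]


SourceFn = Callable[[float], np.ndarray]


@dataclass(frozen=True)
class CircuitModel:
    """State-space form of a lumped RCL hydraulic circuit.

    Parameters
    ----------
    A : (d, d) array
        Constant system matrix (entries in 1/s); depends on the circuit
        graph and the R, C, L values.
    U : (d, d) array
        Diagonal positive matrix of capacitances and inductances.
    source_fn : callable
        ``s(t) -> (d,)`` vector of pressure/flow sources.
    connection_capacitance : float
        The capacitance C grounding the connecting node; the interface flow
        enters the ODE as ``b Q`` with ``b = e_1 / C``.
    params : dict
        Optional named parameters (R_bar, R1, C, C1, L1, ...) of the
        concrete instance, kept for reporting.
    """

    A: np.ndarray
    U: np.ndarray
    source_fn: SourceFn
    connection_capacitance: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        U = np.asarray(self.U, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("A must be square")
        if U.shape != A.shape:
            raise ValueError("U must have the same shape as A")
        if not np.allclose(U, np.diag(np.diag(U))):
            raise ValueError("U must be diagonal")
        if np.any(np.diag(U) <= 0.0):
            raise ValueError("U must have strictly positive diagonal entries")
        if self.connection_capacitance <= 0.0:
            raise ValueError("connection capacitance must be positive")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "U", U)

    @property
    def d(self) -> int:
        return self.A.shape[0]

    @property
    def B(self) -> np.ndarray:
        """Dissipation matrix B = -U A."""
        return -self.U @ self.A

    @property
    def e1(self) -> np.ndarray:
        e = np.zeros(self.d)
        e[0] = 1.0
        return e

    def b_vector(self, Q: float) -> np.ndarray:
        """Interface forcing b Q = (Q / C) e_1."""
        return (Q / self.connection_capacitance) * self.e1

    def s(self, t: float) -> np.ndarray:
        s = np.asarray(self.source_fn(t), dtype=float)
        if s.shape != (self.d,):
            raise ValueError(f"source_fn must return shape ({self.d},)")
        return s


@dataclass(frozen=True)
class CircuitState:
    """Circuit state ``y`` at time ``t``; y = (pi, Pi_1.., Q_1..)."""

    t: float
    y: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        if y.ndim != 1:
            raise ValueError("y must be a vector")
        if not np.all(np.isfinite(y)):
            raise ValueError("y must be finite")
        object.__setattr__(self, "y", y)

    @property
    def pi(self) -> float:
        return float(self.y[0])


def assemble_example_circuit(
    R_bar: float,
    R1: float,
    C: float,
    C1: float,
    L1: float,
    p_bar: Callable[[float], float] | float = 0.0,
) -> CircuitModel:
    """Build the series R_bar--C1--R1--L1 circuit grounded through C.

    The internal circuit has a pressure source ``p_bar(t)`` behind the
    resistor ``R_bar``, one capacitor ``C1`` to ground, and an inductor
    ``L1`` in series with the resistor ``R1`` leading to the connecting
    node, which is grounded through the connection capacitor ``C``.  State
    vector: y = (pi, pi_1, Q_1).
    """
    for name, val in (("R_bar", R_bar), ("R1", R1), ("C", C), ("C1", C1), ("L1", L1)):
        if val <= 0.0:
            raise ValueError(f"circuit parameter {name} must be positive, got {val}")
    A = np.array(
        [
            [0.0, 0.0, -1.0 / C],
            [0.0, -1.0 / (R_bar * C1), 1.0 / C1],
            [1.0 / L1, -1.0 / L1, -R1 / L1],
        ]
    )
    U = np.diag([C, C1, L1])
    pb = p_bar if callable(p_bar) else (lambda t, _v=float(p_bar): _v)

    def source(t: float) -> np.ndarray:
        return np.array([0.0, pb(t) / (R_bar * C1), 0.0])

    return CircuitModel(
        A=A,
        U=U,
        source_fn=source,
        connection_capacitance=C,
        params={"R_bar": R_bar, "R1": R1, "C": C, "C1": C1, "L1": L1, "p_bar": pb},
    )


def circuit_energy(U: np.ndarray, y: np.ndarray) -> float:
    """Stored energy 1/2 y^T U y (capacitors + inductors)."""
    U = np.asarray(U, dtype=float)
    y = np.asarray(y, dtype=float)
    if U.shape != (y.size, y.size):
        raise ValueError("dimension mismatch between U and y")
    return 0.5 * float(y @ (U @ y))


def circuit_dissipation(B: np.ndarray, y: np.ndarray) -> float:
    """Dissipation quadratic form y^T B y with B = -U A."""
    B = np.asarray(B, dtype=float)
    y = np.asarray(y, dtype=float)
    if B.shape != (y.size, y.size):
        raise ValueError("dimension mismatch between B and y")
    return float(y @ (B @ y))


def passivity_margin(model: CircuitModel) -> float:
    """Smallest eigenvalue of sym(B) relative to ||B||.

    Nonnegative (to roundoff) for passive circuits.  The series example
    circuit is only positive *semi*definite: the form vanishes on states
    with pi != 0, Pi_1 = Q_1 = 0.
    """
    B = model.B
    Bs = 0.5 * (B + B.T)
    scale = np.linalg.norm(B, 2)
    if scale == 0.0:
        return 0.0
    return float(np.linalg.eigvalsh(Bs).min() / scale)


def _expm_with_integral(A: np.ndarray, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (e^{Ah}, int_0^h e^{A tau} d tau), valid for singular A.

    Uses the block-triangular augmentation expm([[A, I], [0, 0]] h) whose
    top-right block is the integral.
    """
    d = A.shape[0]
    M = np.zeros((2 * d, 2 * d))
    M[:d, :d] = A
    M[:d, d:] = np.eye(d)
    E = expm(M * h)
    return E[:d, :d], E[:d, d:]


def solve_circuit_exact(
    model: CircuitModel,
    Q_fn: Callable[[float], float] | None,
    y0: np.ndarray,
    t_grid: Sequence[float],
    micro_points: int = 10_000,
) -> list[CircuitState]:
    """Evaluate the variation-of-constants solution on ``t_grid``.

    y(t) = e^{At} y0 + int_0^t e^{A(t-tau)} (s(tau) + b Q(tau)) d tau.

    The forcing ``s + bQ`` is treated as piecewise constant on a uniform
    micro-grid of ``micro_points`` subintervals spanning the full time range
    (sampled at midpoints), and each piece is propagated exactly with the
    matrix exponential.  Serves as the oracle for the backward Euler stepper.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    y = np.asarray(y0, dtype=float).copy()
    if y.shape != (model.d,):
        raise ValueError("y0 has wrong dimension")
    Q = Q_fn if Q_fn is not None else (lambda t: 0.0)

    T = t_grid[-1] - t_grid[0]
    t = float(t_grid[0])
    states = [CircuitState(t=t, y=y.copy())]
    cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for t_next in t_grid[1:]:
        span = float(t_next - t)
        m = max(1, int(round(micro_points * span / T))) if T > 0 else 1
        h = span / m
        key = round(h, 15)
        if key not in cache:
            cache[key] = _expm_with_integral(model.A, h)
        E, Phi = cache[key]
        for j in range(m):
            tm = t + (j + 0.5) * h
            f = model.s(tm) + model.b_vector(float(Q(tm)))
            y = E @ y + Phi @ f
        t = float(t_next)
        states.append(CircuitState(t=t, y=y.copy()))
    return states


def step_circuit_be(
    model: CircuitModel,
    y_n: np.ndarray,
    Q_value: float,
    dt: float,
    t_next: float,
) -> np.ndarray:
    """One backward Euler step: (I - dt A) y_{n+1} = y_n + dt (s(t_{n+1}) + b Q)."""
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    y_n = np.asarray(y_n, dtype=float)
    M = np.eye(model.d) - dt * model.A
    rhs = y_n + dt * (model.s(t_next) + model.b_vector(Q_value))
    # For passive circuits I - dt A is nonsingular for every dt > 0.
    y_next = np.linalg.solve(M, rhs)
    if not np.all(np.isfinite(y_next)):
        raise FloatingPointError("backward Euler circuit step produced non-finite state")
    return y_next
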