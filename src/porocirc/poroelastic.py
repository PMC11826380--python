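"""Quasi-static Biot poroelasticity on a box domain (3D) and in 1D.

The tissue is a fluid-saturated deformable porous medium with incompressible
constituents (storage coefficient c0 = 0, Biot-Willis alpha = 1).  Unknowns
are the solid displacement u and the pore pressure p:

    -mu_e Lap(u) - (lambda_e + mu_e) grad(div u) + grad p = F,
    d/dt (div u) - div(k grad p) = S,

equivalently div T + F = 0 and d/dt(div u) + div v = S with total stress
T = 2 mu_e E(u) + lambda_e (div u) I - p I and discharge (Darcy) velocity
v = -k grad p.  Time discretization is backward Euler; space discretization
is an equal-order conforming Q1-Q1 pair on a structured hexahedral grid of
the box.  On this tensor-product mesh, data that depend on x only produce a
discrete solution that is exactly one-dimensional, which the interface
studies rely on.

Boundary labels (per box face):

=============  =========================================================
``neumann``    T n = g (traction), v.n = 0
``dirichlet_p``  u = 0, p = 0
``dirichlet_v``  u = 0, v.n = psi (prescribed normal discharge)
``slip``       u.n = 0, zero tangential traction, v.n = 0
``interface``  u = 0; pressure/flux handled by the coupling module
=============  =========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import scipy.sparse as sp

__all__ = [
    "PoroParams",
    "Geometry",
    "ForcingData",
    "BiotFields",
    "BoxMesh",
    "build_mesh_box",
    "BiotBox3D",
    "Biot1D",
    "BiotStepSystem",
    "assemble_biot",
    "assemble_biot_1d",
    "eval_stress",
    "eval_velocity",
    "FACES",
    "LABELS",
]

FACES = ("x-", "x+", "y-", "y+", "z-", "z+")
LABELS = ("neumann", "dirichlet_p", "dirichlet_v", "slip", "interface")
_FACE_AXIS = {"x-": 0, "x+": 0, "y-": 1, "y+": 1, "z-": 2, "z+": 2}

DEFAULT_FACE_LABELS: Mapping[str, str] = {
    "x-": "neumann",
    "x+": "interface",
    "y-": "slip",
    "y+": "slip",
    "z-": "slip",
    "z+": "slip",
}


@dataclass(frozen=True)
class PoroParams:
    """Material constants of the incompressible-constituent Biot model.

    lam, mu : Lame parameters (Pa); k : permeability (m^4 N^-1 s^-1).
    alpha = 1 and c0 = 0 are fixed by the incompressibility assumption.
    The 1D confined-compression stiffness is the aggregate modulus
    H_A = lam + 2 mu.
    """

    lam: float
    mu: float
    k: float

    alpha: float = field(default=1.0, init=False)
    c0: float = field(default=0.0, init=False)

    def __post_init__(self) -> None:
        if self.mu <= 0.0:
            raise ValueError("shear modulus mu must be positive")
        if self.lam < 0.0:
            raise ValueError("first Lame parameter lam must be nonnegative")
        if self.k <= 0.0:
            raise ValueError("permeability k must be positive")

    @property
    def H_A(self) -> float:
        return self.lam + 2.0 * self.mu


@dataclass(frozen=True)
class Geometry:
    """Box domain (0,c) x (-a/2,a/2) x (-b/2,b/2) with labelled faces."""

    c: float
    a: float
    b: float
    face_labels: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_FACE_LABELS))

    def __post_init__(self) -> None:
        if min(self.c, self.a, self.b) <= 0.0:
            raise ValueError("box dimensions must be positive")
        labels = dict(self.face_labels)
        if set(labels) != set(FACES):
            raise ValueError(f"face_labels must assign exactly the faces {FACES}")
        for f, lab in labels.items():
            if lab not in LABELS:
                raise ValueError(f"unknown boundary label {lab!r} on face {f}")
        n_if = sum(1 for v in labels.values() if v == "interface")
        if n_if > 1 or (n_if == 1 and labels.get("x+") != "interface"):
            raise ValueError("the coupling interface must be the single face x = c")
        object.__setattr__(self, "face_labels", labels)

    @property
    def has_interface(self) -> bool:
        return "interface" in self.face_labels.values()

    @property
    def m_sigma(self) -> float:
        """Area of the interface face x = c."""
        return self.a * self.b


@dataclass
class ForcingData:
    """Volume/boundary forcing and initial data.

    All spatial callables must be numpy-vectorized: they receive an (n, 3)
    array of points and the time, and return (n,) (scalar data) or (n, 3)
    (vector data).  For the 1D model, ``g`` is a scalar function of time
    (total axial traction at x = 0) and ``chi`` an initial strain profile.
    """

    F: Callable | None = None            # body force (N/m^3), (x, t) -> (n, 3)
    S: Callable | None = None            # fluid source (1/s), (x, t) -> (n,)
    g: Callable | None = None            # traction on Gamma_N; 3D: (x, t) -> (n, 3); 1D: t -> float
    psi: Mapping[str, Callable] = field(default_factory=dict)  # normal discharge per dirichlet_v face
    u0: np.ndarray | Callable | None = None
    y0: np.ndarray | None = None
    chi: Callable | None = None          # 1D initial strain du/dx(x, 0)


# ---------------------------------------------------------------------------
# Mesh
# ---------------------------------------------------------------------------

# Kuhn split of the reference hexahedron (VTK vertex ordering) into 6 tets
# sharing the 0-6 diagonal.
_KUHN_TETS = ((0, 1, 2, 6), (0, 2, 3, 6), (0, 3, 7, 6), (0, 7, 4, 6), (0, 4, 5, 6), (0, 5, 1, 6))


@dataclass
class BoxMesh:
    geometry: Geometry
    nx: int
    ny: int
    nz: int
    points: np.ndarray           # (N, 3)
    cells: np.ndarray            # (ncell, 8) hexes or (ncell, 4) tets
    cell_type: str               # "hexahedron" | "tetra"
    face_nodes: dict             # face -> unique node ids
    face_quads: dict             # face -> (nq, 4) node ids of boundary quadrilaterals

    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    @property
    def h(self) -> tuple[float, float, float]:
        g = self.geometry
        return (g.c / self.nx, g.a / self.ny, g.b / self.nz)

    def node_grid_id(self, i, j, k):
        return i + (self.nx + 1) * (j + (self.ny + 1) * k)

    def cell_volumes(self) -> np.ndarray:
        if self.cell_type == "hexahedron":
            hx, hy, hz = self.h
            return np.full(self.cells.shape[0], hx * hy * hz)
        p = self.points[self.cells]
        a, b, c = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
        return np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0


def build_mesh_box(geometry: Geometry, resolution, cell_type: str = "hexahedron") -> BoxMesh:
    """Structured mesh of the box with face tags matching the boundary partition.

    ``resolution`` is an int (cells per axis) or a (nx, ny, nz) triple.
    ``cell_type="tetra"`` splits each hexahedron into 6 tetrahedra (the Biot
    assembler itself operates on the hexahedral mesh).
    """
    if np.isscalar(resolution):
        nx = ny = nz = int(resolution)
    else:
        nx, ny, nz = (int(r) for r in resolution)
    if min(nx, ny, nz) < 1:
        raise ValueError("resolution must be at least 1 cell per axis")
    g = geometry
    x = np.linspace(0.0, g.c, nx + 1)
    y = np.linspace(-g.a / 2, g.a / 2, ny + 1)
    z = np.linspace(-g.b / 2, g.b / 2, nz + 1)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    # node id = i + (nx+1)*(j + (ny+1)*k)
    points = np.stack(
        [X.transpose(2, 1, 0).ravel(), Y.transpose(2, 1, 0).ravel(), Z.transpose(2, 1, 0).ravel()],
        axis=1,
    )

    def nid(i, j, k):
        return i + (nx + 1) * (j + (ny + 1) * k)

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    hexes = np.stack(
        [
            nid(I, J, K), nid(I + 1, J, K), nid(I + 1, J + 1, K), nid(I, J + 1, K),
            nid(I, J, K + 1), nid(I + 1, J, K + 1), nid(I + 1, J + 1, K + 1), nid(I, J + 1, K + 1),
        ],
        axis=1,
    )

    face_nodes = {}
    face_quads = {}
    ii = np.arange(nx + 1)
    jj = np.arange(ny + 1)
    kk = np.arange(nz + 1)

    def face_grid(face):
        if face in ("x-", "x+"):
            i = 0 if face == "x-" else nx
            Jf, Kf = np.meshgrid(jj, kk, indexing="ij")
            return nid(i, Jf, Kf)
        if face in ("y-", "y+"):
            j = 0 if face == "y-" else ny
            If, Kf = np.meshgrid(ii, kk, indexing="ij")
            return nid(If, j, Kf)
        i = 0 if face == "z-" else nz
        If, Jf = np.meshgrid(ii, jj, indexing="ij")
        return nid(If, Jf, i)

    for f in FACES:
        grid = face_grid(f)
        face_nodes[f] = grid.ravel()
        q = np.stack(
            [grid[:-1, :-1].ravel(), grid[1:, :-1].ravel(), grid[1:, 1:].ravel(), grid[:-1, 1:].ravel()],
            axis=1,
        )
        face_quads[f] = q

    if cell_type == "hexahedron":
        cells = hexes
    elif cell_type == "tetra":
        cells = np.concatenate([hexes[:, list(t)] for t in _KUHN_TETS], axis=0)
    else:
        raise ValueError(f"unknown cell_type {cell_type!r}")

    return BoxMesh(
        geometry=g, nx=nx, ny=ny, nz=nz, points=points, cells=cells,
        cell_type=cell_type, face_nodes=face_nodes, face_quads=face_quads,
    )


# ---------------------------------------------------------------------------
# Q1 reference element
# ---------------------------------------------------------------------------

_LOCAL_COORDS = np.array(
    [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]],
    dtype=float,
)


def _shape_q1(xi):
    """Trilinear shape functions and reference gradients at points xi (n, 3)."""
    xi = np.atleast_2d(xi)
    n = xi.shape[0]
    N = np.ones((n, 8))
    dN = np.zeros((n, 8, 3))
    for a in range(8):
        la = _LOCAL_COORDS[a]
        facs = np.stack([xi[:, d] if la[d] == 1 else 1.0 - xi[:, d] for d in range(3)], axis=1)
        N[:, a] = facs.prod(axis=1)
        for d in range(3):
            sign = 1.0 if la[d] == 1 else -1.0
            others = [e for e in range(3) if e != d]
            dN[:, a, d] = sign * facs[:, others[0]] * facs[:, others[1]]
    return N, dN


def _gauss2_unit():
    g = 0.5 - 0.5 / np.sqrt(3.0)
    pts1 = np.array([g, 1.0 - g])
    P = np.array([[a, b, c] for a in pts1 for b in pts1 for c in pts1])
    w = np.full(8, 0.125)
    return P, w


def _element_matrices(hx, hy, hz, lam, mu):
    """Exact (2x2x2 Gauss) Q1 element matrices on an hx*hy*hz brick."""
    P, w = _gauss2_unit()
    N, dNr = _shape_q1(P)
    detJ = hx * hy * hz
    dN = dNr / np.array([hx, hy, hz])          # physical gradients, (8q, 8a, 3)
    Ke = np.zeros((24, 24))
    De = np.zeros((8, 24))
    Kp = np.zeros((8, 8))
    Mp = np.zeros((8, 8))
    for q in range(P.shape[0]):
        wq = w[q] * detJ
        G = dN[q]                               # (8, 3)
        Nq = N[q]
        Kp += wq * (G @ G.T)
        Mp += wq * np.outer(Nq, Nq)
        for a in range(8):
            for b in range(8):
                gab = G[a] @ G[b]
                for i in range(3):
                    for j in range(3):
                        val = mu * ((gab if i == j else 0.0) + G[a][j] * G[b][i])
                        val += lam * G[a][i] * G[b][j]
                        Ke[3 * a + i, 3 * b + j] += wq * val
        for a in range(8):
            for b in range(8):
                for j in range(3):
                    De[a, 3 * b + j] += wq * Nq[a] * G[b][j]
    return Ke, De, Kp, Mp


def _face_mass(h1, h2):
    """4x4 bilinear face mass matrix on an h1*h2 quadrilateral."""
    # exact: tensor product of 1D P1 mass matrices
    m1 = np.array([[2.0, 1.0], [1.0, 2.0]]) / 6.0
    M1 = m1 * h1
    M2 = m1 * h2
    # face node ordering (0,0),(1,0),(1,1),(0,1) in local (s1, s2)
    order = [(0, 0), (1, 0), (1, 1), (0, 1)]
    Mf = np.zeros((4, 4))
    for a, (ia, ja) in enumerate(order):
        for b, (ib, jb) in enumerate(order):
            Mf[a, b] = M1[ia, ib] * M2[ja, jb]
    return Mf


def _assemble_constant(Ae, row_dofs, col_dofs, shape):
    """COO assembly of identical element matrix Ae over cells.

    row_dofs, col_dofs: (ne, nr) and (ne, nc) global dof arrays.
    """
    ne = row_dofs.shape[0]
    nr, nc = Ae.shape
    rows = np.repeat(row_dofs[:, :, None], nc, axis=2).ravel()
    cols = np.repeat(col_dofs[:, None, :], nr, axis=1).ravel()
    data = np.tile(Ae.ravel(), ne)
    return sp.coo_matrix((data, (rows, cols)), shape=shape).tocsr()


# ---------------------------------------------------------------------------
# 3D assembler
# ---------------------------------------------------------------------------


class BiotBox3D:
    """Q1-Q1 finite element discretization of quasi-static Biot on a box.

    Exposes the block matrices of the one-step backward Euler system

        [ A_e   -D^T ] [u^{n+1}]   [ f_u           ]
        [ D   dt*Kk  ] [p^{n+1}] = [ D u^n + dt f_p]   (+ interface terms),

    together with interface quadrature objects (M_sigma, w_sigma, m_sigma)
    used by the coupling module.  ``stabilization`` (delta >= 0) adds a
    Brezzi-Pitkaranta-type term delta*h^2 to the effective permeability,
    equivalent to a consistent permeability perturbation; the default 0 is
    adequate whenever k*dt is not vanishingly small.
    """

    dim = 3

    def __init__(self, mesh: BoxMesh, params: PoroParams, stabilization: float = 0.0):
        if mesh.cell_type != "hexahedron":
            raise ValueError("the Biot assembler requires a hexahedral mesh")
        self.mesh = mesh
        self.params = params
        self.geometry = mesh.geometry
        hx, hy, hz = mesh.h
        self.k_eff = params.k + stabilization * ((hx * hx + hy * hy + hz * hz) / 3.0)

        N = mesh.n_nodes
        self.n_nodes = N
        self.ndof_u = 3 * N
        self.ndof_p = N

        Ke, De, Kp, Mp = _element_matrices(hx, hy, hz, params.lam, params.mu)
        cells = mesh.cells
        udofs = (3 * cells[:, :, None] + np.arange(3)[None, None, :]).reshape(cells.shape[0], 24)
        pdofs = cells
        self.A_e = _assemble_constant(Ke, udofs, udofs, (3 * N, 3 * N))
        self.Dmat = _assemble_constant(De, pdofs, udofs, (N, 3 * N))
        self.K_p = _assemble_constant(Kp, pdofs, pdofs, (N, N))      # unit permeability
        self.M_p = _assemble_constant(Mp, pdofs, pdofs, (N, N))

        # boundary face mass matrices per label
        g = mesh.geometry
        hface = {"x": (hy, hz), "y": (hx, hz), "z": (hx, hy)}
        self.face_mass: dict[str, sp.csr_matrix] = {}
        for f in FACES:
            h1, h2 = hface[f[0]]
            Mf = _face_mass(h1, h2)
            quads = mesh.face_quads[f]
            self.face_mass[f] = _assemble_constant(Mf, quads, quads, (N, N))

        self.labels = dict(g.face_labels)
        self.has_interface = g.has_interface
        if self.has_interface:
            self.M_sigma = self.face_mass["x+"]
            self.w_sigma = np.asarray(self.M_sigma.sum(axis=1)).ravel()
            self.m_sigma = float(self.w_sigma.sum())
            self.sigma_p_nodes = mesh.face_nodes["x+"]
        else:
            self.M_sigma = sp.csr_matrix((N, N))
            self.w_sigma = np.zeros(N)
            self.m_sigma = 0.0
            self.sigma_p_nodes = np.array([], dtype=int)

        self._build_constraints()
        # centroid gradient operator for per-cell stress/velocity evaluation
        _, dNr = _shape_q1(np.array([[0.5, 0.5, 0.5]]))
        self._grad_centroid = dNr[0] / np.array([hx, hy, hz])  # (8, 3)

    def _build_constraints(self) -> None:
        mesh = self.mesh
        u_fixed = np.zeros(self.ndof_u, dtype=bool)
        p_fixed = np.zeros(self.ndof_p, dtype=bool)
        for f, lab in self.labels.items():
            nodes = mesh.face_nodes[f]
            if lab in ("dirichlet_p", "dirichlet_v", "interface"):
                for c in range(3):
                    u_fixed[3 * nodes + c] = True
            elif lab == "slip":
                u_fixed[3 * nodes + _FACE_AXIS[f]] = True
            if lab == "dirichlet_p":
                p_fixed[nodes] = True
        self.u_fixed = u_fixed
        self.p_fixed = p_fixed
        self.u_free = np.where(~u_fixed)[0]
        self.p_free_mask = ~p_fixed
        self.p_free = np.where(self.p_free_mask)[0]

    # -- forcing -----------------------------------------------------------

    def loads(self, forcing: ForcingData, t: float) -> dict[str, np.ndarray]:
        """Consistent load vectors at time t: f_F, f_g (3N,), f_S, f_psi (N,).

        Smooth data are interpolated nodally and integrated with the
        consistent mass matrices (second-order accurate for Q1).
        """
        N = self.n_nodes
        pts = self.mesh.points
        f_F = np.zeros(3 * N)
        f_g = np.zeros(3 * N)
        f_S = np.zeros(N)
        f_psi = np.zeros(N)
        if forcing.F is not None:
            Fv = np.asarray(forcing.F(pts, t), dtype=float)
            if Fv.shape != (N, 3):
                raise ValueError("F(x, t) must return an (n, 3) array")
            f_F = np.column_stack([self.M_p @ Fv[:, c] for c in range(3)]).ravel()
        if forcing.S is not None:
            f_S = self.M_p @ np.asarray(forcing.S(pts, t), dtype=float)
        if forcing.g is not None:
            for f, lab in self.labels.items():
                if lab != "neumann":
                    continue
                nodes = self.mesh.face_nodes[f]
                gv = np.zeros((N, 3))
                gv[nodes] = np.asarray(forcing.g(pts[nodes], t), dtype=float)
                for c in range(3):
                    f_g[c::3] += self.face_mass[f] @ gv[:, c]
        for f, psi_f in forcing.psi.items():
            if self.labels.get(f) != "dirichlet_v":
                raise ValueError(f"psi given on face {f!r} which is not dirichlet_v")
            nodes = self.mesh.face_nodes[f]
            pv = np.zeros(N)
            pv[nodes] = np.asarray(psi_f(pts[nodes], t), dtype=float)
            f_psi += self.face_mass[f] @ pv
        return {"f_F": f_F, "f_g": f_g, "f_S": f_S, "f_psi": f_psi}

    # -- field evaluation --------------------------------------------------

    def cell_gradients(self, p: np.ndarray) -> np.ndarray:
        """grad p at cell centroids, (ncell, 3)."""
        return np.einsum("ca,ad->cd", p[self.mesh.cells], self._grad_centroid)

    def cell_strain(self, u: np.ndarray) -> np.ndarray:
        """Symmetric gradient E(u) at cell centroids, (ncell, 3, 3)."""
        uc = u.reshape(-1, 3)[self.mesh.cells]              # (ncell, 8, 3)
        G = np.einsum("cai,ad->cid", uc, self._grad_centroid)  # grad u, (ncell, 3, 3)
        return 0.5 * (G + G.transpose(0, 2, 1))

    def interpolate_u0(self, u0) -> np.ndarray:
        if u0 is None:
            return np.zeros(self.ndof_u)
        if callable(u0):
            vals = np.asarray(u0(self.mesh.points), dtype=float)
            out = vals.ravel()
        else:
            out = np.asarray(u0, dtype=float).copy()
        if out.shape != (self.ndof_u,):
            raise ValueError("u0 has wrong shape")
        out[self.u_fixed] = 0.0
        return out


# ---------------------------------------------------------------------------
# 1D assembler
# ---------------------------------------------------------------------------


class Biot1D:
    """P1 finite elements for the 1D confined-compression Biot column.

    The column occupies [0, c] with cross-section area a*b; all integrals
    carry the cross-section factor so that energies, fluxes and interface
    quantities coincide with those of the 3D box under x-only data.  The
    stress is T = H_A du/dx - p; boundary conditions at x = 0 are T = g(t)
    and v = 0; the end x = c is the coupling interface (u = 0) unless
    ``sealed`` is set, in which case u = 0, p = 0 there.
    """

    dim = 1

    def __init__(self, geometry: Geometry, params: PoroParams, n_cells: int, sealed: bool = False):
        if n_cells < 1:
            raise ValueError("need at least one cell")
        self.geometry = geometry
        self.params = params
        self.sealed = sealed
        self.n_cells = n_cells
        c = geometry.c
        self.x = np.linspace(0.0, c, n_cells + 1)
        self.hx = c / n_cells
        area = geometry.a * geometry.b
        self.area = area
        n = n_cells + 1
        self.n_nodes = n
        self.ndof_u = n
        self.ndof_p = n
        self.k_eff = params.k

        h = self.hx
        e_k = np.array([[1.0, -1.0], [-1.0, 1.0]]) / h
        e_m = np.array([[2.0, 1.0], [1.0, 2.0]]) * h / 6.0
        e_d = np.array([[-0.5, 0.5], [-0.5, 0.5]])     # D[a,b] = int N_a N_b'
        cells = np.stack([np.arange(n_cells), np.arange(1, n_cells + 1)], axis=1)
        self.A_e = _assemble_constant(area * params.H_A * e_k, cells, cells, (n, n))
        self.Dmat = _assemble_constant(area * e_d, cells, cells, (n, n))
        self.K_p = _assemble_constant(area * e_k, cells, cells, (n, n))  # unit permeability
        self.M_p = _assemble_constant(area * e_m, cells, cells, (n, n))

        self.has_interface = not sealed
        self.m_sigma = area if not sealed else 0.0
        w = np.zeros(n)
        if not sealed:
            w[-1] = area
        self.w_sigma = w
        self.M_sigma = sp.diags(w).tocsr()
        self.sigma_p_nodes = np.array([n - 1]) if not sealed else np.array([], dtype=int)

        u_fixed = np.zeros(n, dtype=bool)
        p_fixed = np.zeros(n, dtype=bool)
        u_fixed[-1] = True                      # u(c) = 0 in both modes
        if sealed:
            p_fixed[-1] = True
        self.u_fixed = u_fixed
        self.p_fixed = p_fixed
        self.u_free = np.where(~u_fixed)[0]
        self.p_free_mask = ~p_fixed
        self.p_free = np.where(self.p_free_mask)[0]

    def loads(self, forcing: ForcingData, t: float) -> dict[str, np.ndarray]:
        n = self.n_nodes
        f_F = np.zeros(n)
        f_g = np.zeros(n)
        f_S = np.zeros(n)
        f_psi = np.zeros(n)
        pts = np.column_stack([self.x, np.zeros(n), np.zeros(n)])
        if forcing.F is not None:
            Fv = np.asarray(forcing.F(pts, t), dtype=float)
            if Fv.ndim == 2:
                Fv = Fv[:, 0]
            f_F = self.M_p @ Fv
        if forcing.S is not None:
            f_S = self.M_p @ np.asarray(forcing.S(pts, t), dtype=float)
        if forcing.g is not None:
            # total-stress traction at x = 0: contributes -g(t) * area * w(0)
            f_g[0] = -self.area * float(forcing.g(t))
        return {"f_F": f_F, "f_g": f_g, "f_S": f_S, "f_psi": f_psi}

    def cell_gradients(self, p: np.ndarray) -> np.ndarray:
        return (np.diff(p) / self.hx)[:, None]

    def cell_strain(self, u: np.ndarray) -> np.ndarray:
        return (np.diff(u) / self.hx)[:, None, None]

    def interpolate_u0(self, u0) -> np.ndarray:
        if u0 is None:
            return np.zeros(self.ndof_u)
        if callable(u0):
            out = np.asarray(u0(self.x), dtype=float).copy()
        else:
            out = np.asarray(u0, dtype=float).copy()
        if out.shape != (self.ndof_u,):
            raise ValueError("u0 has wrong shape")
        out[self.u_fixed] = 0.0
        return out

    def u0_from_chi(self, chi: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
        """Displacement with strain chi and u(c) = 0: u(x) = -int_x^c chi."""
        strain = np.asarray(chi(0.5 * (self.x[:-1] + self.x[1:])), dtype=float)
        u = np.concatenate([[0.0], np.cumsum(strain * self.hx)])
        return u - u[-1]


# ---------------------------------------------------------------------------
# One-step system assembly
# ---------------------------------------------------------------------------


@dataclass
class BiotStepSystem:
    """Backward Euler one-step linear system, interface terms not yet applied.

    Full-dof block matrix over [u; p]; the coupling module appends/condenses
    interface unknowns and reduces to free dofs.
    """

    fe: object
    t: float
    dt: float
    u_prev: np.ndarray
    A: sp.csr_matrix
    rhs: np.ndarray
    loads: dict


def _assemble_step(fe, forcing: ForcingData, t: float, dt: float, u_prev: np.ndarray) -> BiotStepSystem:
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    u_prev = np.asarray(u_prev, dtype=float)
    if u_prev.shape != (fe.ndof_u,):
        raise ValueError("u_prev has wrong shape")
    loads = fe.loads(forcing, t)
    A = sp.bmat(
        [[fe.A_e, -fe.Dmat.T], [fe.Dmat, dt * fe.k_eff * fe.K_p]], format="csr"
    )
    rhs = np.concatenate(
        [
            loads["f_F"] + loads["f_g"],
            fe.Dmat @ u_prev + dt * loads["f_S"] - dt * loads["f_psi"],
        ]
    )
    return BiotStepSystem(fe=fe, t=t, dt=dt, u_prev=u_prev, A=A, rhs=rhs, loads=loads)


def assemble_biot(fe: BiotBox3D, forcing: ForcingData, t: float, dt: float, u_prev: np.ndarray) -> BiotStepSystem:
    """One implicit (backward Euler) step of the 3D Biot system.

    Natural and essential boundary conditions of the labelled faces are
    encoded in the system; interface terms on Sigma are left to the
    coupling module.
    """
    return _assemble_step(fe, forcing, t, dt, u_prev)


def assemble_biot_1d(fe: Biot1D, forcing: ForcingData, t: float, dt: float, u_prev: np.ndarray) -> BiotStepSystem:
    """One backward Euler step of the 1D column (primal u, p form)."""
    return _assemble_step(fe, forcing, t, dt, u_prev)


# ---------------------------------------------------------------------------
# Fields and derived quantities
# ---------------------------------------------------------------------------


@dataclass
class BiotFields:
    """Discrete displacement and pressure at one time level."""

    fe: object
    u: np.ndarray
    p: np.ndarray
    t: float = 0.0

    def velocity(self) -> np.ndarray:
        return eval_velocity(self, self.fe.params)

    def stress(self) -> np.ndarray:
        return eval_stress(self, self.fe.params)


def eval_velocity(fields: BiotFields, params: PoroParams) -> np.ndarray:
    """Discharge velocity v = -k grad p at cell centroids.

    3D: (ncell, 3); 1D: (ncell, 1) (x-component).
    """
    return -params.k * fields.fe.cell_gradients(fields.p)


def eval_stress(fields: BiotFields, params: PoroParams) -> np.ndarray:
    """Total stress T = 2 mu E(u) + lam (div u) I - p I at cell centroids.

    3D: (ncell, 3, 3).  1D: (ncell,) axial component H_A du/dx - p.
    """
    fe = fields.fe
    if fe.dim == 1:
        strain = fe.cell_strain(fields.u)[:, 0, 0]
        p_mid = 0.5 * (fields.p[:-1] + fields.p[1:])
        return params.H_A * strain - p_mid
    E = fe.cell_strain(fields.u)
    div = np.trace(E, axis1=1, axis2=2)
    cells = fe.mesh.cells
    p_mid = fields.p[cells].mean(axis=1)
    eye = np.eye(3)
    return 2.0 * params.mu * E + (params.lam * div - p_mid)[:, None, None] * eye
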