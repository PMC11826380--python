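import numpy as np
import pytest

from porocirc.poroelastic import Biot1D, BiotBox3D, Geometry, PoroParams, build_mesh_box
from porocirc.timeloop import TimeGrid, run_operator_splitting
from porocirc.verification import make_problem_1d


@pytest.fixture(scope="session")
def ref_params():
    return PoroParams(lam=0.5, mu=0.25, k=1.0)


@pytest.fixture(scope="session")
def ref_geometry():
    return Geometry(c=0.5, a=0.1, b=0.1)


@pytest.fixture(scope="session")
def small_mesh(ref_geometry):
    return build_mesh_box(ref_geometry, (6, 3, 3))


@pytest.fixture(scope="session")
def small_fe(small_mesh, ref_params):
    return BiotBox3D(small_mesh, ref_params)


@pytest.fixture(scope="session")
def fe_1d(ref_geometry, ref_params):
    return Biot1D(ref_geometry, ref_params, 32)


@pytest.fixture(scope="session")
def forced_1d_trajectories():
    """Identically forced 1D-0D runs under both interface variants."""
    p_bar = lambda t: 0.3 * np.sin(0.2 * np.pi * t)
    grid = TimeGrid(dt=0.02, t_end=4.0)
    out = {}
    for var in ("ppc", "ipc"):
        prob = make_problem_1d(variant=var, p_bar=p_bar, n_cells=64)
        out[var] = run_operator_splitting(prob, var, grid)
    return out
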