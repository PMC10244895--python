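"""Shared fixtures: small meshed-and-solved models reused across test modules.

Everything here is generated at test time from the synthetic generators; no
fixture files are stored.  Session scope keeps the FEM solves (the expensive
part) to one per shape.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import antfea as af
from antfea.fem import assemble_stiffness, solve_constrained


@pytest.fixture(scope="session")
def unit_square() -> af.Outline:
    return af.Outline(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float), name="square")


@pytest.fixture(scope="session")
def head_outline() -> af.Outline:
    """A mid-morphospace symmetric head shape (no noise)."""
    return af.generate_head_outline(
        af.HeadShapeParams(width_height_ratio=1.2, lobe_amplitude=0.2,
                           vertex_concavity=0.1, scale=1.0, seed=5))


@pytest.fixture(scope="session")
def head_mesh(head_outline) -> af.Mesh:
    return af.triangulate(head_outline, 0.035)


@pytest.fixture(scope="session")
def head_solution(head_mesh):
    """(mesh, loadcase, displacement, stress) for the standard head solve."""
    lc = af.build_load_case(head_mesh, 1.0, 45.0)
    disp = af.solve_linear_static(head_mesh, af.CUTICLE, lc)
    fld = af.recover_stress(head_mesh, af.CUTICLE, disp)
    return head_mesh, lc, disp, fld


def _solved_model(params: af.HeadShapeParams, name: str, density: float = 0.035):
    o = af.generate_head_outline(params, name=name)
    m = af.triangulate(o, density)
    lc = af.build_load_case(m, 1.0, 45.0)
    disp = af.solve_linear_static(m, af.CUTICLE, lc)
    fld = af.recover_stress(m, af.CUTICLE, disp)
    return o, m, lc, disp, fld


@pytest.fixture(scope="session")
def wide_narrow_pair():
    """Equal-area wide/heart-shaped vs narrow/rounded solved pair.

    Equal areas mean equal normalized side loads (1 N each), isolating the
    effect of shape on the stress distribution.
    """
    wide = _solved_model(af.HeadShapeParams(
        width_height_ratio=1.3, lobe_amplitude=0.25, vertex_concavity=0.15,
        scale=1.0, seed=11), "wide")
    narrow = _solved_model(af.HeadShapeParams(
        width_height_ratio=0.85, lobe_amplitude=0.0, vertex_concavity=0.0,
        scale=1.0, seed=12), "narrow")
    return wide, narrow


def consistent_edge_loads(mesh: af.Mesh, axis: int, value: float,
                          traction: tuple[float, float]) -> np.ndarray:
    """Work-consistent nodal forces for a uniform traction on the boundary
    edges lying on coord[axis] == value (quadratic edge weights 1/6, 4/6, 1/6).

    Test oracle helper, independent of the solver's load construction.
    """
    f = np.zeros(2 * mesh.n_nodes)
    on = np.isclose(mesh.nodes[:, axis], value, atol=1e-9)
    for e in range(mesh.n_elements):
        c = mesh.elements[e, :3]
        mids = mesh.elements[e, 3:]
        for k, (i, j) in enumerate(((c[0], c[1]), (c[1], c[2]), (c[2], c[0]))):
            if on[i] and on[j]:
                length = np.linalg.norm(mesh.nodes[j] - mesh.nodes[i])
                for node, w in ((i, 1 / 6), (mids[k], 4 / 6), (j, 1 / 6)):
                    f[2 * node] += w * length * traction[0]
                    f[2 * node + 1] += w * length * traction[1]
    return f


def solve_with_bc(mesh: af.Mesh, material: af.Material, forces: np.ndarray,
                  fixed_dofs) -> tuple[np.ndarray, af.StressField]:
    """Solve with explicit per-DOF constraints; returns (u (nn,2), stresses)."""
    k = assemble_stiffness(mesh, material)
    u, reactions = solve_constrained(k, forces, np.asarray(sorted(set(fixed_dofs)), int))
    disp = af.DisplacementField(u.reshape(-1, 2), 0.0, reactions)
    return disp.displacements, af.recover_stress(mesh, material, disp)


@pytest.fixture(scope="session")
def synthetic_tables() -> pd.DataFrame:
    """8 models with graded log-location shifts, 4000 elements each."""
    params = af.SyntheticStressParams(
        models={f"m{i}": (-0.9 + 0.08 * i, 0.8) for i in range(8)},
        n_elements=4000, seed=3)
    return af.generate_element_tables(params)
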