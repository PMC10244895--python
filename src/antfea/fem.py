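"""Plane-stress linear-static finite element solver on quadratic triangles.

The discretisation uses 6-node straight-sided triangles (CPS6-style): corner
nodes plus midside nodes at edge midpoints, quadratic Lagrange shape
functions in area coordinates, and a 3-point interior Gauss rule (degree-2
exact, which is exact for the stiffness of straight-sided elements with a
constant constitutive matrix).  Boundary conditions are homogeneous Dirichlet
(fixed nodes) applied by row/column elimination, loads are concentrated nodal
forces, and stresses are recovered at element centroids with principal values
and the plane-stress Tresca equivalent (sigma_3 = 0):

    Tresca = max(|s1|, |s2|, |s1 - s2|).

Units: mm, N, MPa (N/mm^2), unit thickness by default, so forces per unit
thickness coincide with forces.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshing import Mesh

logger = logging.getLogger(__name__)


class FemError(ValueError):
    """Raised for invalid materials, load cases or singular systems."""


# ---------------------------------------------------------------------------
# material and constitutive model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material for plane stress.

    ``young_modulus`` is in MPa (N/mm^2); insect cuticle at 2.75 GPa is
    ``Material(2750.0, 0.3)``, available as :data:`CUTICLE`.
    """

    young_modulus: float
    poisson_ratio: float
    thickness: float = 1.0

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise FemError("Young's modulus must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise FemError("Poisson ratio must lie in [0, 0.5) for plane stress")
        if self.thickness <= 0:
            raise FemError("thickness must be positive")


#: Ant head cuticle: E = 2.75 GPa, nu = 0.3, unit thickness.
CUTICLE = Material(young_modulus=2750.0, poisson_ratio=0.3)


def constitutive_matrix(material: Material) -> np.ndarray:
    """Plane-stress elasticity matrix D (3x3, MPa)."""
    e, nu = material.young_modulus, material.poisson_ratio
    return (e / (1.0 - nu**2)) * np.array([
        [1.0, nu, 0.0],
        [nu, 1.0, 0.0],
        [0.0, 0.0, (1.0 - nu) / 2.0],
    ])


# ---------------------------------------------------------------------------
# element matrices
# ---------------------------------------------------------------------------

# 3-point Gauss rule on the reference triangle (xi, eta), weights sum to 1/2.
_GAUSS_POINTS = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
_GAUSS_WEIGHTS = np.array([1 / 6, 1 / 6, 1 / 6])
_CENTROID = np.array([[1 / 3, 1 / 3]])


def shape_gradients(xi: float, eta: float) -> np.ndarray:
    """d N_i / d(xi, eta) for the 6 quadratic shape functions, shape (6, 2).

    Node order: corners (L1, L2, L3 vertices) then midsides 1-2, 2-3, 3-1,
    with area coordinates L1 = 1 - xi - eta, L2 = xi, L3 = eta.
    """
    l1 = 1.0 - xi - eta
    l2, l3 = xi, eta
    # dN/dL as chain through (dL1, dL2, dL3)/d(xi,eta) = [(-1,-1),(1,0),(0,1)]
    return np.array([
        [-(4 * l1 - 1), -(4 * l1 - 1)],
        [4 * l2 - 1, 0.0],
        [0.0, 4 * l3 - 1],
        [4 * (l1 - l2), -4 * l2],
        [4 * l3, 4 * l2],
        [-4 * l3, 4 * (l1 - l3)],
    ])


def _b_matrix(coords: np.ndarray, xi: float, eta: float) -> tuple[np.ndarray, float]:
    """Strain-displacement matrix B (3x12) and |J| at one reference point."""
    dn = shape_gradients(xi, eta)          # (6, 2)
    jac = dn.T @ coords                    # (2, 2)
    detj = jac[0, 0] * jac[1, 1] - jac[0, 1] * jac[1, 0]
    if detj <= 0:
        raise FemError("inverted element (non-positive Jacobian)")
    dndx = dn @ np.linalg.inv(jac).T       # (6, 2) gradients in x, y
    b = np.zeros((3, 12))
    b[0, 0::2] = dndx[:, 0]
    b[1, 1::2] = dndx[:, 1]
    b[2, 0::2] = dndx[:, 1]
    b[2, 1::2] = dndx[:, 0]
    return b, detj


def element_stiffness(coords: np.ndarray, d_matrix: np.ndarray,
                      thickness: float = 1.0) -> np.ndarray:
    """12x12 stiffness of one 6-node triangle (coords (6, 2), CPS6 order)."""
    coords = np.asarray(coords, dtype=float)
    k = np.zeros((12, 12))
    for (xi, eta), w in zip(_GAUSS_POINTS, _GAUSS_WEIGHTS):
        b, detj = _b_matrix(coords, xi, eta)
        k += w * detj * thickness * (b.T @ d_matrix @ b)
    return k


def assemble_stiffness(mesh: Mesh, material: Material) -> sp.csr_matrix:
    """Global stiffness (2*nn x 2*nn), sparse CSR."""
    d = constitutive_matrix(material)
    ndof = 2 * mesh.n_nodes
    rows, cols, vals = [], [], []
    for e in range(mesh.n_elements):
        conn = mesh.elements[e]
        try:
            ke = element_stiffness(mesh.nodes[conn], d, material.thickness)
        except FemError as err:
            raise FemError(f"element {e}: {err}") from err
        dofs = np.empty(12, dtype=int)
        dofs[0::2] = 2 * conn
        dofs[1::2] = 2 * conn + 1
        rows.append(np.repeat(dofs, 12))
        cols.append(np.tile(dofs, 12))
        vals.append(ke.ravel())
    k = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, ndof)).tocsr()
    return k


# ---------------------------------------------------------------------------
# load case
# ---------------------------------------------------------------------------

@dataclass
class LoadCase:
    """Nodal forces and homogeneous constraints for one simulation.

    ``forces`` is the assembled global force vector (2*nn,); ``fixed_dofs``
    lists the eliminated degrees of freedom.  The named sets are retained for
    reporting and symmetry checks.
    """

    side_load: float
    load_angle: float
    loaded_sets: dict[str, np.ndarray]
    fixed_sets: dict[str, np.ndarray]
    forces: np.ndarray
    fixed_dofs: np.ndarray = field(default_factory=lambda: np.empty(0, int))


def normalize_load(area_model: float, area_ref: float, load_ref: float) -> float:
    """Scale the reference side load to another model by the square root of
    the area ratio: F = F_ref * sqrt(A_model / A_ref).

    For plane models of unit thickness this keeps the stress field invariant
    under isometric scaling, making stress distributions comparable across
    head sizes (quasi-ideal force scaling).
    """
    if area_model <= 0 or area_ref <= 0 or load_ref <= 0:
        raise FemError("areas and reference load must be positive")
    return load_ref * math.sqrt(area_model / area_ref)


def build_load_case(mesh: Mesh, side_load: float, angle: float = 45.0,
                    toward_base: bool = True) -> LoadCase:
    """Distribute ``side_load`` (N) equally over each lateral load arc.

    Forces are inclined ``angle`` degrees from the vertical midline, pointing
    medially and (by default) downward toward the head base, mirrored across
    the midline: left-side components ``(+f sin a, -f cos a)``, right-side
    ``(-f sin a, -f cos a)`` for per-node magnitude ``f``.
    """
    for name in ("left_load", "right_load", "left_fix", "right_fix"):
        if name not in mesh.boundary_node_sets or len(mesh.boundary_node_sets[name]) == 0:
            raise FemError(f"mesh is missing a populated '{name}' node set")
    a = math.radians(angle)
    sy = -1.0 if toward_base else 1.0
    forces = np.zeros(2 * mesh.n_nodes)
    loaded = {}
    for name, sx in (("left_load", +1.0), ("right_load", -1.0)):
        nodes = np.asarray(mesh.boundary_node_sets[name], dtype=int)
        f = side_load / len(nodes)
        forces[2 * nodes] += sx * f * math.sin(a)
        forces[2 * nodes + 1] += sy * f * math.cos(a)
        loaded[name] = nodes
    fixed = {name: np.asarray(mesh.boundary_node_sets[name], dtype=int)
             for name in ("left_fix", "right_fix")}
    fixed_nodes = np.concatenate(list(fixed.values()))
    fixed_dofs = np.sort(np.concatenate([2 * fixed_nodes, 2 * fixed_nodes + 1]))
    return LoadCase(side_load=side_load, load_angle=angle, loaded_sets=loaded,
                    fixed_sets=fixed, forces=forces, fixed_dofs=fixed_dofs)


# ---------------------------------------------------------------------------
# solve
# ---------------------------------------------------------------------------

@dataclass
class DisplacementField:
    """Per-node displacements (mm) plus the solve residual and reactions."""

    displacements: np.ndarray        # (nn, 2)
    residual: float                  # ||K u - f|| / ||f||
    reactions: np.ndarray            # (2*nn,), nonzero only at fixed dofs

    @property
    def u_flat(self) -> np.ndarray:
        return self.displacements.ravel()


def solve_constrained(k: sp.csr_matrix, f: np.ndarray,
                      fixed_dofs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve K u = f with u[fixed] = 0 by elimination; returns (u, reactions)."""
    ndof = k.shape[0]
    fixed_dofs = np.asarray(fixed_dofs, dtype=int)
    if len(fixed_dofs) == 0:
        raise FemError(
            "no constrained degrees of freedom: the system has free rigid-body "
            "modes (two translations and one rotation)"
        )
    free = np.setdiff1d(np.arange(ndof), fixed_dofs)
    kff = k[free][:, free].tocsc()
    try:
        u_free = spla.spsolve(kff, f[free])
    except Exception as err:  # umfpack/superlu raise different types
        raise FemError(f"singular stiffness system: {err}") from err
    if not np.all(np.isfinite(u_free)):
        raise FemError(
            "singular stiffness system (non-finite solution): constraints do "
            "not suppress all rigid-body modes"
        )
    u = np.zeros(ndof)
    u[free] = u_free
    reactions = k @ u - f
    reactions[free] = 0.0
    return u, reactions


def solve_linear_static(mesh: Mesh, material: Material,
                        loadcase: LoadCase) -> DisplacementField:
    """One linear static solve; verifies the residual and global equilibrium."""
    k = assemble_stiffness(mesh, material)
    u, reactions = solve_constrained(k, loadcase.forces, loadcase.fixed_dofs)
    fnorm = np.linalg.norm(loadcase.forces)
    resid = float(np.linalg.norm((k @ u - loadcase.forces)[np.setdiff1d(
        np.arange(k.shape[0]), loadcase.fixed_dofs)]) / fnorm) if fnorm else 0.0
    if resid > 1e-8:
        raise FemError(f"solver residual {resid:.2e} exceeds 1e-8")
    return DisplacementField(displacements=u.reshape(-1, 2),
                             residual=resid, reactions=reactions)


# ---------------------------------------------------------------------------
# stress recovery
# ---------------------------------------------------------------------------

def principal_stresses(sx: np.ndarray, sy: np.ndarray,
                       txy: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mohr-circle principal values and angle: s1 >= s2, angle of s1 (rad)."""
    sx, sy, txy = map(np.asarray, (sx, sy, txy))
    c = 0.5 * (sx + sy)
    r = np.sqrt((0.5 * (sx - sy)) ** 2 + txy**2)
    angle = 0.5 * np.arctan2(2.0 * txy, sx - sy)
    return c + r, c - r, angle


def tresca_equivalent(s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    """Plane-stress Tresca equivalent with sigma_3 = 0."""
    return np.maximum.reduce([np.abs(s1), np.abs(s2), np.abs(s1 - s2)])


@dataclass
class StressField:
    """Centroid stresses per element plus nodal-averaged Tresca for probes."""

    sigma: np.ndarray          # (ne, 3): sx, sy, txy at element centroids, MPa
    sigma1: np.ndarray         # (ne,)
    sigma2: np.ndarray         # (ne,)
    principal_angle: np.ndarray  # (ne,), radians, direction of sigma1
    tresca: np.ndarray         # (ne,)
    areas: np.ndarray          # (ne,), mm^2
    nodal_tresca: np.ndarray   # (nn,), arithmetic average over adjacent elements


def recover_stress(mesh: Mesh, material: Material,
                   disp: DisplacementField) -> StressField:
    """Element-centroid stresses, principal values, Tresca and nodal averages."""
    d = constitutive_matrix(material)
    u = disp.u_flat
    ne = mesh.n_elements
    sigma = np.empty((ne, 3))
    (xi, eta) = _CENTROID[0]
    for e in range(ne):
        conn = mesh.elements[e]
        b, _ = _b_matrix(mesh.nodes[conn], xi, eta)
        dofs = np.empty(12, dtype=int)
        dofs[0::2] = 2 * conn
        dofs[1::2] = 2 * conn + 1
        sigma[e] = d @ (b @ u[dofs])
    s1, s2, ang = principal_stresses(sigma[:, 0], sigma[:, 1], sigma[:, 2])
    tresca = tresca_equivalent(s1, s2)
    # nodal Tresca = mean of adjacent element centroid values
    counts = np.zeros(mesh.n_nodes)
    sums = np.zeros(mesh.n_nodes)
    for k in range(6):
        np.add.at(sums, mesh.elements[:, k], tresca)
        np.add.at(counts, mesh.elements[:, k], 1.0)
    nodal = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    return StressField(sigma=sigma, sigma1=s1, sigma2=s2, principal_angle=ang,
                       tresca=tresca, areas=mesh.element_areas(), nodal_tresca=nodal)


# ---------------------------------------------------------------------------
# results writers
# ---------------------------------------------------------------------------

def element_table(field: StressField, model: str) -> pd.DataFrame:
    """Per-element interchange table: model, element_id, tresca, area_mm2."""
    return pd.DataFrame({
        "model": model,
        "element_id": np.arange(1, len(field.tresca) + 1),
        "tresca": field.tresca,
        "area_mm2": field.areas,
    })


def write_stress_csv(field: StressField, model: str, path: str) -> None:
    """Full per-element results CSV with stress components and principals."""
    df = pd.DataFrame({
        "model": model,
        "element_id": np.arange(1, len(field.tresca) + 1),
        "sigma_xx": field.sigma[:, 0],
        "sigma_yy": field.sigma[:, 1],
        "tau_xy": field.sigma[:, 2],
        "sigma_1": field.sigma1,
        "sigma_2": field.sigma2,
        "tresca": field.tresca,
        "area_mm2": field.areas,
    })
    df.to_csv(path, index=False)


def write_displacement_csv(disp: DisplacementField, path: str) -> None:
    df = pd.DataFrame({
        "node_id": np.arange(len(disp.displacements)),
        "ux_mm": disp.displacements[:, 0],
        "uy_mm": disp.displacements[:, 1],
    })
    df.to_csv(path, index=False)
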