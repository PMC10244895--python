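"""Deterministic triangulation of outlines into 6-node quadratic plane triangles.

The mesher is Delaunay-based: the boundary polygon is resampled at the target
edge length, interior seed points are laid on a hexagonal lattice (kept clear
of the boundary), a few Laplacian smoothing passes improve angles, exterior
triangles are removed by a point-in-polygon filter, and the linear
triangulation is upgraded to straight-sided quadratic elements by midside
insertion with global deduplication.  There is no randomness anywhere, so the
same outline and density always give the same mesh.

Element node ordering follows the CPS6 convention: corners 0,1,2
counter-clockwise, then midsides 3 (between 0-1), 4 (1-2), 5 (2-0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import Polygon

from .geometry import Outline, REGION_NAMES, s_in_interval

logger = logging.getLogger(__name__)

_INTERIOR_CLEARANCE = 0.7  # interior seeds keep this * density away from the boundary
_SMOOTHING_PASSES = 4


class MeshingError(ValueError):
    """Raised when an outline cannot be meshed at the requested density."""


@dataclass
class Mesh:
    """Nodes + 6-node quadratic triangles with named boundary node sets.

    ``boundary_nodes`` are the node indices lying on the outline, with their
    arc-length positions in ``boundary_s`` (same order); ``boundary_node_sets``
    holds the load/fix sets keyed by region name.
    """

    nodes: np.ndarray                       # (nn, 2) mm
    elements: np.ndarray                    # (ne, 6) int
    density: float                          # target edge length, mm
    boundary_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    boundary_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    boundary_node_sets: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def corner_coords(self) -> np.ndarray:
        """(ne, 3, 2) corner coordinates of every element."""
        return self.nodes[self.elements[:, :3]]

    def element_areas(self) -> np.ndarray:
        """Exact areas of the (straight-sided) elements."""
        c = self.corner_coords()
        d1 = c[:, 1] - c[:, 0]
        d2 = c[:, 2] - c[:, 0]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def element_centroids(self) -> np.ndarray:
        return self.corner_coords().mean(axis=1)


# ---------------------------------------------------------------------------
# boundary resampling and interior seeding
# ---------------------------------------------------------------------------

def _resample_boundary(outline: Outline, h: float,
                       corner_deg: float = 25.0) -> tuple[np.ndarray, np.ndarray]:
    """Points along the polygon at near-uniform spacing ~h, with arc lengths.

    True corners (turn angle above ``corner_deg``) are always kept; the arcs
    between them are subdivided at equal arc length, so densely sampled
    smooth outlines get boundary spacing matching the interior lattice
    instead of inheriting their fine vertex spacing.  Chords that cut curved
    boundary too deeply (sagitta above ~0.3% of area/perimeter) are split
    further, keeping the meshed area within the 0.5% contract even at coarse
    densities.
    """
    v = outline.vertices
    cum = outline.cumulative_arclength()
    perim = outline.perimeter
    max_sagitta = 0.003 * outline.polygon.area / perim
    prev = v - np.roll(v, 1, axis=0)
    nxt = np.roll(v, -1, axis=0) - v
    turn = np.abs(np.degrees(np.arctan2(
        prev[:, 0] * nxt[:, 1] - prev[:, 1] * nxt[:, 0], (prev * nxt).sum(axis=1))))
    forced = np.where(turn > corner_deg)[0]
    if len(forced) == 0:
        forced = np.array([0])

    def _worst_sagitta(sa: float, sb: float) -> float:
        """Max deviation of the polygon arc (sa, sb) from its chord."""
        a, b = outline.point_at(sa % perim), outline.point_at(sb % perim)
        chord = b - a
        norm = np.linalg.norm(chord)
        if norm < 1e-14:
            return 0.0
        inside = (cum > sa) & (cum < sb) if sb <= perim else \
            (cum > sa) | (cum < sb - perim)
        if not inside.any():
            return 0.0
        rel = v[inside] - a
        cross = chord[0] * rel[:, 1] - chord[1] * rel[:, 0]
        return float(np.abs(cross).max() / norm)

    pts, svals = [], []
    for a, b in zip(forced, np.roll(forced, -1)):
        sa = cum[a]
        sb = cum[b] if b > a else cum[b] + perim
        arc = sb - sa
        n_sub = max(1, int(round(arc / h)))
        for _ in range(12):
            step = arc / n_sub
            worst = max(_worst_sagitta(sa + k * step, sa + (k + 1) * step)
                        for k in range(n_sub))
            if worst <= max_sagitta:
                break
            n_sub = int(np.ceil(n_sub * 1.4))
        for k in range(n_sub):
            s = (sa + k * arc / n_sub) % perim
            pts.append(outline.point_at(s))
            svals.append(s)
    return np.array(pts), np.array(svals)


def _hex_lattice(bounds: tuple[float, float, float, float], h: float) -> np.ndarray:
    """Hexagonal point lattice covering the bounds, mirror-symmetric about the
    vertical centreline (so symmetric outlines get symmetric seeds)."""
    xmin, ymin, xmax, ymax = bounds
    cx = 0.5 * (xmin + xmax)
    half = 0.5 * (xmax - xmin)
    dy = h * np.sqrt(3.0) / 2.0
    n_half = int(np.ceil(half / h)) + 1
    xs_even = cx + h * np.arange(-n_half, n_half + 1)
    xs_odd = cx + h * (np.arange(-n_half, n_half) + 0.5)
    rows = []
    j = 0
    y = ymin
    while y <= ymax:
        xs = xs_odd if j % 2 else xs_even
        rows.append(np.column_stack([xs, np.full_like(xs, y)]))
        y += dy
        j += 1
    return np.vstack(rows) if rows else np.empty((0, 2))


def _laplacian_smooth(points: np.ndarray, n_fixed: int, passes: int) -> np.ndarray:
    """Move interior points toward the average of their Delaunay neighbours."""
    pts = points.copy()
    for _ in range(passes):
        tri = Delaunay(pts)
        indptr, indices = tri.vertex_neighbor_vertices
        new = pts.copy()
        for i in range(n_fixed, len(pts)):
            nb = indices[indptr[i]:indptr[i + 1]]
            if len(nb):
                new[i] = pts[nb].mean(axis=0)
        pts = new
    return pts


# ---------------------------------------------------------------------------
# triangulation
# ---------------------------------------------------------------------------

def triangulate(outline: Outline, density: float) -> Mesh:
    """Mesh an annotated outline at a target element edge length (mm).

    Raises :class:`MeshingError` if the density is too coarse to resolve the
    boundary (fewer than 8 boundary samples) or if the triangulated area
    disagrees with the polygon area by more than 0.5%.
    """
    if density <= 0:
        raise MeshingError("density must be a positive edge length in mm")
    poly = outline.polygon
    bpts, bs = _resample_boundary(outline, density)
    if len(bpts) < 3:
        suggested = outline.perimeter / 8.0
        raise MeshingError(
            f"density {density} mm too coarse for outline '{outline.name}' "
            f"({len(bpts)} boundary samples); try <= {suggested:.4g} mm"
        )
    interior = _hex_lattice(poly.bounds, density)
    if len(interior):
        shrunk = poly.buffer(-_INTERIOR_CLEARANCE * density)
        if not shrunk.is_empty:
            keep = shapely.contains_xy(shrunk, interior[:, 0], interior[:, 1])
            interior = interior[keep]
        else:
            interior = interior[:0]
    points = np.vstack([bpts, interior]) if len(interior) else bpts
    if len(interior):
        points = _laplacian_smooth(points, n_fixed=len(bpts), passes=_SMOOTHING_PASSES)

    tri = Delaunay(points)
    simplices = tri.simplices
    cent = points[simplices].mean(axis=1)
    inside = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
    simplices = simplices[inside]
    # drop degenerate slivers (can appear along the boundary)
    c = points[simplices]
    areas2 = ((c[:, 1, 0] - c[:, 0, 0]) * (c[:, 2, 1] - c[:, 0, 1])
              - (c[:, 1, 1] - c[:, 0, 1]) * (c[:, 2, 0] - c[:, 0, 0]))
    simplices = simplices[np.abs(areas2) > 1e-12 * density**2]
    if len(simplices) == 0:
        raise MeshingError(f"no interior triangles for outline '{outline.name}'")

    # enforce CCW corners
    c = points[simplices]
    signed = ((c[:, 1, 0] - c[:, 0, 0]) * (c[:, 2, 1] - c[:, 0, 1])
              - (c[:, 1, 1] - c[:, 0, 1]) * (c[:, 2, 0] - c[:, 0, 0]))
    flip = signed < 0
    simplices[flip] = simplices[flip][:, [0, 2, 1]]

    # drop nodes not referenced by any kept triangle, then renumber
    used = np.unique(simplices)
    remap = -np.ones(len(points), dtype=int)
    remap[used] = np.arange(len(used))
    nodes = points[used]
    corners = remap[simplices]
    # boundary points are first in `points`, so they stay first after renumber
    boundary_nodes = remap[used[used < len(bpts)]]
    boundary_s = bs[used[used < len(bpts)]]

    nodes, elements = _upgrade_quadratic(nodes, corners)

    area_err = abs(float(_total_area(nodes, elements)) - poly.area) / poly.area
    if area_err > 0.005:
        raise MeshingError(
            f"meshed area deviates {area_err:.2%} from outline '{outline.name}' "
            f"area; refine the density (current {density} mm)"
        )

    mesh = Mesh(nodes=nodes, elements=elements, density=density,
                boundary_nodes=boundary_nodes, boundary_s=boundary_s)
    _attach_midside_boundary(mesh, outline)
    if outline.landmarks:
        _populate_node_sets(mesh, outline)
    return mesh


def _total_area(nodes: np.ndarray, elements: np.ndarray) -> float:
    c = nodes[elements[:, :3]]
    d1 = c[:, 1] - c[:, 0]
    d2 = c[:, 2] - c[:, 0]
    return float(np.sum(0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])))


def _upgrade_quadratic(nodes: np.ndarray, corners: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Insert midside nodes (global dedup) -> (all_nodes, elements (ne,6))."""
    edge_mid: dict[tuple[int, int], int] = {}
    new_nodes = [nodes]
    next_id = len(nodes)
    elements = np.empty((len(corners), 6), dtype=int)
    elements[:, :3] = corners
    mids = np.empty((len(corners), 3), dtype=int)
    for e, (a, b, c) in enumerate(corners):
        for k, (i, j) in enumerate(((a, b), (b, c), (c, a))):
            key = (i, j) if i < j else (j, i)
            m = edge_mid.get(key)
            if m is None:
                m = next_id
                edge_mid[key] = m
                new_nodes.append(0.5 * (nodes[i] + nodes[j])[None, :])
                next_id += 1
            mids[e, k] = m
    elements[:, 3:] = mids
    return np.vstack(new_nodes), elements


def _attach_midside_boundary(mesh: Mesh, outline: Outline) -> None:
    """Extend boundary bookkeeping to midside nodes on boundary edges.

    A mesh edge is a boundary edge when both endpoints are consecutive
    boundary samples along the outline loop; the straight-sided midside node
    then lies on the boundary, at the mean arc length (wrap-aware).
    """
    perim = outline.perimeter
    s_of = dict(zip(mesh.boundary_nodes.tolist(), mesh.boundary_s.tolist()))
    n_bsamples = len(mesh.boundary_nodes)
    # consecutive along the loop ~ arc gap close to one sample spacing
    max_gap = 2.5 * perim / max(n_bsamples, 1)
    extra_nodes, extra_s = [], []
    for e in range(mesh.n_elements):
        a, b, c = mesh.elements[e, :3]
        for k, (i, j) in enumerate(((a, b), (b, c), (c, a))):
            if i in s_of and j in s_of:
                si, sj = s_of[i], s_of[j]
                gap = min((si - sj) % perim, (sj - si) % perim)
                if gap <= max_gap:
                    m = mesh.elements[e, 3 + k]
                    if m not in s_of:
                        d = (sj - si) % perim
                        if d > perim / 2:
                            sm = (sj + ((si - sj) % perim) / 2.0) % perim
                        else:
                            sm = (si + d / 2.0) % perim
                        s_of[m] = sm
                        extra_nodes.append(m)
                        extra_s.append(sm)
    if extra_nodes:
        mesh.boundary_nodes = np.concatenate([mesh.boundary_nodes, np.array(extra_nodes, int)])
        mesh.boundary_s = np.concatenate([mesh.boundary_s, np.array(extra_s)])


def _populate_node_sets(mesh: Mesh, outline: Outline) -> None:
    perim = outline.perimeter
    sets: dict[str, np.ndarray] = {}
    for name in REGION_NAMES:
        if name not in outline.landmarks:
            continue
        mask = s_in_interval(mesh.boundary_s, outline.landmarks[name], perim)
        sets[name] = mesh.boundary_nodes[mask]
    # equalize left/right counts pairwise (same number of nodes per side)
    for left, right in (("left_fix", "right_fix"), ("left_load", "right_load")):
        if left in sets and right in sets:
            sets[left], sets[right] = _equalize_sets(
                mesh, outline, sets[left], sets[right], left, right)
    mesh.boundary_node_sets = sets


def _equalize_sets(mesh: Mesh, outline: Outline, left: np.ndarray, right: np.ndarray,
                   lname: str, rname: str) -> tuple[np.ndarray, np.ndarray]:
    """Trim the larger of a left/right set pair from its arc-interior end.

    Nodes are ranked by arc-length distance from the arc centre; the nodes
    farthest into the arc interior are dropped first, so the kept nodes hug
    the landmark centre symmetrically.
    """
    m = min(len(left), len(right))
    if m == 0:
        return left, right
    perim = outline.perimeter
    pos = {int(n): i for i, n in enumerate(mesh.boundary_nodes)}
    out = []
    for name, nodes in ((lname, left), (rname, right)):
        start, length = outline.landmarks[name]
        center = (start + length / 2.0) % perim
        s = np.array([mesh.boundary_s[pos[int(n)]] for n in nodes])
        dist = np.minimum((s - center) % perim, (center - s) % perim)
        order = np.lexsort((nodes, dist))  # stable: distance, then node id
        out.append(np.sort(nodes[order[:m]]))
    return out[0], out[1]


def node_sets_per_side(mesh: Mesh) -> dict[str, int]:
    """Counts of the named boundary sets; errors on an empty fix set."""
    counts = {name: len(mesh.boundary_node_sets.get(name, ())) for name in REGION_NAMES}
    if counts["left_fix"] == 0 or counts["right_fix"] == 0:
        raise MeshingError(
            "empty fixed-node set: increase corner_arc_fraction or refine the mesh"
        )
    assert counts["left_fix"] == counts["right_fix"]
    assert counts["left_load"] == counts["right_load"]
    return counts


# ---------------------------------------------------------------------------
# quality metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QualityReport:
    min_angle_deg: float
    max_aspect: float
    area_error: float          # |mesh area - outline area| / outline area (0 if no outline)
    n_elements: int


def mesh_quality(mesh: Mesh, outline: Outline | None = None,
                 min_angle_gate: float | None = None) -> QualityReport:
    """Minimum corner angle, worst edge-length aspect ratio and area error.

    If ``min_angle_gate`` is given (degrees), a mesh below the gate raises
    :class:`MeshingError`.
    """
    c = mesh.corner_coords()
    e0 = np.linalg.norm(c[:, 1] - c[:, 0], axis=1)
    e1 = np.linalg.norm(c[:, 2] - c[:, 1], axis=1)
    e2 = np.linalg.norm(c[:, 0] - c[:, 2], axis=1)
    edges = np.stack([e0, e1, e2], axis=1)
    angles = []
    for k in range(3):
        a = edges[:, k]
        b = edges[:, (k + 1) % 3]
        cc = edges[:, (k + 2) % 3]
        cosv = np.clip((a**2 + b**2 - cc**2) / (2 * a * b), -1.0, 1.0)
        angles.append(np.degrees(np.arccos(cosv)))
    min_angle = float(np.min(angles))
    aspect = float(np.max(edges.max(axis=1) / edges.min(axis=1)))
    area_err = 0.0
    if outline is not None:
        area_err = abs(float(mesh.element_areas().sum()) - outline.polygon.area) / outline.polygon.area
    rep = QualityReport(min_angle, aspect, area_err, mesh.n_elements)
    if min_angle_gate is not None and min_angle < min_angle_gate:
        raise MeshingError(
            f"mesh min angle {min_angle:.1f} deg below gate {min_angle_gate} deg"
        )
    return rep


# ---------------------------------------------------------------------------
# I/O: Abaqus input-deck dialect and plain CSV dump
# ---------------------------------------------------------------------------

def write_abaqus_inp(mesh: Mesh, path: str, part_name: str = "HEAD") -> None:
    """Write nodes, CPS6M elements and named node sets (1-based ids)."""
    with open(path, "w") as fh:
        fh.write(f"*HEADING\n{part_name}\n*NODE\n")
        for i, (x, y) in enumerate(mesh.nodes, start=1):
            fh.write(f"{i}, {x:.10g}, {y:.10g}\n")
        fh.write("*ELEMENT, TYPE=CPS6M\n")
        for e, conn in enumerate(mesh.elements, start=1):
            fh.write(f"{e}, " + ", ".join(str(n + 1) for n in conn) + "\n")
        for name, nodes in mesh.boundary_node_sets.items():
            fh.write(f"*NSET, NSET={name.upper()}\n")
            ids = [str(n + 1) for n in np.sort(np.asarray(nodes, int))]
            for i in range(0, len(ids), 8):
                fh.write(", ".join(ids[i:i + 8]) + "\n")


def read_abaqus_inp(path: str) -> Mesh:
    """Read the dialect written by :func:`write_abaqus_inp` (round-trip safe)."""
    nodes: list[list[float]] = []
    elements: list[list[int]] = []
    nsets: dict[str, list[int]] = {}
    section = None
    current_set = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("*"):
                key = line.split(",")[0].strip().upper()
                if key == "*NODE":
                    section = "node"
                elif key == "*ELEMENT":
                    section = "element"
                elif key == "*NSET":
                    section = "nset"
                    current_set = line.split("NSET=")[1].split(",")[0].strip().lower()
                    nsets[current_set] = []
                else:
                    section = None
                continue
            parts = [p.strip() for p in line.split(",") if p.strip()]
            if section == "node":
                nodes.append([float(parts[1]), float(parts[2])])
            elif section == "element":
                elements.append([int(p) - 1 for p in parts[1:7]])
            elif section == "nset" and current_set is not None:
                nsets[current_set].extend(int(p) - 1 for p in parts)
    return Mesh(
        nodes=np.array(nodes),
        elements=np.array(elements, dtype=int),
        density=float("nan"),
        boundary_node_sets={k: np.array(v, dtype=int) for k, v in nsets.items()},
    )


def write_mesh_csv(mesh: Mesh, nodes_path: str, elements_path: str) -> None:
    """Plain CSV dump: node table and element connectivity (0-based)."""
    np.savetxt(nodes_path, np.column_stack([np.arange(mesh.n_nodes), mesh.nodes]),
               delimiter=",", header="node_id,x_mm,y_mm", comments="", fmt=["%d", "%.10g", "%.10g"])
    np.savetxt(elements_path,
               np.column_stack([np.arange(mesh.n_elements), mesh.elements]),
               delimiter=",", header="element_id,n1,n2,n3,n4,n5,n6", comments="", fmt="%d")
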