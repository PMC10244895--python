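"""Closed 2D head outlines: I/O, validation, areas and boundary-region annotation.

An :class:`Outline` is a simple, counter-clockwise polygon in the *head frame*:
full-face view, midline along the vertical axis, mandibular (base) margin at
the bottom.  Loads attach to two lateral-margin arcs and displacements are
fixed on two base-corner arcs; both are stored as arc-length intervals on the
polygon perimeter so they survive boundary resampling during meshing.

Units are mm throughout.
"""

from __future__ import annotations

import csv
import logging
import math
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.validation import explain_validity

logger = logging.getLogger(__name__)

# Names of the four boundary regions, in conventional order.
REGION_NAMES = ("left_load", "right_load", "left_fix", "right_fix")


class OutlineError(ValueError):
    """Raised for invalid outline geometry or annotation."""


@dataclass(frozen=True)
class RegionSpec:
    """Arc-length extents of the loaded and fixed boundary regions.

    ``side_arc_fraction`` is the fraction of the total perimeter covered by
    *each* lateral-margin load arc (centred on the widest point of that side);
    ``corner_arc_fraction`` likewise for each base-corner constraint arc.
    The left/right specs are symmetric by construction.
    """

    side_arc_fraction: float = 0.20
    corner_arc_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in ("side_arc_fraction", "corner_arc_fraction"):
            f = getattr(self, name)
            if not 0.0 < f < 0.5:
                raise OutlineError(f"{name} must lie in (0, 0.5), got {f}")


@dataclass
class Outline:
    """A closed, simple, counter-clockwise polygon with named boundary arcs.

    ``vertices`` is an (n, 2) float array; the first vertex is not repeated at
    the end (closure is implicit).  ``landmarks`` maps region names to
    ``(s_start, s_length)`` arc-length intervals on the perimeter, measured
    counter-clockwise from vertex 0; an interval may wrap through 0.
    """

    vertices: np.ndarray
    name: str = "outline"
    landmarks: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        validate_outline(self)

    # -- derived geometry ---------------------------------------------------

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def perimeter(self) -> float:
        return float(self.polygon.exterior.length)

    def edge_lengths(self) -> np.ndarray:
        v = self.vertices
        return np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)

    def cumulative_arclength(self) -> np.ndarray:
        """Arc length s at each vertex (s[0] = 0), length n."""
        return np.concatenate([[0.0], np.cumsum(self.edge_lengths())[:-1]])

    def point_at(self, s: float) -> np.ndarray:
        """Point on the boundary at arc length ``s`` (mod perimeter)."""
        s = s % self.perimeter
        cum = self.cumulative_arclength()
        lens = self.edge_lengths()
        i = int(np.searchsorted(cum, s, side="right") - 1)
        t = (s - cum[i]) / lens[i]
        v = self.vertices
        return (1 - t) * v[i] + t * v[(i + 1) % len(v)]

    def arclength_of_vertex(self, i: int) -> float:
        return float(self.cumulative_arclength()[i])


def polygon_signed_area(vertices: np.ndarray) -> float:
    """Shoelace signed area; positive for counter-clockwise order."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def validate_outline(outline: Outline) -> None:
    """Check simplicity, orientation and implicit closure; raise OutlineError."""
    v = outline.vertices
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
        raise OutlineError(
            f"outline '{outline.name}' is degenerate: needs >= 3 planar vertices"
        )
    if np.linalg.norm(v[0] - v[-1]) < 1e-12:
        raise OutlineError(
            f"outline '{outline.name}' repeats its first vertex; closure is implicit"
        )
    poly = Polygon(v)
    if not poly.is_valid or not poly.is_simple:
        raise OutlineError(
            f"outline '{outline.name}' self-intersects: {explain_validity(poly)}"
        )
    if polygon_signed_area(v) <= 0:
        raise OutlineError(
            f"outline '{outline.name}' is clockwise; vertices must be counter-clockwise"
        )


def _dedupe_ring(points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Drop consecutive duplicates and an explicit closing vertex."""
    pts = np.asarray(points, dtype=float)
    keep = [0]
    for i in range(1, len(pts)):
        if np.linalg.norm(pts[i] - pts[keep[-1]]) > tol:
            keep.append(i)
    pts = pts[keep]
    if len(pts) > 1 and np.linalg.norm(pts[0] - pts[-1]) <= tol:
        pts = pts[:-1]
    return pts


def _as_ccw(points: np.ndarray) -> np.ndarray:
    return points if polygon_signed_area(points) > 0 else points[::-1]


# ---------------------------------------------------------------------------
# SVG path input
#
# A deliberately small parser: enough for the closed <path> outlines that a
# manual vectorisation workflow produces (move/line/cubic/quadratic commands,
# absolute or relative, plus Z).  The SVG y-down axis is flipped to the
# mathematical y-up head frame on import.
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?")
_CMD_RE = re.compile(r"([MmLlHhVvCcSsQqTtZzAa])")


def _tokenize_path(d: str) -> list[tuple[str, list[float]]]:
    out: list[tuple[str, list[float]]] = []
    for part in _CMD_RE.split(d):
        part = part.strip()
        if not part:
            continue
        if _CMD_RE.fullmatch(part):
            out.append((part, []))
        else:
            if not out:
                raise OutlineError(f"SVG path data does not start with a command: {d[:40]!r}")
            out[-1][1].extend(float(m) for m in _NUM_RE.findall(part))
    return out


def _sample_bezier(ctrl: np.ndarray, n: int) -> np.ndarray:
    """Uniform-parameter samples of a Bezier curve, excluding the start point."""
    t = np.linspace(0.0, 1.0, n + 1)[1:, None]
    if len(ctrl) == 4:  # cubic
        p = ((1 - t) ** 3 * ctrl[0] + 3 * (1 - t) ** 2 * t * ctrl[1]
             + 3 * (1 - t) * t**2 * ctrl[2] + t**3 * ctrl[3])
    elif len(ctrl) == 3:  # quadratic
        p = (1 - t) ** 2 * ctrl[0] + 2 * (1 - t) * t * ctrl[1] + t**2 * ctrl[2]
    else:
        raise OutlineError(f"unsupported Bezier order {len(ctrl) - 1}")
    return p


def _sample_path(d: str, samples_per_curve: int) -> tuple[np.ndarray, bool]:
    """Sample the first subpath of an SVG path; returns (points, closed)."""
    tokens = _tokenize_path(d)
    pts: list[np.ndarray] = []
    cur = np.zeros(2)
    start = np.zeros(2)
    prev_cubic_ctrl: np.ndarray | None = None
    prev_quad_ctrl: np.ndarray | None = None
    closed = False
    for cmd, args in tokens:
        rel = cmd.islower()
        op = cmd.upper()
        if op == "A":
            raise OutlineError("SVG arc (A) commands are not supported; flatten the path first")
        if op == "Z":
            closed = True
            break  # first subpath only
        if op == "M":
            xy = np.array(args[:2])
            cur = cur + xy if rel and pts else xy
            start = cur.copy()
            pts.append(cur.copy())
            # subsequent M pairs are implicit linetos
            for i in range(2, len(args), 2):
                nxt = np.array(args[i:i + 2])
                cur = cur + nxt if rel else nxt
                pts.append(cur.copy())
            prev_cubic_ctrl = prev_quad_ctrl = None
        elif op in "LHV":
            if op == "L":
                coords = [np.array(args[i:i + 2]) for i in range(0, len(args), 2)]
            elif op == "H":
                coords = [np.array([a, 0.0 if rel else cur[1]]) for a in args]
            else:  # V
                coords = [np.array([0.0 if rel else cur[0], a]) for a in args]
            for xy in coords:
                cur = cur + xy if rel else xy
                pts.append(cur.copy())
            prev_cubic_ctrl = prev_quad_ctrl = None
        elif op in "CS":
            step = 6 if op == "C" else 4
            for i in range(0, len(args), step):
                chunk = np.array(args[i:i + step]).reshape(-1, 2)
                if rel:
                    chunk = chunk + cur
                if op == "C":
                    c1, c2, end = chunk
                else:  # S: reflect previous cubic control
                    c1 = 2 * cur - prev_cubic_ctrl if prev_cubic_ctrl is not None else cur
                    c2, end = chunk
                seg = _sample_bezier(np.vstack([cur, c1, c2, end]), samples_per_curve)
                pts.extend(seg)
                cur = end
                prev_cubic_ctrl = c2
            prev_quad_ctrl = None
        elif op in "QT":
            step = 4 if op == "Q" else 2
            for i in range(0, len(args), step):
                chunk = np.array(args[i:i + step]).reshape(-1, 2)
                if rel:
                    chunk = chunk + cur
                if op == "Q":
                    c1, end = chunk
                else:  # T: reflect previous quadratic control
                    c1 = 2 * cur - prev_quad_ctrl if prev_quad_ctrl is not None else cur
                    (end,) = chunk
                seg = _sample_bezier(np.vstack([cur, c1, end]), samples_per_curve)
                pts.extend(seg)
                cur = end
                prev_quad_ctrl = c1
            prev_cubic_ctrl = None
        else:  # pragma: no cover - regex restricts commands
            raise OutlineError(f"unsupported SVG path command {cmd!r}")
    points = np.array(pts)
    if not closed and len(points) > 1 and np.linalg.norm(points[0] - points[-1]) < 1e-9:
        closed = True
    return points, closed


def load_outline_svg(path: str, samples_per_curve: int = 64, name: str | None = None) -> Outline:
    """Read the first closed ``<path>`` of an SVG file as an :class:`Outline`.

    Curves are flattened by uniform parameter sampling (``samples_per_curve``
    points per Bezier segment).  The SVG y-down axis is flipped so the head
    frame has y pointing up; orientation is normalised counter-clockwise and
    duplicate consecutive vertices are removed.
    """
    tree = ET.parse(path)
    paths = [el for el in tree.iter() if el.tag.split("}")[-1] == "path"]
    if not paths:
        raise OutlineError(f"no <path> element found in {path}")
    last_err: OutlineError | None = None
    for el in paths:
        d = el.get("d", "")
        points, closed = _sample_path(d, samples_per_curve)
        if not closed:
            last_err = OutlineError(
                f"path {el.get('id', d[:32] + '...')!r} in {path} is open; outlines must be closed"
            )
            continue
        points = points * np.array([1.0, -1.0])  # SVG y-down -> head frame y-up
        points = _as_ccw(_dedupe_ring(points))
        return Outline(points, name=name or el.get("id") or "svg_outline")
    assert last_err is not None
    raise last_err


def load_outline_csv(path: str, name: str | None = None) -> Outline:
    """Read the plain polyline dialect: header ``x_mm,y_mm``, one vertex per row."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip().lower() for h in header[:2]] != ["x_mm", "y_mm"]:
            raise OutlineError(f"{path}: expected header 'x_mm,y_mm', got {header!r}")
        pts = np.array([[float(r[0]), float(r[1])] for r in reader if r])
    pts = _as_ccw(_dedupe_ring(pts))
    import os
    return Outline(pts, name=name or os.path.splitext(os.path.basename(path))[0])


def write_outline_csv(outline: Outline, path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_mm", "y_mm"])
        w.writerows(outline.vertices.tolist())


# ---------------------------------------------------------------------------
# Areas
# ---------------------------------------------------------------------------

def outline_area(outline: Outline) -> float:
    """Surface area (mm^2) of the outline polygon."""
    return float(outline.polygon.area)


# ---------------------------------------------------------------------------
# Region annotation
# ---------------------------------------------------------------------------

def _band_width(v: np.ndarray, lo: float, hi: float) -> float:
    band = v[(v[:, 1] >= lo) & (v[:, 1] <= hi)]
    return float(band[:, 0].max() - band[:, 0].min()) if len(band) else 0.0


def _check_head_frame(outline: Outline) -> None:
    """Heuristic guard for the frame convention (base margin at the bottom).

    Head outlines are wider toward the posterior margin (top) than at the
    mandibular base; a clearly wider *bottom* band means the outline is
    upside down.  Symmetric shapes (squares, ellipses) pass trivially, and a
    featureless rounded outline is accepted in either orientation (the two
    are geometrically indistinguishable).
    """
    v = outline.vertices
    ymin, ymax = v[:, 1].min(), v[:, 1].max()
    h = ymax - ymin
    bottom = _band_width(v, ymin, ymin + 0.25 * h)
    top = _band_width(v, ymax - 0.25 * h, ymax)
    if bottom > 1.10 * top:
        raise OutlineError(
            f"outline '{outline.name}': the base margin appears to be at the top "
            "(bottom band wider than top); rotate the outline 180 degrees so the "
            "mandibular base is at the bottom"
        )


def _interval_nodes(center_s: float, length: float, perimeter: float) -> tuple[float, float]:
    return ((center_s - length / 2.0) % perimeter, length)


def _intervals_overlap(a: tuple[float, float], b: tuple[float, float], perim: float) -> bool:
    def segments(iv):
        s, ln = iv
        if s + ln <= perim:
            return [(s, s + ln)]
        return [(s, perim), (0.0, s + ln - perim)]

    for a0, a1 in segments(a):
        for b0, b1 in segments(b):
            if a0 < b1 and b0 < a1:
                return True
    return False


def annotate_regions(outline: Outline, spec: RegionSpec | None = None) -> Outline:
    """Assign the four landmark arcs: lateral-margin load arcs and base-corner
    constraint arcs, mirror-symmetric in arc-length extent.

    Arc centres are found from scale-free extremes of the vertex coordinates:
    lateral arcs centre on each side's widest point; base-corner arcs centre on
    the bottom-left (min x+y, normalised) and bottom-right (max x-y) extremes.
    """
    spec = spec or RegionSpec()
    _check_head_frame(outline)
    perim = outline.perimeter
    # candidate boundary points: the vertices plus a uniform arc-length grid
    # (mid-edge candidates matter for sparse polygons like squares)
    s_grid = np.concatenate([outline.cumulative_arclength(),
                             np.linspace(0.0, perim, 1024, endpoint=False)])
    pts = np.array([outline.point_at(s) for s in s_grid])
    cx = 0.5 * (pts[:, 0].min() + pts[:, 0].max())
    w = pts[:, 0].max() - pts[:, 0].min()
    h = pts[:, 1].max() - pts[:, 1].min()
    xn = (pts[:, 0] - cx) / w
    yn = (pts[:, 1] - pts[:, 1].min()) / h

    def _pick(*keys: np.ndarray) -> float:
        return float(s_grid[np.lexsort((s_grid, *keys[::-1]))[0]])

    # lateral-margin centres: widest point within the mid-height band
    band = np.where((yn >= 0.30) & (yn <= 0.80), 0.0, 1.0)
    mid = np.abs(yn - 0.55)
    s_left = _pick(band, np.round(xn, 9), np.round(mid, 9))
    s_right = _pick(band, np.round(-xn, 9), np.round(mid, 9))
    # base corners: bottom-left / bottom-right extremes, weighted toward the
    # bottom so rounded (minor-like) heads keep the corner arcs clear of the
    # lateral load arcs
    s_bl = _pick(np.round(xn + 2.0 * yn, 9), np.round(yn, 9))
    s_br = _pick(np.round(2.0 * yn - xn, 9), np.round(yn, 9))

    side_len = spec.side_arc_fraction * perim
    corner_len = spec.corner_arc_fraction * perim
    landmarks = {
        "left_load": _interval_nodes(s_left, side_len, perim),
        "right_load": _interval_nodes(s_right, side_len, perim),
        "left_fix": _interval_nodes(s_bl, corner_len, perim),
        "right_fix": _interval_nodes(s_br, corner_len, perim),
    }
    names = list(landmarks)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if _intervals_overlap(landmarks[a], landmarks[b], perim):
                raise OutlineError(
                    f"outline '{outline.name}': landmark arcs {a} and {b} overlap; "
                    "reduce RegionSpec fractions"
                )
    return replace(outline, landmarks=landmarks)


def s_in_interval(s: np.ndarray, interval: tuple[float, float], perimeter: float) -> np.ndarray:
    """Boolean mask: which arc-length positions fall inside a landmark interval."""
    s = np.asarray(s, dtype=float) % perimeter
    start, length = interval
    rel = (s - start) % perimeter
    return rel <= length + 1e-12


def mirror_outline(outline: Outline) -> Outline:
    """Reflect across the vertical midline, preserving CCW orientation.

    Landmark arcs are not carried over; re-annotate after mirroring.
    """
    v = outline.vertices.copy()
    cx = 0.5 * (v[:, 0].min() + v[:, 0].max())
    v[:, 0] = 2 * cx - v[:, 0]
    return Outline(v[::-1], name=outline.name + "_mirrored")


def transform_outline(outline: Outline, angle_deg: float = 0.0,
                      translation: tuple[float, float] = (0.0, 0.0),
                      scale: float = 1.0) -> Outline:
    """Rigid rotation + translation (+ optional uniform scale) of the vertices.

    Landmark arc-length intervals are carried over, rescaled by ``scale``.
    """
    th = math.radians(angle_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    v = scale * (outline.vertices @ rot.T) + np.asarray(translation)
    landmarks = {k: (s * scale, ln * scale) for k, (s, ln) in outline.landmarks.items()}
    return Outline(v, name=outline.name, landmarks=landmarks)
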