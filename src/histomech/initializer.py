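"""Initial polygonal cell nest construction and rest-state initialization.

The nest is built by successively dividing a rectangular cell with the
shortest-wall rule: the dividing wall is the shortest chord through the
cell centroid, found by scanning candidate orientations at 1 degree
resolution (ties broken by the lowest angle), with a small seed-controlled
jitter on the chosen orientation.  Pinching shortens the new wall by
sliding its attachment points along the host boundary.  The largest cell
divides next, until the requested count is reached.
"""

from __future__ import annotations

import math

import numpy as np
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import substring

from .core import SimParams, TissueMesh

TWO_PI = 2.0 * math.pi
_SNAP = 1e-9


def _shortest_centroid_chord(poly: Polygon, rng: np.random.Generator):
    """Shortest chord through the centroid, scanning orientations at 1 deg."""
    c = poly.centroid
    minx, miny, maxx, maxy = poly.bounds
    span = 2.0 * math.hypot(maxx - minx, maxy - miny)
    best = None
    best_len = np.inf
    jitter = math.radians(rng.uniform(-0.4, 0.4))
    for deg in range(180):
        ang = math.radians(deg) + jitter
        dx, dy = math.cos(ang), math.sin(ang)
        line = LineString(
            [(c.x - span * dx, c.y - span * dy), (c.x + span * dx, c.y + span * dy)]
        )
        inter = line.intersection(poly)
        if inter.is_empty:
            continue
        segs = list(inter.geoms) if inter.geom_type == "MultiLineString" else [inter]
        for seg in segs:
            if seg.geom_type != "LineString":
                continue
            if seg.distance(c) > 1e-9 * max(1.0, span):
                continue  # keep the piece containing the centroid
            if seg.length < best_len - 1e-12:
                best_len = seg.length
                best = seg
    if best is None:
        raise RuntimeError("no centroid chord found (degenerate polygon)")
    return best


def _divide(poly: Polygon, pinch_fraction: float, rng: np.random.Generator):
    """Split ``poly`` in two along its shortest centroid chord, with pinching."""
    chord = _shortest_centroid_chord(poly, rng)
    ring = LineString(poly.exterior.coords)
    L = ring.length
    t0 = ring.project(Point(chord.coords[0]))
    t1 = ring.project(Point(chord.coords[-1]))

    if pinch_fraction > 0:
        # Slide each attachment point along the boundary in the direction
        # that shortens the chord, by pinch_fraction * chord length.
        delta = pinch_fraction * chord.length
        cands0 = [(t0 + s * delta) % L for s in (-1.0, 0.0, 1.0)]
        cands1 = [(t1 + s * delta) % L for s in (-1.0, 0.0, 1.0)]
        best = (np.inf, t0, t1)
        for a in cands0:
            pa = ring.interpolate(a)
            for b in cands1:
                pb = ring.interpolate(b)
                d = pa.distance(pb)
                if d > 1e-6 and d < best[0]:
                    best = (d, a, b)
        _, t0, t1 = best

    if t1 < t0:
        t0, t1 = t1, t0
    if t1 - t0 < 1e-9 or (L - (t1 - t0)) < 1e-9:
        raise RuntimeError("degenerate division wall")
    arc1 = substring(ring, t0, t1)
    arc2 = substring(ring, t1, L)
    arc2b = substring(ring, 0, t0)
    coords2 = list(arc2.coords) + list(arc2b.coords)[1:]
    p1 = Polygon(list(arc1.coords))
    p2 = Polygon(coords2)
    if not (p1.is_valid and p2.is_valid) or p1.area < 1e-9 or p2.area < 1e-9:
        raise RuntimeError("division produced an invalid polygon")
    return p1, p2


def _dedupe_key(x: float, y: float):
    return (round(x / _SNAP) * _SNAP, round(y / _SNAP) * _SNAP)


def _polygons_to_mesh(polys, width: float, height: float) -> TissueMesh:
    """Assemble a shared-vertex mesh from a set of exactly tiling polygons.

    Vertices of one polygon that lie in the interior of another polygon's
    edge are inserted into that edge so that all face loops are consistent.
    """
    # Collect unique vertices.
    coords: dict = {}
    order: list = []
    for poly in polys:
        for x, y in poly.exterior.coords[:-1]:
            key = _dedupe_key(x, y)
            if key not in coords:
                coords[key] = len(order)
                order.append(key)
    pts = np.array(order, dtype=float)

    # Build face loops, inserting any global vertex lying on an edge interior.
    faces = []
    for poly in polys:
        ring = [_dedupe_key(x, y) for x, y in poly.exterior.coords[:-1]]
        loop: list = []
        m = len(ring)
        for s in range(m):
            a = np.asarray(ring[s])
            b = np.asarray(ring[(s + 1) % m])
            loop.append(coords[ring[s]])
            seg = b - a
            seg_len2 = float(seg @ seg)
            onseg = []
            for key, idx in coords.items():
                if key == ring[s] or key == ring[(s + 1) % m]:
                    continue
                p = np.asarray(key)
                t = float((p - a) @ seg) / seg_len2
                if 1e-12 < t < 1 - 1e-12:
                    proj = a + t * seg
                    if np.hypot(*(p - proj)) < 1e-7:
                        onseg.append((t, idx))
            for _, idx in sorted(onseg):
                loop.append(idx)
        # enforce counter-clockwise winding
        area2 = 0.0
        for s in range(len(loop)):
            x1, y1 = pts[loop[s]]
            x2, y2 = pts[loop[(s + 1) % len(loop)]]
            area2 += x1 * y2 - x2 * y1
        if area2 < 0:
            loop = loop[::-1]
        faces.append(loop)

    edges = set()
    for loop in faces:
        for s in range(len(loop)):
            i, j = loop[s], loop[(s + 1) % len(loop)]
            edges.add((min(i, j), max(i, j)))
    edges = np.array(sorted(edges), dtype=np.int64)

    on_border = (
        (np.abs(pts[:, 0]) < 1e-7)
        | (np.abs(pts[:, 0] - width) < 1e-7)
        | (np.abs(pts[:, 1]) < 1e-7)
        | (np.abs(pts[:, 1] - height) < 1e-7)
    )
    d = pts[edges[:, 1]] - pts[edges[:, 0]]
    lengths = np.hypot(d[:, 0], d[:, 1])
    mesh = TissueMesh(
        positions=pts,
        foundation=pts.copy(),
        edges=edges,
        rest_lengths=lengths,
        rest_angles=np.full(len(pts), np.nan),
        faces=faces,
        fixed=on_border,
    )
    _set_rest_angles(mesh)
    return mesh


def _set_rest_angles(mesh: TissueMesh) -> None:
    """Apply the 2*pi/n rule to every vertex with n >= 2 neighbors."""
    deg = mesh.degrees()
    with np.errstate(divide="ignore"):
        angles = np.where(deg >= 2, TWO_PI / np.maximum(deg, 1), np.nan)
    mesh.rest_angles = angles


def make_cell_grid(
    width: float,
    height: float,
    n_cells: int,
    pinch_fraction: float = 0.1,
    seed: int = 0,
) -> TissueMesh:
    """Build an irregular polygonal nest of ``n_cells`` tiling a rectangle.

    Outer-rectangle vertices are flagged fixed (Dirichlet template frame).
    Rest lengths are set to current lengths and rest angles to 2*pi/n.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not (0.0 <= pinch_fraction < 0.5):
        raise ValueError("pinch_fraction must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    polys = [Polygon([(0, 0), (width, 0), (width, height), (0, height)])]
    while len(polys) < n_cells:
        polys.sort(key=lambda p: p.area, reverse=True)
        parent = polys.pop(0)
        for attempt in range(8):
            try:
                p1, p2 = _divide(parent, pinch_fraction, rng)
                break
            except RuntimeError:
                if attempt == 7:
                    raise
        polys.extend([p1, p2])
    return _polygons_to_mesh(polys, width, height)


def subdivide_long_edges(mesh: TissueMesh, Th_sub: float) -> TissueMesh:
    """Split every boundary edge longer than ``Th_sub`` at its midpoint.

    Each split halves the parent's rest length onto the two children and
    assigns the new degree-2 vertex a rest angle of pi (the 2*pi/n rule).
    New vertices inherit a foundation anchor at their creation position and
    are fixed only if they lie on the fixed template frame.
    """
    mesh = mesh.copy()
    if np.any(mesh.fixed):
        fx = mesh.positions[mesh.fixed]
        bounds = (fx[:, 0].min(), fx[:, 1].min(), fx[:, 0].max(), fx[:, 1].max())
    else:
        bounds = None

    def on_frame(p) -> bool:
        if bounds is None:
            return False
        x0, y0, x1, y1 = bounds
        return (
            abs(p[0] - x0) < 1e-9 or abs(p[0] - x1) < 1e-9
            or abs(p[1] - y0) < 1e-9 or abs(p[1] - y1) < 1e-9
        )

    while True:
        lengths = mesh.edge_lengths()
        too_long = np.where(lengths > Th_sub)[0]
        if len(too_long) == 0:
            break
        positions = list(mesh.positions)
        foundation = list(mesh.foundation)
        rest_angles = list(mesh.rest_angles)
        fixed = list(mesh.fixed)
        new_edges = []
        new_rest = []
        midpoint_of = {}  # (i, j) sorted -> new vertex id
        split = set(int(e) for e in too_long)
        for e, (i, j) in enumerate(mesh.edges):
            if e in split:
                mid = 0.5 * (mesh.positions[i] + mesh.positions[j])
                vid = len(positions)
                positions.append(mid)
                foundation.append(mid.copy())
                rest_angles.append(math.pi)
                fixed.append(bool(mesh.fixed[i] and mesh.fixed[j] and on_frame(mid)))
                midpoint_of[(min(i, j), max(i, j))] = vid
                half = 0.5 * mesh.rest_lengths[e]
                new_edges.extend([(i, vid), (vid, j)])
                new_rest.extend([half, half])
            else:
                new_edges.append((int(i), int(j)))
                new_rest.append(float(mesh.rest_lengths[e]))
        faces = []
        for loop in mesh.faces:
            out = []
            m = len(loop)
            for s in range(m):
                a, b = loop[s], loop[(s + 1) % m]
                out.append(a)
                key = (min(a, b), max(a, b))
                if key in midpoint_of:
                    out.append(midpoint_of[key])
            faces.append(out)
        mesh = TissueMesh(
            positions=np.array(positions),
            foundation=np.array(foundation),
            edges=np.array(new_edges, dtype=np.int64),
            rest_lengths=np.array(new_rest),
            rest_angles=np.array(rest_angles),
            faces=faces,
            fixed=np.array(fixed, dtype=bool),
        )
    return mesh


def init_rest_state(mesh: TissueMesh) -> TissueMesh:
    """Set the unstressed reference state from the current geometry.

    Every rest length becomes the edge's current length and every vertex
    rest angle becomes 2*pi/n (pi for chain vertices, 2*pi/3 at three-way
    junctions); foundation anchors snap to current positions.  The result
    carries zero stretch, bending and foundation energy.
    """
    deg = mesh.degrees()
    lonely = np.where((deg < 2) & ~mesh.fixed)[0]
    if len(lonely):
        raise ValueError(
            f"vertices with fewer than 2 neighbors cannot anchor springs: {lonely.tolist()}"
        )
    mesh = mesh.copy()
    mesh.rest_lengths = mesh.edge_lengths().copy()
    _set_rest_angles(mesh)
    mesh.foundation = mesh.positions.copy()
    return mesh
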