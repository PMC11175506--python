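"""Shape statistics: area, perimeter, circularity, straightness, fluctuation
RMS and morphospace summary tables.

Circularity is ``4 * pi * area / perimeter**2`` — 1 for a circle, decreasing
as the outline becomes more convoluted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from skimage import measure


@dataclass
class PolygonStats:
    cell_id: int
    area: float
    perimeter: float
    circularity: float

    @property
    def valid(self) -> bool:
        return np.isfinite(self.circularity)


def polygon_stats(points, scale: float = 1.0, cell_id: int = 0) -> PolygonStats:
    """Area (surveyor's formula), perimeter and circularity of a closed loop.

    ``points`` is an ordered loop of 2D coordinates (closing point optional);
    ``scale`` converts to micrometres (e.g. the pixel size).  A
    self-intersecting loop yields NaN circularity (flagged result).
    """
    pts = np.asarray(points, dtype=float) * scale
    if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        raise ValueError("polygon needs at least 3 distinct points")
    x, y = pts[:, 0], pts[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    perimeter = float(np.hypot(d[:, 0], d[:, 1]).sum())
    simple = Polygon(pts).is_valid
    if not simple or perimeter <= 0:
        circ = float("nan")
    else:
        circ = 4.0 * math.pi * area / perimeter**2
    return PolygonStats(cell_id=cell_id, area=float(area), perimeter=perimeter,
                        circularity=circ)


def junction_straightness(polyline) -> float:
    """End-to-end distance over arc length of an open polyline, in [0, 1]."""
    pts = np.asarray(polyline, dtype=float)
    if len(pts) < 2:
        raise ValueError("polyline needs at least 2 points")
    d = np.diff(pts, axis=0)
    arc = float(np.hypot(d[:, 0], d[:, 1]).sum())
    if arc <= 0:
        raise ValueError("polyline has zero arc length")
    return float(np.hypot(*(pts[-1] - pts[0])) / arc)


def vertex_fluctuation_rms(
    trajectories: np.ndarray, drift_correct: bool = True
) -> tuple[float, np.ndarray]:
    """Positional fluctuation RMS of tracked vertices.

    ``trajectories`` has shape (n_vertices, T, 2).  With ``drift_correct``
    the frame-wise displacement of the center of mass of all vertices is
    subtracted from every trajectory first.  The scalar RMS pools squared
    displacements from each vertex's time-mean position over time and
    vertices before taking the root; per-vertex RMS values are also
    returned.
    """
    traj = np.asarray(trajectories, dtype=float)
    if traj.ndim != 3 or traj.shape[2] != 2:
        raise ValueError("trajectories must have shape (n_vertices, T, 2)")
    n, T, _ = traj.shape
    if n < 1 or T < 2:
        raise ValueError("need at least 1 vertex and 2 time points")
    if drift_correct:
        com = traj.mean(axis=0)  # (T, 2)
        traj = traj - (com - com[0])[None, :, :]
    dev = traj - traj.mean(axis=1, keepdims=True)
    sq = np.sum(dev**2, axis=2)  # (n, T): squared planar displacement
    per_vertex = np.sqrt(sq.mean(axis=1))
    return float(np.sqrt(sq.mean())), per_vertex


# ----------------------------------------------------------------------
# Junction chains on a mesh
# ----------------------------------------------------------------------

def junction_polylines(mesh) -> list:
    """Vertex-index chains between junction/fixed endpoints of a mesh.

    Chains are maximal runs of free degree-2 vertices delimited by
    junctions (degree != 2) or fixed vertices; each is returned once.
    """
    deg = mesh.degrees()
    nbrs = mesh.adjacency()
    is_end = (deg != 2) | mesh.fixed
    seen = set()
    chains = []
    for v in np.where(is_end)[0]:
        for start in nbrs[v]:
            key = (min(v, start), max(v, start))
            if key in seen:
                continue
            path = [int(v), int(start)]
            seen.add(key)
            prev, cur = v, start
            while not is_end[cur]:
                nxt = [u for u in nbrs[cur] if u != prev][0]
                seen.add((min(cur, nxt), max(cur, nxt)))
                prev, cur = cur, nxt
                path.append(int(cur))
            chains.append(path)
    return chains


def count_inflection_clusters(points, angle_floor: float = 0.1) -> int:
    """Number of same-sign runs of significant turning along a polyline.

    Discrete turning angles below ``angle_floor`` (radians) are treated as
    straight; a straight chain scores 0, one lobule 1, an undulating chain
    one per alternation.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        return 0
    seg = np.diff(pts, axis=0)
    ang = np.arctan2(seg[:, 1], seg[:, 0])
    turn = np.mod(np.diff(ang) + np.pi, 2 * np.pi) - np.pi
    signs = np.sign(turn[np.abs(turn) > angle_floor])
    if len(signs) == 0:
        return 0
    return int(1 + np.count_nonzero(np.diff(signs) != 0))


def mesh_inflection_count(mesh, angle_floor: float = 0.1) -> int:
    """Total inflection clusters over all junction chains of a mesh."""
    return sum(
        count_inflection_clusters(mesh.positions[chain], angle_floor)
        for chain in junction_polylines(mesh)
    )


# ----------------------------------------------------------------------
# Label-image path
# ----------------------------------------------------------------------

def label_image_stats(labels: np.ndarray, pixel_size: float) -> list:
    """Per-cell :class:`PolygonStats` from an integer label image.

    Each label's outline is extracted with marching squares at the 0.5
    level of its binary mask, then measured as a polygon in micrometres.
    Label 0 is background.
    """
    labels = np.asarray(labels)
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    out = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        # pad so border-touching labels still yield closed contours
        mask = np.pad((labels == lab).astype(float), 1)
        contours = measure.find_contours(mask, 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        out.append(polygon_stats(contour, scale=pixel_size, cell_id=int(lab)))
    return out


# ----------------------------------------------------------------------
# Morphospace tables
# ----------------------------------------------------------------------

def morphospace_summary(
    stats: list,
    groups: list | None = None,
    n_bins: int = 16,
    area_range: tuple | None = None,
    perimeter_range: tuple | None = None,
) -> dict:
    """Per-group medians/quartiles plus 2D bin counts in the
    perimeter-area and circularity-area planes.

    Returns ``{"groups": DataFrame, "perimeter_area": DataFrame,
    "circularity_area": DataFrame}`` with declared bin edges in the count
    tables.  Empty groups yield NaN rows.  Deterministic and order-invariant.
    """
    if not stats:
        raise ValueError("stats must be non-empty")
    if groups is None:
        groups = ["all"] * len(stats)
    df = pd.DataFrame(
        {
            "group": groups,
            "cell_id": [s.cell_id for s in stats],
            "area": [s.area for s in stats],
            "perimeter": [s.perimeter for s in stats],
            "circularity": [s.circularity for s in stats],
        }
    ).sort_values(["group", "cell_id", "area"], kind="stable")

    rows = []
    for g, sub in df.groupby("group", sort=True):
        row = {"group": g, "n": len(sub)}
        for col in ("area", "perimeter", "circularity"):
            vals = sub[col].dropna()
            if len(vals):
                row[f"{col}_q25"], row[f"{col}_median"], row[f"{col}_q75"] = (
                    np.percentile(vals, [25, 50, 75])
                )
            else:
                row[f"{col}_q25"] = row[f"{col}_median"] = row[f"{col}_q75"] = float("nan")
        rows.append(row)
    group_df = pd.DataFrame(rows)

    a_rng = area_range or (0.0, max(df["area"].max(), 1e-9))
    p_rng = perimeter_range or (0.0, max(df["perimeter"].max(), 1e-9))
    a_edges = np.linspace(*a_rng, n_bins + 1)
    p_edges = np.linspace(*p_rng, n_bins + 1)
    c_edges = np.linspace(0.0, 1.0, n_bins + 1)

    def bin_table(xcol, xedges, ycol, yedges):
        recs = []
        for g, sub in df.groupby("group", sort=True):
            h, _, _ = np.histogram2d(sub[xcol].fillna(-1), sub[ycol].fillna(-1),
                                     bins=[xedges, yedges])
            xi, yi = np.nonzero(h)
            for i, j in zip(xi, yi):
                recs.append(
                    {
                        "group": g,
                        f"{xcol}_lo": xedges[i], f"{xcol}_hi": xedges[i + 1],
                        f"{ycol}_lo": yedges[j], f"{ycol}_hi": yedges[j + 1],
                        "count": int(h[i, j]),
                    }
                )
        return pd.DataFrame(recs)

    return {
        "groups": group_df,
        "perimeter_area": bin_table("perimeter", p_edges, "area", a_edges),
        "circularity_area": bin_table("circularity", c_edges, "area", a_edges),
    }
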