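"""The quasi-static simulation loop.

Each iteration executes, in order: connection placement (self-contact
penalty springs), boundary growth plus domain shrinkage, implicit
relaxation to mechanical equilibrium, subdivision of over-long segments,
and the plastic update of the elastic foundation anchors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.strtree import STRtree

from .core import ConnectionSet, SimParams, TissueMesh
from .initializer import subdivide_long_edges
from .mechanics import ForceReport, solve_equilibrium, total_energy
from .morphometrics import polygon_stats

log = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# Connection placement (penalty method against self-contact)
# ----------------------------------------------------------------------

def _cross(ax, ay, bx, by):
    return ax * by - ay * bx


def _proper_crossings(p0, p1, q0, q1) -> np.ndarray:
    """Vectorized proper segment crossing test (strict interior crossing)."""
    d1 = _cross(q1[:, 0] - q0[:, 0], q1[:, 1] - q0[:, 1], p0[:, 0] - q0[:, 0], p0[:, 1] - q0[:, 1])
    d2 = _cross(q1[:, 0] - q0[:, 0], q1[:, 1] - q0[:, 1], p1[:, 0] - q0[:, 0], p1[:, 1] - q0[:, 1])
    d3 = _cross(p1[:, 0] - p0[:, 0], p1[:, 1] - p0[:, 1], q0[:, 0] - p0[:, 0], q0[:, 1] - p0[:, 1])
    d4 = _cross(p1[:, 0] - p0[:, 0], p1[:, 1] - p0[:, 1], q1[:, 0] - p0[:, 0], q1[:, 1] - p0[:, 1])
    return (d1 * d2 < 0) & (d3 * d4 < 0)


def _tangents(mesh: TissueMesh) -> np.ndarray:
    """Unit local boundary tangent per vertex.

    Degree-2 vertices use the chord between their two chain neighbors; at
    junctions the tangent is taken per incident edge during the angle test,
    so here we store the first incident edge direction as a fallback.
    """
    nbrs = mesh.adjacency()
    t = np.zeros_like(mesh.positions)
    for v, nn in enumerate(nbrs):
        if len(nn) == 2:
            d = mesh.positions[nn[1]] - mesh.positions[nn[0]]
        elif nn:
            d = mesh.positions[nn[0]] - mesh.positions[v]
        else:
            d = np.array([1.0, 0.0])
        n = np.hypot(*d)
        t[v] = d / n if n > 0 else (1.0, 0.0)
    return t


def place_connections(mesh: TissueMesh, params: SimParams) -> ConnectionSet:
    """Place compression-only springs between close, mutually visible vertices.

    A pair qualifies if the vertices are within ``length_factor * Th_sub``,
    at topological distance >= 3 (not neighbors nor neighbors of neighbors),
    mutually visible (the segment properly crosses no boundary edge), and
    the segment meets the local boundary tangent at both ends at an angle
    above ``angle_threshold``.  Rest lengths are set on the tangent circle
    of diameter ``Th_sub``: ``l_rest = Th_sub * sin(alpha)`` with ``alpha``
    the smaller of the two boundary angles.
    """
    pts = mesh.positions
    if mesh.n_edges == 0 or mesh.n_vertices < 4:
        return ConnectionSet(stiffness=params.k_connect)
    radius = params.length_factor * params.Th_sub
    tree = cKDTree(pts)
    raw = tree.query_pairs(radius, output_type="ndarray")
    if len(raw) == 0:
        return ConnectionSet(stiffness=params.k_connect)

    nbrs = mesh.adjacency()
    nbr_sets = [set(nn) for nn in nbrs]

    def too_close(i, j):
        if j in nbr_sets[i]:
            return True
        return any(j in nbr_sets[m] for m in nbrs[i])

    keep = np.array([not too_close(i, j) for i, j in raw], dtype=bool)
    raw = raw[keep]
    if len(raw) == 0:
        return ConnectionSet(stiffness=params.k_connect)

    # Angle to local boundary tangent at both endpoints.
    tan = _tangents(mesh)
    d = pts[raw[:, 1]] - pts[raw[:, 0]]
    dn = np.hypot(d[:, 0], d[:, 1])
    u = d / np.maximum(dn, 1e-12)[:, None]
    sin_i = np.abs(_cross(u[:, 0], u[:, 1], tan[raw[:, 0], 0], tan[raw[:, 0], 1]))
    sin_j = np.abs(_cross(u[:, 0], u[:, 1], tan[raw[:, 1], 0], tan[raw[:, 1], 1]))
    # A connection exists as soon as ONE endpoint sees it at a steep enough
    # angle (a vertex ramming an opposing chain head-on must still be
    # repelled even though the angle at the rammed chain is shallow).
    sin_a = np.maximum(np.clip(sin_i, 0, 1), np.clip(sin_j, 0, 1))
    alpha = np.arcsin(sin_a)
    keep = alpha > params.angle_threshold
    raw, sin_a, dn = raw[keep], sin_a[keep], dn[keep]
    if len(raw) == 0:
        return ConnectionSet(stiffness=params.k_connect)

    # Mutual visibility: no proper crossing with any boundary edge.
    edge_coords = pts[mesh.edges]  # (E, 2, 2)
    seg_coords = np.stack([pts[raw[:, 0]], pts[raw[:, 1]]], axis=1)
    tree2 = STRtree(shapely.linestrings(edge_coords))
    qi, ti = tree2.query(shapely.linestrings(seg_coords))
    if len(qi):
        shares = (
            (mesh.edges[ti, 0] == raw[qi, 0])
            | (mesh.edges[ti, 0] == raw[qi, 1])
            | (mesh.edges[ti, 1] == raw[qi, 0])
            | (mesh.edges[ti, 1] == raw[qi, 1])
        )
        qi, ti = qi[~shares], ti[~shares]
    blocked = np.zeros(len(raw), dtype=bool)
    if len(qi):
        crossing = _proper_crossings(
            seg_coords[qi, 0], seg_coords[qi, 1],
            edge_coords[ti, 0], edge_coords[ti, 1],
        )
        blocked[np.unique(qi[crossing])] = True
    raw, sin_a = raw[~blocked], sin_a[~blocked]

    rest = params.Th_sub * sin_a
    return ConnectionSet(pairs=raw, rest_lengths=rest, stiffness=params.k_connect)


# ----------------------------------------------------------------------
# Growth, shrinkage, foundation plasticity
# ----------------------------------------------------------------------

def grow_rest_lengths(mesh: TissueMesh, params: SimParams) -> TissueMesh:
    """Multiply every boundary rest length by ``(1 + dt * g_b)``."""
    mesh = mesh.copy()
    mesh.rest_lengths = mesh.rest_lengths * (1.0 + params.dt * params.g_b)
    return mesh


def template_center(mesh: TissueMesh) -> np.ndarray:
    ref = mesh.positions[mesh.fixed] if np.any(mesh.fixed) else mesh.positions
    return 0.5 * (ref.min(axis=0) + ref.max(axis=0))


def template_width(mesh: TissueMesh, params: SimParams) -> float:
    axis = 0 if params.shrink_axis == "x" else 1
    ref = mesh.positions[mesh.fixed] if np.any(mesh.fixed) else mesh.positions
    return float(ref[:, axis].max() - ref[:, axis].min())


def shrink_domain(mesh: TissueMesh, params: SimParams) -> TissueMesh:
    """Scale all positions (and anchors) along the shrink axis about the center.

    The per-step scale is ``1 - g_axis * dt`` (``g_axis`` is the shrink-rate
    magnitude, 0.6 by default, giving 0.997 per step at dt = 0.005).
    """
    if abs(params.g_axis * params.dt) >= 1.0:
        raise ValueError("|g_axis * dt| must be < 1")
    scale = 1.0 - params.g_axis * params.dt
    if scale == 1.0:
        return mesh.copy()
    axis = 0 if params.shrink_axis == "x" else 1
    mesh = mesh.copy()
    c = template_center(mesh)[axis]
    mesh.positions[:, axis] = c + (mesh.positions[:, axis] - c) * scale
    mesh.foundation[:, axis] = c + (mesh.foundation[:, axis] - c) * scale
    return mesh


def update_foundation(mesh: TissueMesh, params: SimParams) -> TissueMesh:
    """Move each anchor a fraction ``dt_foundation`` of the way to its vertex."""
    mesh = mesh.copy()
    mesh.foundation = mesh.foundation + (
        mesh.positions - mesh.foundation
    ) * params.dt_foundation
    return mesh


# ----------------------------------------------------------------------
# Step and run drivers
# ----------------------------------------------------------------------

@dataclass
class StepLog:
    step: int
    energy: float
    residual: float
    converged: bool
    n_connections: int
    n_vertices: int
    mean_circularity: float
    template_width: float


def mean_circularity(mesh: TissueMesh) -> float:
    vals = []
    for face in mesh.faces:
        if len(face) >= 3:
            st = polygon_stats(mesh.positions[face])
            if np.isfinite(st.circularity):
                vals.append(st.circularity)
    return float(np.mean(vals)) if vals else float("nan")


def simulation_step(
    mesh: TissueMesh,
    params: SimParams,
    step: int = 0,
    shrink: bool = True,
) -> tuple[TissueMesh, StepLog]:
    """One loop iteration in the canonical order.

    place_connections -> grow_rest_lengths + shrink_domain ->
    solve_equilibrium -> subdivide_long_edges -> update_foundation.
    """
    connections = place_connections(mesh, params)
    mesh = grow_rest_lengths(mesh, params)
    if shrink and params.g_axis != 0.0:
        mesh = shrink_domain(mesh, params)
    mesh, report = solve_equilibrium(mesh, connections, params)
    if not report.converged:
        log.warning("step %d: solver did not converge (residual %.3g)", step, report.residual)
    mesh = subdivide_long_edges(mesh, params.Th_sub)
    mesh = update_foundation(mesh, params)
    entry = StepLog(
        step=step,
        energy=report.energy,
        residual=report.residual,
        converged=report.converged,
        n_connections=len(connections),
        n_vertices=mesh.n_vertices,
        mean_circularity=mean_circularity(mesh),
        template_width=template_width(mesh, params),
    )
    return mesh, entry


def run_simulation(
    mesh: TissueMesh,
    params: SimParams,
    n_steps: int,
    snapshot_every: int | None = None,
    out_dir=None,
    stop_width_fraction: float = 0.4,
) -> tuple[list, pd.DataFrame]:
    """Run the loop for ``n_steps``; returns (snapshots, per-step log).

    Domain shrinkage stops once the template width along the shrink axis
    falls below ``stop_width_fraction`` of its initial value (growth and
    relaxation continue).  Deterministic: the loop draws no random numbers.
    """
    from .core import write_mesh  # local import to avoid cycle at module load

    snapshots = [mesh.copy()]
    rows = []
    width0 = template_width(mesh, params)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_mesh(mesh, out_dir / "snapshot_000000.txt")
    for step in range(1, n_steps + 1):
        shrink = template_width(mesh, params) > stop_width_fraction * width0
        mesh, entry = simulation_step(mesh, params, step=step, shrink=shrink)
        rows.append(asdict(entry))
        if snapshot_every and (step % snapshot_every == 0 or step == n_steps):
            snapshots.append(mesh.copy())
            if out_dir is not None:
                write_mesh(mesh, out_dir / f"snapshot_{step:06d}.txt")
    if not snapshot_every and n_steps > 0:
        snapshots.append(mesh.copy())
        if out_dir is not None:
            write_mesh(mesh, out_dir / f"snapshot_{n_steps:06d}.txt")
    log_df = pd.DataFrame(
        rows,
        columns=["step", "energy", "residual", "converged", "n_connections",
                 "n_vertices", "mean_circularity", "template_width"],
    )
    if out_dir is not None:
        log_df.to_csv(out_dir / "run_log.csv", index=False)
    return snapshots, log_df


def boundary_self_crossings(mesh: TissueMesh) -> int:
    """Count proper crossings between non-adjacent boundary edges."""
    pts = mesh.positions
    coords = pts[mesh.edges]
    geoms = shapely.linestrings(coords)
    tree = STRtree(geoms)
    qi, ti = tree.query(geoms)
    mask = qi < ti
    qi, ti = qi[mask], ti[mask]
    shares = (
        (mesh.edges[qi, 0] == mesh.edges[ti, 0])
        | (mesh.edges[qi, 0] == mesh.edges[ti, 1])
        | (mesh.edges[qi, 1] == mesh.edges[ti, 0])
        | (mesh.edges[qi, 1] == mesh.edges[ti, 1])
    )
    qi, ti = qi[~shares], ti[~shares]
    if not len(qi):
        return 0
    crossing = _proper_crossings(coords[qi, 0], coords[qi, 1], coords[ti, 0], coords[ti, 1])
    return int(np.count_nonzero(crossing))
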