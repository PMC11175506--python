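"""Force laws and quasi-static equilibrium solving.

Boundary segments act as linear springs with force proportional to their
relative stretch, ``F = k * (l / l_rest - 1)``; angular springs penalize
deviations of the inter-neighbor angle from its rest value; an elastic
foundation pulls every vertex back toward its anchor; compression-only
connection springs penalize self-contact.

Equilibration integrates the overdamped dynamics ``x' = F`` with a
backward-Euler (proximal) scheme: each implicit step minimizes
``E(x) + |x - x_prev|^2 / (2 h)``, which guarantees a monotone energy
decrease; the step size ``h`` is adapted upward so that in practice the
solver converges directly to the energy minimum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .core import ConnectionSet, SimParams, TissueMesh

log = logging.getLogger(__name__)

TWO_PI = 2.0 * math.pi


# ----------------------------------------------------------------------
# Scalar force laws
# ----------------------------------------------------------------------

def edge_force(l: float, l_rest: float, k: float):
    """Axial spring force ``k * (l / l_rest - 1)``.

    Positive values are tension (pulling the endpoints together).
    """
    l = np.asarray(l, dtype=float)
    if np.any(np.asarray(l_rest) <= 0):
        raise ValueError("l_rest must be > 0")
    out = k * (l / l_rest - 1.0)
    return float(out) if out.ndim == 0 else out


def bending_torque(theta: float, theta_rest: float, k_bend: float) -> float:
    """Restoring torque ``k_bend * (theta - theta_rest)``."""
    return k_bend * (theta - theta_rest)


def foundation_force(p_current, p_foundation, k_foundation: float) -> np.ndarray:
    """Hookean pull toward the anchor, ``k_foundation * (P_foundation - P_current)``.

    The stretch-ratio law used for boundary springs is undefined at zero rest
    length (anchor coincident with vertex), so the foundation spring is
    Hookean in the displacement with a unit reference length.
    """
    p_current = np.asarray(p_current, dtype=float)
    p_foundation = np.asarray(p_foundation, dtype=float)
    return k_foundation * (p_foundation - p_current)


def connection_force(l: float, rest_length: float, k_connect: float):
    """Compression-only penalty force: ``k * (l/rest - 1)`` if ``l < rest``, else 0."""
    l = np.asarray(l, dtype=float)
    out = np.where(l < rest_length, k_connect * (l / rest_length - 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


# ----------------------------------------------------------------------
# Angular-spring bookkeeping
# ----------------------------------------------------------------------

def bend_triplets(mesh: TissueMesh, params: SimParams):
    """Assemble angular-spring triplets ``(a, v, b)`` and their rest angles.

    Degree-2 vertices carry one spring between their two chain neighbors.
    With ``params.junction_bending`` enabled, degree-3 vertices carry one
    spring per wedge between azimuthally consecutive neighbors (rest angle
    2*pi/3).  Springs whose three vertices are all fixed are skipped — they
    can never produce a force and would only add a constant to the energy.
    """
    nbrs = mesh.adjacency()
    trips: list = []
    rests: list = []
    for v in range(mesh.n_vertices):
        nn = nbrs[v]
        if len(nn) == 2:
            rest = mesh.rest_angles[v]
            if not np.isfinite(rest):
                continue
            a, b = nn
            if mesh.fixed[v] and mesh.fixed[a] and mesh.fixed[b]:
                continue
            trips.append((a, v, b))
            rests.append(rest)
        elif len(nn) == 3 and params.junction_bending:
            rest = mesh.rest_angles[v]
            if not np.isfinite(rest):
                rest = TWO_PI / 3.0
            d = mesh.positions[nn] - mesh.positions[v]
            order = np.argsort(np.arctan2(d[:, 1], d[:, 0]))
            ordered = [nn[o] for o in order]
            for k in range(3):
                a = ordered[k]
                b = ordered[(k + 1) % 3]
                if mesh.fixed[v] and mesh.fixed[a] and mesh.fixed[b]:
                    continue
                trips.append((a, v, b))
                rests.append(rest)
    if not trips:
        return np.empty((0, 3), dtype=np.int64), np.empty(0)
    return np.asarray(trips, dtype=np.int64), np.asarray(rests, dtype=float)


def wedge_angles(pos: np.ndarray, trips: np.ndarray) -> np.ndarray:
    """Angle at ``v`` from neighbor ``a`` to neighbor ``b``, wrapped to [0, 2pi)."""
    u1 = pos[trips[:, 0]] - pos[trips[:, 1]]
    u2 = pos[trips[:, 2]] - pos[trips[:, 1]]
    th = np.arctan2(u2[:, 1], u2[:, 0]) - np.arctan2(u1[:, 1], u1[:, 0])
    return np.mod(th, TWO_PI)


# ----------------------------------------------------------------------
# Energy and gradient assembly
# ----------------------------------------------------------------------

def _stretch_k(params: SimParams, eps: np.ndarray) -> np.ndarray:
    if params.k_b_compression is None:
        return np.full_like(eps, params.k_b)
    return np.where(eps < 0, params.k_b_compression, params.k_b)


def energy_and_forces(
    mesh: TissueMesh,
    connections: ConnectionSet | None = None,
    params: SimParams | None = None,
    positions: np.ndarray | None = None,
    trips_cache=None,
):
    """Total elastic energy and per-vertex force vectors (= -gradient).

    Returns ``(energy, forces)`` with ``forces`` of shape (N, 2).  Forces on
    fixed vertices are computed (for reporting reaction forces) but the
    solver never applies them.
    """
    params = params or SimParams()
    pos = mesh.positions if positions is None else positions
    forces = np.zeros_like(pos)
    energy = 0.0

    # Stretch springs -------------------------------------------------
    if mesh.n_edges:
        i, j = mesh.edges[:, 0], mesh.edges[:, 1]
        d = pos[j] - pos[i]
        l = np.hypot(d[:, 0], d[:, 1])
        l = np.maximum(l, 1e-12)
        eps = l / mesh.rest_lengths - 1.0
        k = _stretch_k(params, eps)
        energy += float(np.sum(0.5 * k * mesh.rest_lengths * eps**2))
        f = (k * eps / l)[:, None] * d  # force on i (toward j when stretched)
        np.add.at(forces, i, f)
        np.add.at(forces, j, -f)

    # Bending springs -------------------------------------------------
    if trips_cache is None:
        trips, rests = bend_triplets(mesh, params)
    else:
        trips, rests = trips_cache
    if len(trips) and params.k_bend > 0:
        a, v, b = trips[:, 0], trips[:, 1], trips[:, 2]
        u1 = pos[a] - pos[v]
        u2 = pos[b] - pos[v]
        r1 = np.maximum(np.einsum("ij,ij->i", u1, u1), 1e-24)
        r2 = np.maximum(np.einsum("ij,ij->i", u2, u2), 1e-24)
        th = np.mod(
            np.arctan2(u2[:, 1], u2[:, 0]) - np.arctan2(u1[:, 1], u1[:, 0]), TWO_PI
        )
        dth = th - rests
        energy += float(np.sum(0.5 * params.k_bend * dth**2))
        # d(theta)/da = perp(u1)/|u1|^2 with perp(u) = (u_y, -u_x); see below.
        ga = np.stack([u1[:, 1], -u1[:, 0]], axis=1) / r1[:, None]
        gb = np.stack([-u2[:, 1], u2[:, 0]], axis=1) / r2[:, None]
        coeff = (params.k_bend * dth)[:, None]
        np.add.at(forces, a, -coeff * ga)
        np.add.at(forces, b, -coeff * gb)
        np.add.at(forces, v, coeff * (ga + gb))

    # Foundation ------------------------------------------------------
    if params.k_foundation > 0 and len(mesh.foundation):
        disp = mesh.foundation - pos
        energy += float(0.5 * params.k_foundation * np.sum(disp**2))
        forces += params.k_foundation * disp

    # Connections (compression-only) ----------------------------------
    if connections is not None and len(connections):
        i, j = connections.pairs[:, 0], connections.pairs[:, 1]
        d = pos[j] - pos[i]
        l = np.maximum(np.hypot(d[:, 0], d[:, 1]), 1e-12)
        eps = l / connections.rest_lengths - 1.0
        active = eps < 0
        if np.any(active):
            kc = connections.stiffness
            lr = connections.rest_lengths[active]
            e = eps[active]
            energy += float(np.sum(0.5 * kc * lr * e**2))
            f = (kc * e / l[active])[:, None] * d[active]
            np.add.at(forces, i[active], f)
            np.add.at(forces, j[active], -f)

    return energy, forces


def total_energy(
    mesh: TissueMesh,
    connections: ConnectionSet | None = None,
    params: SimParams | None = None,
) -> float:
    return energy_and_forces(mesh, connections, params)[0]


# ----------------------------------------------------------------------
# Equilibrium solver
# ----------------------------------------------------------------------

@dataclass
class ForceReport:
    forces: np.ndarray
    energy: float
    residual: float
    converged: bool
    n_iter: int
    energy_trace: list = field(default_factory=list)

    def to_frame(self):
        """Per-vertex force table (for CSV dumps)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "vertex_id": np.arange(len(self.forces)),
                "fx": self.forces[:, 0],
                "fy": self.forces[:, 1],
                "magnitude": np.hypot(self.forces[:, 0], self.forces[:, 1]),
            }
        )


def _residual(forces: np.ndarray, fixed: np.ndarray) -> float:
    free = ~fixed
    if not np.any(free):
        return 0.0
    return float(np.max(np.hypot(forces[free, 0], forces[free, 1])))


def _solve_newton(mesh, connections, params, trips_cache, trace):
    """Damped-Newton relaxation (dense FD Hessian of the analytic gradient).

    Quadratically convergent and able to leave shallow saddle points via the
    trust region; intended for small systems (beam scans) where residual
    tolerances far below the force scale are required.
    """
    free = ~mesh.fixed
    nfree = int(np.count_nonzero(free))
    base = mesh.positions.copy()

    def unpack(x):
        pos = base.copy()
        pos[free] = x.reshape(nfree, 2)
        return pos

    def fun(x):
        return energy_and_forces(mesh, connections, params, positions=unpack(x),
                                 trips_cache=trips_cache)[0]

    def jac(x):
        f = energy_and_forces(mesh, connections, params, positions=unpack(x),
                              trips_cache=trips_cache)[1]
        return -f[free].ravel()

    def hess(x):
        m = len(x)
        H = np.empty((m, m))
        g0 = jac(x)
        eps = 1e-6
        for i in range(m):
            xp = x.copy()
            xp[i] += eps
            H[:, i] = (jac(xp) - g0) / eps
        return 0.5 * (H + H.T)

    result = minimize(
        fun, mesh.positions[free].ravel(), jac=jac, hess=hess,
        method="trust-exact",
        options={"maxiter": params.solver_max_iter, "gtol": 0.5 * params.solver_tol},
    )
    mesh.positions = unpack(result.x)
    e, f = energy_and_forces(mesh, connections, params, trips_cache=trips_cache)
    res = _residual(f, mesh.fixed)
    trace.append(e)
    if res >= params.solver_tol:
        log.warning("newton solve: residual %.3g above tol %.3g", res, params.solver_tol)
    return mesh, ForceReport(f, e, res, res < params.solver_tol, int(result.nit), trace)


def solve_equilibrium(
    mesh: TissueMesh,
    connections: ConnectionSet | None = None,
    params: SimParams | None = None,
    method: str = "lbfgs",
) -> tuple[TissueMesh, ForceReport]:
    """Relax non-fixed vertices until the residual force drops below tolerance.

    The implicit backward-Euler step minimizes the proximal objective
    ``E(x) + |x - x0|^2 / (2h)``; ``h`` grows geometrically while steps keep
    lowering the energy, so the scheme terminates at the energy minimum.
    ``method="newton"`` switches to a dense trust-region Newton solve (small
    systems, very tight tolerances).  Returns the relaxed mesh (a copy) and
    a :class:`ForceReport`.
    """
    params = params or SimParams()
    mesh = mesh.copy()
    trips_cache = bend_triplets(mesh, params)
    free = ~mesh.fixed
    nfree = int(np.count_nonzero(free))

    energy0, forces = energy_and_forces(mesh, connections, params, trips_cache=trips_cache)
    res = _residual(forces, mesh.fixed)
    trace = [energy0]
    if nfree == 0 or res < params.solver_tol:
        return mesh, ForceReport(forces, energy0, res, True, 0, trace)
    if method == "newton":
        return _solve_newton(mesh, connections, params, trips_cache, trace)
    if method != "lbfgs":
        raise ValueError(f"unknown method {method!r}")

    base = mesh.positions.copy()

    def unpack(x):
        pos = base.copy()
        pos[free] = x.reshape(nfree, 2)
        return pos

    h = 1e3  # large step: effectively direct minimization, proximal term for safety
    x = mesh.positions[free].ravel().copy()
    total_iters = 0
    energy_prev = energy0
    stalled = 0

    while total_iters < params.solver_max_iter:
        x0 = x.copy()

        def objective(xf):
            pos = unpack(xf)
            e, f = energy_and_forces(mesh, connections, params, positions=pos,
                                     trips_cache=trips_cache)
            g = -f[free].ravel()
            dx = xf - x0
            return e + np.dot(dx, dx) / (2.0 * h), g + dx / h

        result = minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": max(params.solver_max_iter - total_iters, 1),
                "gtol": 0.5 * params.solver_tol,
                "ftol": 1e-16,
            },
        )
        total_iters += int(result.nit) + 1
        pos = unpack(result.x)
        e, f = energy_and_forces(mesh, connections, params, positions=pos,
                                 trips_cache=trips_cache)
        if e <= energy_prev + 1e-12 * max(1.0, abs(energy_prev)):
            x = result.x
            mesh.positions = pos
            trace.append(e)
            res_new = _residual(f, mesh.fixed)
            forces = f
            if res_new < params.solver_tol:
                return mesh, ForceReport(forces, e, res_new, True, total_iters, trace)
            # Re-centering the proximal term shrinks the dx/h bias each
            # round; treat vanishing progress in both energy and residual
            # as stagnation.
            if result.nit <= 1 and res_new > 0.99 * res and e > energy_prev - 1e-14:
                stalled += 1
            else:
                stalled = 0
            energy_prev = e
            res = res_new
            if stalled >= 3:
                break
            h *= 10.0
        else:
            h /= 10.0
            if h < 1e-10:
                break

    log.warning("solve_equilibrium: residual %.3g above tol %.3g after %d iterations",
                res, params.solver_tol, total_iters)
    return mesh, ForceReport(forces, energy_prev, res, res < params.solver_tol,
                             total_iters, trace)
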