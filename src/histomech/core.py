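"""Domain types, parameters, mesh validation and plain-text serialization.

Lengths are in micrometres.  Stiffnesses (``k_b``, ``k_bend``, ``k_connect``,
``k_foundation``) are dimensionless model constants; forces and energies are
reported in the corresponding model units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
import numpy as np
from shapely.geometry import Polygon


class MeshParseError(ValueError):
    """Raised when a mesh file cannot be parsed; message names line and field."""


@dataclass
class SimParams:
    """Simulation parameter set.

    Defaults reproduce the published parameter table: subdivision threshold
    1 um, boundary stiffness 0.2, bending stiffness 0.0005, connection
    stiffness 0.1, template shrink rate magnitude 0.6, boundary growth rate
    1.0, growth time step 0.005, foundation stiffness 0.1 and foundation
    relaxation fraction 0.01.

    The table prints the template growth pair as ``(0, -0.6)`` while the
    accompanying text describes contraction along X (``g_X < 0``, ``g_Y = 0``).
    We keep a single ``shrink_axis`` plus a rate magnitude ``g_axis`` and
    default the axis to X, following the textual description of intent.
    """

    Th_sub: float = 1.0
    k_b: float = 0.2
    k_bend: float = 0.0005
    k_connect: float = 0.1
    g_axis: float = 0.6
    shrink_axis: str = "x"
    g_b: float = 1.0
    dt: float = 0.005
    k_foundation: float = 0.1
    dt_foundation: float = 0.01
    length_factor: float = 1.5
    angle_threshold: float = math.pi / 4
    solver_tol: float = 1e-4
    solver_max_iter: int = 5000
    seed: int = 0
    # Optional asymmetric stiffness: compression constant for boundary
    # springs (None = symmetric).  Connections are always compression-only.
    k_b_compression: float | None = None
    # Angular springs at 3-way junction wedges (rest angle 2*pi/3).  Off by
    # default so that a freshly initialized rest state carries zero energy.
    junction_bending: bool = False

    def __post_init__(self) -> None:
        if self.Th_sub <= 0:
            raise ValueError("Th_sub must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not (0.0 <= self.dt_foundation <= 1.0):
            raise ValueError("dt_foundation must lie in [0, 1]")
        if self.length_factor < 1.0:
            raise ValueError("length_factor must be >= 1")
        for name in ("k_b", "k_bend", "k_connect", "k_foundation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.shrink_axis not in ("x", "y"):
            raise ValueError("shrink_axis must be 'x' or 'y'")

    def replace(self, **kw) -> "SimParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)


@dataclass
class TissueMesh:
    """Spring-chain representation of cell boundaries.

    ``positions`` holds the current vertex coordinates, ``foundation`` the
    anchor of each vertex's foundation spring.  ``edges`` are vertex index
    pairs with per-edge rest lengths; ``rest_angles`` stores the rest angle
    of each vertex's angular spring (NaN = no angular spring).  ``faces``
    are ordered vertex loops, one per cell.  ``fixed`` marks Dirichlet
    (template-boundary) vertices.
    """

    positions: np.ndarray
    foundation: np.ndarray
    edges: np.ndarray
    rest_lengths: np.ndarray
    rest_angles: np.ndarray
    faces: list
    fixed: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.foundation = np.asarray(self.foundation, dtype=float).reshape(-1, 2)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.rest_lengths = np.asarray(self.rest_lengths, dtype=float).reshape(-1)
        self.rest_angles = np.asarray(self.rest_angles, dtype=float).reshape(-1)
        self.fixed = np.asarray(self.fixed, dtype=bool).reshape(-1)
        self.faces = [list(map(int, f)) for f in self.faces]

    # ------------------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def copy(self) -> "TissueMesh":
        return TissueMesh(
            self.positions.copy(),
            self.foundation.copy(),
            self.edges.copy(),
            self.rest_lengths.copy(),
            self.rest_angles.copy(),
            [list(f) for f in self.faces],
            self.fixed.copy(),
        )

    def edge_lengths(self) -> np.ndarray:
        d = self.positions[self.edges[:, 1]] - self.positions[self.edges[:, 0]]
        return np.hypot(d[:, 0], d[:, 1])

    def adjacency(self) -> list:
        """Neighbor index lists, one per vertex."""
        nbrs: list = [[] for _ in range(self.n_vertices)]
        for i, j in self.edges:
            nbrs[i].append(int(j))
            nbrs[j].append(int(i))
        return nbrs

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_vertices, dtype=int)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def face_polygon(self, face_index: int) -> Polygon:
        return Polygon(self.positions[self.faces[face_index]])


@dataclass
class ConnectionSet:
    """Transient compression-only penalty springs, regenerated each step."""

    pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    rest_lengths: np.ndarray = field(default_factory=lambda: np.empty(0))
    stiffness: float = 0.1

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        self.rest_lengths = np.asarray(self.rest_lengths, dtype=float).reshape(-1)

    def __len__(self) -> int:
        return len(self.pairs)


def empty_connections(params: SimParams | None = None) -> ConnectionSet:
    k = params.k_connect if params is not None else 0.1
    return ConnectionSet(stiffness=k)


# ----------------------------------------------------------------------
# Validation
# ----------------------------------------------------------------------

def _face_is_simple(points: np.ndarray) -> bool:
    if len(points) < 3:
        return False
    try:
        return Polygon(points).is_valid
    except Exception:
        return False


def validate_mesh(mesh: TissueMesh) -> list:
    """Return a list of human-readable invariant violations (empty = valid).

    Checks: positive rest lengths, simple faces, foundation anchors present
    and finite, and boundary-chain degrees (2 for interior chain vertices,
    3 at junctions) for non-fixed vertices.  Never raises.
    """
    violations: list = []
    n = mesh.n_vertices
    if len(mesh.foundation) != n:
        violations.append(
            f"foundation has {len(mesh.foundation)} rows for {n} vertices"
        )
    if len(mesh.fixed) != n:
        violations.append(f"fixed mask has {len(mesh.fixed)} entries for {n} vertices")
    if len(mesh.rest_angles) != n:
        violations.append(
            f"rest_angles has {len(mesh.rest_angles)} entries for {n} vertices"
        )
    if len(mesh.rest_lengths) != mesh.n_edges:
        violations.append(
            f"rest_lengths has {len(mesh.rest_lengths)} entries for {mesh.n_edges} edges"
        )
        return violations

    for e, (i, j) in enumerate(mesh.edges):
        if not (0 <= i < n and 0 <= j < n):
            violations.append(f"edge {e} references out-of-range vertex ({i},{j})")
        elif i == j:
            violations.append(f"edge {e} is a self-loop at vertex {i}")
    bad = np.where(~(mesh.rest_lengths > 0))[0]
    for e in bad:
        violations.append(f"edge {e} has non-positive rest length {mesh.rest_lengths[e]}")

    for fi, face in enumerate(mesh.faces):
        if len(face) < 3:
            violations.append(f"face {fi} has fewer than 3 vertices")
            continue
        if any(not (0 <= v < n) for v in face):
            violations.append(f"face {fi} references out-of-range vertex")
            continue
        if not _face_is_simple(mesh.positions[face]):
            violations.append(f"face {fi} is not a simple polygon")

    if len(mesh.foundation) == n and n:
        nonfinite = np.where(~np.isfinite(mesh.foundation).all(axis=1))[0]
        for v in nonfinite:
            violations.append(f"vertex {v} has non-finite foundation anchor")

    if mesh.n_edges and len(mesh.fixed) == n:
        deg = mesh.degrees()
        for v in range(n):
            if not mesh.fixed[v] and deg[v] not in (2, 3):
                violations.append(
                    f"free vertex {v} has degree {deg[v]} (expected 2 or 3)"
                )
    return violations


# ----------------------------------------------------------------------
# Plain-text mesh format
#
#   VERTICES            x y fixed fx fy        (one line per vertex)
#   EDGES               i j rest_length
#   ANGLES              i rest_angle           (only vertices with a spring)
#   FACES               v1 v2 ... vk
# ----------------------------------------------------------------------

def write_mesh(mesh: TissueMesh, path) -> None:
    path = Path(path)
    lines = ["# histomech mesh v1"]
    lines.append("VERTICES")
    for p, fx, a in zip(mesh.positions, mesh.fixed, mesh.foundation):
        lines.append(f"{float(p[0])!r} {float(p[1])!r} {int(fx)} {float(a[0])!r} {float(a[1])!r}")
    lines.append("EDGES")
    for (i, j), lr in zip(mesh.edges, mesh.rest_lengths):
        lines.append(f"{i} {j} {float(lr)!r}")
    lines.append("ANGLES")
    for v, th in enumerate(mesh.rest_angles):
        if np.isfinite(th):
            lines.append(f"{v} {float(th)!r}")
    lines.append("FACES")
    for face in mesh.faces:
        lines.append(" ".join(str(v) for v in face))
    path.write_text("\n".join(lines) + "\n")


def read_mesh(path) -> TissueMesh:
    path = Path(path)
    verts: list = []
    fixed: list = []
    anchors: list = []
    edges: list = []
    rest_lengths: list = []
    angles: dict = {}
    faces: list = []
    section = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line in ("VERTICES", "EDGES", "ANGLES", "FACES"):
            section = line
            continue
        parts = line.split()
        try:
            if section == "VERTICES":
                if len(parts) != 5:
                    raise MeshParseError(
                        f"{path}:{lineno}: expected 'x y fixed fx fy', got {len(parts)} fields"
                    )
                verts.append((float(parts[0]), float(parts[1])))
                fixed.append(bool(int(parts[2])))
                anchors.append((float(parts[3]), float(parts[4])))
            elif section == "EDGES":
                if len(parts) != 3:
                    raise MeshParseError(
                        f"{path}:{lineno}: expected 'i j rest_length', got {len(parts)} fields"
                    )
                edges.append((int(parts[0]), int(parts[1])))
                rest_lengths.append(float(parts[2]))
            elif section == "ANGLES":
                if len(parts) != 2:
                    raise MeshParseError(
                        f"{path}:{lineno}: expected 'i rest_angle', got {len(parts)} fields"
                    )
                angles[int(parts[0])] = float(parts[1])
            elif section == "FACES":
                faces.append([int(p) for p in parts])
            else:
                raise MeshParseError(f"{path}:{lineno}: data before any section header")
        except MeshParseError:
            raise
        except ValueError as exc:
            raise MeshParseError(f"{path}:{lineno}: {exc}") from exc
    n = len(verts)
    rest_angles = np.full(n, np.nan)
    for v, th in angles.items():
        if not (0 <= v < n):
            raise MeshParseError(f"{path}: ANGLES references vertex {v} of {n}")
        rest_angles[v] = th
    return TissueMesh(
        positions=np.array(verts, dtype=float).reshape(-1, 2),
        foundation=np.array(anchors, dtype=float).reshape(-1, 2),
        edges=np.array(edges, dtype=np.int64).reshape(-1, 2),
        rest_lengths=np.array(rest_lengths, dtype=float),
        rest_angles=rest_angles,
        faces=faces,
        fixed=np.array(fixed, dtype=bool),
    )


def meshes_equal(a: TissueMesh, b: TissueMesh) -> bool:
    """Field-for-field equality at full precision (NaN-aware for angles)."""
    return (
        np.array_equal(a.positions, b.positions)
        and np.array_equal(a.foundation, b.foundation)
        and np.array_equal(a.edges, b.edges)
        and np.array_equal(a.rest_lengths, b.rest_lengths)
        and np.array_equal(a.rest_angles, b.rest_angles, equal_nan=True)
        and a.faces == b.faces
        and np.array_equal(a.fixed, b.fixed)
    )
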