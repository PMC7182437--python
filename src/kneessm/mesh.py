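"""Triangle-mesh container, I/O and preprocessing filters.

The in-memory surface container is :class:`trimesh.Trimesh` (vertices in mm,
triangular faces).  Package-wide coordinate convention:

* x = medio-lateral (+lateral for a right knee)
* y = antero-posterior (+anterior)
* z = proximo-distal (+proximal)

so the frontal plane is (x, z), the sagittal plane (y, z) and the axial plane
(x, y).  Mirroring a left knee to a right knee negates x.

Surface scale and shaft lengths are deliberately never normalized: the relative
size of femur and tibia (and the variable shaft crops) carry shape information
the downstream model is meant to see.
"""

from __future__ import annotations

import heapq
from pathlib import Path

import numpy as np
import trimesh
from trimesh import Trimesh

__all__ = [
    "MeshFormatError",
    "NonManifoldError",
    "read_mesh",
    "write_mesh",
    "smooth",
    "decimate",
    "mirror_ml",
    "remesh_to_edge_length",
    "surface_distances",
    "point_surface_distance",
]

_SUPPORTED = {".ply", ".stl", ".obj"}


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be read or has an unsupported format."""


class NonManifoldError(ValueError):
    """Raised when an operation requires a 2-manifold mesh and the input is not."""


def _as_mesh(vertices, faces) -> Trimesh:
    return Trimesh(vertices=np.asarray(vertices, dtype=float),
                   faces=np.asarray(faces, dtype=np.int64),
                   process=False)


def read_mesh(path) -> Trimesh:
    """Read a PLY/STL/OBJ surface.

    STL stores a facet soup; duplicated vertices are welded at a 1e-6 mm
    tolerance so the result has shared connectivity.  PLY/OBJ keep their
    vertex arrays untouched.
    """
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED:
        raise MeshFormatError(f"unsupported mesh extension: {path.suffix!r}")
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise MeshFormatError(f"empty mesh file: {path}")
    try:
        m = trimesh.load_mesh(path, process=False)
    except Exception as exc:  # noqa: BLE001 - normalize loader failures
        raise MeshFormatError(f"could not read {path}: {exc}") from exc
    if isinstance(m, trimesh.Scene):
        geoms = list(m.geometry.values())
        if not geoms:
            raise MeshFormatError(f"no geometry in {path}")
        m = trimesh.util.concatenate(geoms)
    if m.vertices.size == 0 or m.faces.size == 0:
        raise MeshFormatError(f"no triangles in {path}")
    mesh = _as_mesh(m.vertices, m.faces)
    if path.suffix.lower() == ".stl":
        mesh.merge_vertices(digits_vertex=6)
    if not np.all(np.isfinite(mesh.vertices)):
        raise MeshFormatError(f"non-finite vertex coordinates in {path}")
    return mesh


def write_mesh(mesh: Trimesh, path) -> None:
    """Write a surface to PLY (binary), STL or OBJ, by extension."""
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED:
        raise MeshFormatError(f"unsupported mesh extension: {path.suffix!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(path)


def smooth(mesh: Trimesh, iterations: int, lamb: float = 0.5, mu: float = -0.53) -> Trimesh:
    """Taubin lambda/mu smoothing (volume preserving, shrinkage-free).

    ``iterations=0`` returns a copy of the input; the vertex count never
    changes.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    out = _as_mesh(mesh.vertices, mesh.faces)
    if iterations == 0:
        return out
    trimesh.smoothing.filter_taubin(out, lamb=lamb, nu=-mu, iterations=iterations)
    return _as_mesh(out.vertices, out.faces)


def mirror_ml(mesh: Trimesh) -> Trimesh:
    """Mirror in the medio-lateral direction (negate x), flipping face winding
    so outward normals stay outward."""
    v = mesh.vertices.copy()
    v[:, 0] *= -1.0
    f = mesh.faces[:, ::-1].copy()
    return _as_mesh(v, f)


# ---------------------------------------------------------------------------
# Quadric edge-collapse decimation
# ---------------------------------------------------------------------------

def _face_quadrics(V, F):
    """4x4 plane quadric per face, area-weighted."""
    a, b, c = V[F[:, 0]], V[F[:, 1]], V[F[:, 2]]
    n = np.cross(b - a, c - a)
    area2 = np.linalg.norm(n, axis=1)
    good = area2 > 1e-14
    n_unit = np.zeros_like(n)
    n_unit[good] = n[good] / area2[good, None]
    d = -np.einsum("ij,ij->i", n_unit, a)
    p = np.concatenate([n_unit, d[:, None]], axis=1)  # (F,4)
    Q = p[:, :, None] * p[:, None, :] * (0.5 * area2)[:, None, None]
    return Q


def _edge_face_counts(F):
    e = np.concatenate([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]])
    e = np.sort(e, axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    return uniq, counts


def decimate(mesh: Trimesh, target_vertices: int) -> Trimesh:
    """Quadric edge-collapse decimation to ``target_vertices`` (within ~2%).

    Collapses are rejected if they would break the link condition (so a
    watertight manifold stays watertight) or flip face normals.  Non-manifold
    input raises :class:`NonManifoldError` rather than being silently repaired.
    """
    V = np.asarray(mesh.vertices, dtype=float)
    F = np.asarray(mesh.faces, dtype=np.int64)
    n = len(V)
    if target_vertices < 4:
        raise ValueError("target_vertices must be >= 4")
    if target_vertices > n:
        raise ValueError("target_vertices exceeds current vertex count")
    edges, counts = _edge_face_counts(F)
    if np.any(counts > 2):
        raise NonManifoldError("mesh has edges shared by more than two faces")
    if target_vertices == n:
        return _as_mesh(V, F)

    V = V.copy()
    Qf = _face_quadrics(V, F)
    Q = np.zeros((n, 4, 4))
    for k in range(3):
        np.add.at(Q, F[:, k], Qf)

    # boundary edges get a perpendicular constraint plane so borders stay put
    boundary = edges[counts == 1]
    if len(boundary):
        edge_to_face = {}
        for fi, f in enumerate(F):
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                edge_to_face[(min(a, b), max(a, b))] = fi
        for a, b in boundary:
            fi = edge_to_face[(a, b)]
            fv = F[fi]
            fn = np.cross(V[fv[1]] - V[fv[0]], V[fv[2]] - V[fv[0]])
            e = V[b] - V[a]
            cn = np.cross(e, fn)
            norm = np.linalg.norm(cn)
            if norm < 1e-14:
                continue
            cn /= norm
            d = -cn @ V[a]
            p = np.array([*cn, d])
            Kb = np.outer(p, p) * (np.linalg.norm(e) ** 2 * 1e3)
            Q[a] += Kb
            Q[b] += Kb

    vert_faces: list[set] = [set() for _ in range(n)]
    for fi, f in enumerate(F):
        for vi in f:
            vert_faces[vi].add(fi)
    faces = {fi: tuple(f) for fi, f in enumerate(F)}
    alive = np.ones(n, dtype=bool)
    stamp = np.zeros(n, dtype=np.int64)

    def neighbors(u):
        out = set()
        for fi in vert_faces[u]:
            out.update(faces[fi])
        out.discard(u)
        return out

    def collapse_cost(u, v):
        Quv = Q[u] + Q[v]
        A = Quv[:3, :3] + 1e-12 * np.eye(3)
        b = -Quv[:3, 3]
        try:
            pos = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            pos = 0.5 * (V[u] + V[v])
        if not np.all(np.isfinite(pos)) or np.linalg.norm(pos - 0.5 * (V[u] + V[v])) > 10 * np.linalg.norm(V[u] - V[v]) + 1e-9:
            pos = 0.5 * (V[u] + V[v])
        h = np.array([*pos, 1.0])
        return float(h @ Quv @ h), pos

    heap = []
    counter = 0
    for a, b in edges:
        cost, pos = collapse_cost(a, b)
        heap.append((cost, counter, a, b, stamp[a], stamp[b], pos))
        counter += 1
    heapq.heapify(heap)

    n_alive = n
    while n_alive > target_vertices and heap:
        cost, _, u, v, su, sv, pos = heapq.heappop(heap)
        if not (alive[u] and alive[v]) or stamp[u] != su or stamp[v] != sv:
            continue
        shared = vert_faces[u] & vert_faces[v]
        if not shared or len(shared) > 2:
            continue
        third = {w for fi in shared for w in faces[fi] if w not in (u, v)}
        if neighbors(u) & neighbors(v) != third:
            continue  # link condition: collapse would pinch the surface
        # reject normal flips among surviving faces
        flip = False
        for fi in (vert_faces[u] | vert_faces[v]) - shared:
            f = faces[fi]
            old = np.cross(V[f[1]] - V[f[0]], V[f[2]] - V[f[0]])
            p = [pos if w in (u, v) else V[w] for w in f]
            new = np.cross(p[1] - p[0], p[2] - p[0])
            if old @ new <= 1e-14:
                flip = True
                break
        if flip:
            continue

        V[u] = pos
        Q[u] = Q[u] + Q[v]
        alive[v] = False
        n_alive -= 1
        for fi in shared:
            for w in faces[fi]:
                vert_faces[w].discard(fi)
            faces.pop(fi)
        for fi in list(vert_faces[v]):
            f = faces[fi]
            faces[fi] = tuple(u if w == v else w for w in f)
            vert_faces[v].discard(fi)
            vert_faces[u].add(fi)
        stamp[u] += 1
        stamp[v] += 1
        for w in neighbors(u):
            c, p = collapse_cost(u, w)
            heapq.heappush(heap, (c, counter, u, w, stamp[u], stamp[w], p))
            counter += 1

    keep = np.flatnonzero(alive)
    remap = -np.ones(n, dtype=np.int64)
    remap[keep] = np.arange(len(keep))
    new_faces = np.array([remap[list(f)] for f in faces.values()], dtype=np.int64)
    new_faces = new_faces[(new_faces[:, 0] != new_faces[:, 1])
                          & (new_faces[:, 1] != new_faces[:, 2])
                          & (new_faces[:, 2] != new_faces[:, 0])]
    return _as_mesh(V[keep], new_faces)


# ---------------------------------------------------------------------------
# Isotropic remeshing
# ---------------------------------------------------------------------------

def _mean_edge(mesh: Trimesh) -> float:
    e = mesh.vertices[mesh.edges_unique]
    return float(np.linalg.norm(e[:, 0] - e[:, 1], axis=1).mean())


def remesh_to_edge_length(mesh: Trimesh, target_edge_mm: float,
                          relax_iterations: int = 2) -> Trimesh:
    """Isotropic remesh: mean edge length within 10% of the target.

    Long edges are split, then the mesh is decimated to the vertex budget
    implied by surface area (for a closed, near-uniform triangulation
    ``V ~= 2 A / (sqrt(3) L^2)``) and lightly Taubin-relaxed.  The budget is
    re-calibrated from the measured mean edge, at most three times.
    """
    if target_edge_mm <= 0:
        raise ValueError("target_edge_mm must be > 0")
    if target_edge_mm > float(np.max(mesh.extents)):
        raise ValueError("target edge length exceeds the mesh bounding box")
    v, f = trimesh.remesh.subdivide_to_size(mesh.vertices, mesh.faces,
                                            max_edge=1.33 * target_edge_mm)
    fine = _as_mesh(v, f)
    area = float(fine.area)
    n_target = max(4, int(round(2.0 * area / (np.sqrt(3.0) * target_edge_mm ** 2))))
    out = fine
    for _ in range(3):
        n_target = min(n_target, len(fine.vertices))
        out = decimate(fine, n_target)
        if relax_iterations:
            out = smooth(out, relax_iterations)
        mean = _mean_edge(out)
        if abs(mean - target_edge_mm) <= 0.08 * target_edge_mm:
            break
        n_target = max(4, int(round(n_target * (mean / target_edge_mm) ** 2)))
    return out


# ---------------------------------------------------------------------------
# Surface distances
# ---------------------------------------------------------------------------

def point_surface_distance(points: np.ndarray, mesh: Trimesh,
                           chunk: int = 32, return_points: bool = False):
    """Exact distance from each point to the closest point on the surface.

    Evaluates every point against every triangle (vectorized, chunked); no
    spatial pruning, so the result is exact to floating precision.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tris = mesh.triangles
    nf = len(tris)
    dists = np.empty(len(points))
    closest = np.empty_like(points) if return_points else None
    for i in range(0, len(points), chunk):
        P = points[i:i + chunk]
        pp = np.repeat(P, nf, axis=0)
        tt = np.tile(tris, (len(P), 1, 1))
        cp = trimesh.triangles.closest_point(tt, pp)
        d = np.linalg.norm(cp - pp, axis=1).reshape(len(P), nf)
        j = np.argmin(d, axis=1)
        dists[i:i + len(P)] = d[np.arange(len(P)), j]
        if return_points:
            closest[i:i + len(P)] = cp.reshape(len(P), nf, 3)[np.arange(len(P)), j]
    if return_points:
        return dists, closest
    return dists


def surface_distances(a: Trimesh, b: Trimesh) -> tuple[float, float]:
    """Symmetric Hausdorff and symmetric mean surface distance (mm).

    Vertices of each mesh are measured against the full triangle set of the
    other; the Hausdorff value is the max of the two directed maxima, the mean
    is the average of the two directed means.
    """
    if len(a.vertices) == 0 or len(b.vertices) == 0:
        raise ValueError("both meshes must be non-empty")
    d_ab = point_surface_distance(a.vertices, b)
    d_ba = point_surface_distance(b.vertices, a)
    haus = max(float(d_ab.max()), float(d_ba.max()))
    mean = 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))
    return haus, mean
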