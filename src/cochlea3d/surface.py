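"""Lofting swept 3D rings into triangulated surface meshes.

Consecutive rings of a swept structure share point ordering by
construction, so lofting joins them index-to-index with a quad strip split
into triangles along the shorter diagonal.  Closed rings may be capped with
triangle fans for a watertight solid; open contours (membrane sheets) loft
into ribbon strips.  A validator reports manifoldness, orientation
consistency, boundary loops, the Euler characteristic and watertightness.
"""
from __future__ import annotations

import logging
import struct
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from .projection import Curve3D

logger = logging.getLogger(__name__)

__all__ = [
    "SurfaceMesh",
    "MeshReport",
    "loft_rings",
    "loft_strip",
    "validate_mesh",
    "signed_volume",
    "point_surface_distance",
    "export_mesh",
    "export_combined_obj",
]


@dataclass
class SurfaceMesh:
    """Triangulated surface of one anatomical structure."""

    label: str
    vertices: np.ndarray  # (V, 3)
    faces: np.ndarray  # (F, 3) int
    capped: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)


def _split_quad(faces: list, a: int, b: int, c: int, d: int,
                verts: np.ndarray) -> None:
    """Split quad (a, b, c, d) along its shorter diagonal.

    Tie-break: the diagonal from the lower vertex index (a-c, since a is the
    quad's smallest index by construction).
    """
    ac = np.linalg.norm(verts[a] - verts[c])
    bd = np.linalg.norm(verts[b] - verts[d])
    if ac <= bd:
        faces.append((a, b, c))
        faces.append((a, c, d))
    else:
        faces.append((a, b, d))
        faces.append((b, c, d))


def loft_rings(curve: Curve3D, cap_ends: bool = True,
               check_self_intersections: bool = False) -> SurfaceMesh:
    """Loft a stack of closed rings into a tube surface.

    Rings are joined index-to-index (they come from the same 2D contour, so
    the ordering is shared); each quad is split along its shorter diagonal.
    With ``cap_ends`` the first and last rings are closed by triangle fans
    from their centroids, producing a watertight solid for non-degenerate
    input.  Counter-clockwise rings (viewed against the tangent) give
    positive enclosed volume.
    """
    rings = curve.rings
    r, k = rings.shape[:2]
    if not curve.closed_ring:
        raise ValueError("loft_rings requires closed rings; use loft_strip")
    if r < 2 or k < 3:
        raise ValueError("need >= 2 rings of >= 3 points")
    verts = rings.reshape(-1, 3).copy()
    faces: list[tuple[int, int, int]] = []
    for i in range(r - 1):
        base, nxt = i * k, (i + 1) * k
        for j in range(k):
            j1 = (j + 1) % k
            _split_quad(faces, base + j, base + j1, nxt + j1, nxt + j, verts)
    capped = bool(cap_ends)
    if capped:
        c0 = rings[0].mean(axis=0)
        c1 = rings[-1].mean(axis=0)
        i0, i1 = len(verts), len(verts) + 1
        verts = np.vstack([verts, c0[None], c1[None]])
        last = (r - 1) * k
        for j in range(k):
            j1 = (j + 1) % k
            faces.append((i0, j1, j))          # base cap, inward-facing fan
            faces.append((i1, last + j, last + j1))  # apex cap
    mesh = SurfaceMesh(label=curve.label, vertices=verts,
                       faces=np.asarray(faces), capped=capped)
    if check_self_intersections:
        n = _count_self_intersections(mesh)
        if n:
            logger.warning("lofted mesh %r has %d self-intersecting "
                           "triangle pairs", curve.label, n)
    return mesh


def loft_strip(curve: Curve3D) -> SurfaceMesh:
    """Loft open contours (membrane sheets) into a ribbon mesh.

    The result is an open, bordered surface whose boundary is a single loop.
    """
    rings = curve.rings
    r, k = rings.shape[:2]
    if curve.closed_ring:
        raise ValueError("loft_strip requires open contours; use loft_rings")
    if r < 2 or k < 2:
        raise ValueError("need >= 2 rows of >= 2 points")
    verts = rings.reshape(-1, 3).copy()
    faces: list[tuple[int, int, int]] = []
    for i in range(r - 1):
        base, nxt = i * k, (i + 1) * k
        for j in range(k - 1):
            _split_quad(faces, base + j, base + j + 1, nxt + j + 1, nxt + j,
                        verts)
    return SurfaceMesh(label=curve.label, vertices=verts,
                       faces=np.asarray(faces), capped=False)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeshReport:
    n_vertices: int
    n_faces: int
    n_edges: int
    euler_characteristic: int
    non_manifold_edges: int
    flipped_edges: int  # interior edges traversed twice in the same direction
    degenerate_faces: int
    boundary_loops: int
    boundary_edges: int
    watertight: bool


def validate_mesh(mesh: SurfaceMesh) -> MeshReport:
    """Exact census of mesh integrity; never mutates the mesh.

    An interior edge must be shared by exactly two faces with opposite
    traversal direction (consistent winding); boundary edges belong to one
    face.  Watertight means manifold, consistently wound and boundary-free.
    """
    faces = mesh.faces
    verts = mesh.vertices
    degenerate = 0
    edge_count: dict[tuple[int, int], int] = defaultdict(int)
    directed: dict[tuple[int, int], int] = defaultdict(int)
    for f in faces:
        a, b, c = (int(f[0]), int(f[1]), int(f[2]))
        if a == b or b == c or a == c:
            degenerate += 1
            continue
        area = 0.5 * np.linalg.norm(np.cross(verts[b] - verts[a],
                                             verts[c] - verts[a]))
        if area < 1e-12:
            degenerate += 1
        for u, v in ((a, b), (b, c), (c, a)):
            directed[(u, v)] += 1
            edge_count[(min(u, v), max(u, v))] += 1

    non_manifold = sum(1 for n in edge_count.values() if n > 2)
    flipped = 0
    boundary = []
    for (u, v), n in edge_count.items():
        if n == 1:
            if directed.get((u, v), 0) == 1:
                boundary.append((u, v))
            else:
                boundary.append((v, u))
        elif n == 2 and (directed.get((u, v), 0) == 2
                         or directed.get((v, u), 0) == 2):
            flipped += 1

    loops = _count_loops(boundary)
    e = len(edge_count)
    chi = len(verts) - e + len(faces)
    watertight = (len(boundary) == 0 and non_manifold == 0 and flipped == 0
                  and degenerate == 0 and len(faces) > 0)
    return MeshReport(
        n_vertices=len(verts), n_faces=len(faces), n_edges=e,
        euler_characteristic=chi, non_manifold_edges=non_manifold,
        flipped_edges=flipped, degenerate_faces=degenerate,
        boundary_loops=loops, boundary_edges=len(boundary),
        watertight=watertight,
    )


def _count_loops(boundary_edges: list[tuple[int, int]]) -> int:
    """Connected cycles among boundary edges (undirected component count)."""
    if not boundary_edges:
        return 0
    adj: dict[int, set[int]] = defaultdict(set)
    for u, v in boundary_edges:
        adj[u].add(v)
        adj[v].add(u)
    seen: set[int] = set()
    loops = 0
    for start in adj:
        if start in seen:
            continue
        loops += 1
        stack = [start]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            stack.extend(adj[node] - seen)
    return loops


def signed_volume(mesh: SurfaceMesh) -> float:
    """Signed enclosed volume by the divergence theorem (valid if watertight)."""
    v = mesh.vertices
    f = mesh.faces
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def point_surface_distance(points: np.ndarray, mesh: SurfaceMesh,
                           k: int = 32) -> np.ndarray:
    """Exact unsigned distance from each query point to the mesh surface.

    Candidate triangles are preselected by a KD-tree over face centroids
    (``k`` nearest, padded by the largest face circumradius), then the exact
    point-to-triangle distance is minimized over the candidates.
    """
    from scipy.spatial import cKDTree

    points = np.asarray(points, dtype=float).reshape(-1, 3)
    tris = mesh.vertices[mesh.faces]  # (F, 3, 3)
    cent = tris.mean(axis=1)
    k = min(k, len(tris))
    _, idx = cKDTree(cent).query(points, k=k)
    idx = np.atleast_2d(idx.T).T if idx.ndim == 1 else idx
    out = np.empty(len(points))
    for i, (p, cand) in enumerate(zip(points, idx)):
        out[i] = _point_tri_distance(p, tris[cand]).min()
    return out


def _point_tri_distance(p: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Distance from one point to each triangle (barycentric clamping)."""
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    ab, ac, ap = b - a, c - a, p[None, :] - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p[None, :] - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p[None, :] - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    closest = np.empty_like(a)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    closest[m] = a[m]
    m2 = (d3 >= 0) & (d4 <= d3)
    closest[m2] = b[m2]
    m3 = (d6 >= 0) & (d5 <= d6)
    closest[m3] = c[m3]
    done = m | m2 | m3
    # edge AB
    e = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    t = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 == 0, 1.0, d1 - d3), 0.0)
    closest[e] = a[e] + t[e, None] * ab[e]
    done |= e
    # edge AC
    e = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    t = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 == 0, 1.0, d2 - d6), 0.0)
    closest[e] = a[e] + t[e, None] * ac[e]
    done |= e
    # edge BC
    e = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    t = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1.0, denom), 0.0)
    closest[e] = b[e] + t[e, None] * (c[e] - b[e])
    done |= e
    # interior
    inside = ~done
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    closest[inside] = (a[inside] + v[inside, None] * ab[inside]
                       + w[inside, None] * ac[inside])
    return np.linalg.norm(p[None, :] - closest, axis=1)


def _count_self_intersections(mesh: SurfaceMesh) -> int:
    """Conservative count of intersecting non-adjacent triangle pairs."""
    tm = mesh.to_trimesh()
    from scipy.spatial import cKDTree
    cent = tm.triangles_center
    rad = np.linalg.norm(tm.triangles - cent[:, None, :], axis=2).max(axis=1)
    tree = cKDTree(cent)
    pairs = tree.query_pairs(2.0 * rad.max())
    count = 0
    for i, j in pairs:
        if set(mesh.faces[i]) & set(mesh.faces[j]):
            continue
        if np.linalg.norm(cent[i] - cent[j]) > rad[i] + rad[j]:
            continue
        if _tri_tri_intersect(tm.triangles[i], tm.triangles[j]):
            count += 1
    return count


def _tri_tri_intersect(t1: np.ndarray, t2: np.ndarray) -> bool:
    """Segment-against-triangle test in both directions."""
    for a, b in ((t1, t2), (t2, t1)):
        n = np.cross(b[1] - b[0], b[2] - b[0])
        nn = np.linalg.norm(n)
        if nn == 0:
            continue
        n = n / nn
        for k in range(3):
            p, q = a[k], a[(k + 1) % 3]
            dp = (p - b[0]) @ n
            dq = (q - b[0]) @ n
            if dp * dq >= 0:
                continue
            x = p + (q - p) * (dp / (dp - dq))
            # barycentric inside test
            v0, v1, v2 = b[1] - b[0], b[2] - b[0], x - b[0]
            d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
            d20, d21 = v2 @ v0, v2 @ v1
            den = d00 * d11 - d01 * d01
            if den == 0:
                continue
            s = (d11 * d20 - d01 * d21) / den
            t = (d00 * d21 - d01 * d20) / den
            if s >= 0 and t >= 0 and s + t <= 1:
                return True
    return False


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_mesh(mesh: SurfaceMesh, path) -> Path:
    """Write one mesh as OBJ / PLY (binary) / STL (binary) by extension."""
    path = Path(path)
    tm = mesh.to_trimesh()
    suffix = path.suffix.lower()
    if suffix == ".obj":
        with open(path, "w") as fh:
            fh.write(f"o {mesh.label}\n")
            for v in mesh.vertices:
                fh.write(f"v {float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
            for f in mesh.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    elif suffix == ".ply":
        path.write_bytes(trimesh.exchange.ply.export_ply(tm, encoding="binary_little_endian"))
    elif suffix == ".stl":
        path.write_bytes(trimesh.exchange.stl.export_stl(tm))
    else:
        raise ValueError(f"unsupported mesh format {suffix!r}")
    return path


def export_combined_obj(meshes: list[SurfaceMesh], path) -> Path:
    """Single OBJ holding every structure as a named group."""
    path = Path(path)
    offset = 0
    with open(path, "w") as fh:
        for mesh in meshes:
            fh.write(f"o {mesh.label}\ng {mesh.label}\n")
            for v in mesh.vertices:
                fh.write(f"v {float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
            for f in mesh.faces:
                fh.write(f"f {f[0] + 1 + offset} {f[1] + 1 + offset} "
                         f"{f[2] + 1 + offset}\n")
            offset += len(mesh.vertices)
    return path
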