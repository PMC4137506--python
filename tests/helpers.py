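"""Shared oracles and measurement helpers for the test suite.

These stay independent of the code paths they check: distances are computed
against densely sampled analytic phantom geometry, areas and volumes by
quadrature, masks by direct rasterization.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from skimage.draw import polygon as _sk_polygon

from cochlea3d import phantom as ph


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    return 2.0 * float((a & b).sum()) / float(denom) if denom else 1.0


def rasterize_contour(points_px: np.ndarray, shape: tuple[int, int]
                      ) -> np.ndarray:
    """Fill a closed (x, y) pixel contour into a boolean mask."""
    mask = np.zeros(shape, dtype=bool)
    rr, cc = _sk_polygon(points_px[:, 1], points_px[:, 0], shape=shape)
    mask[rr, cc] = True
    return mask


def scala_curve(spec: ph.HelixSpec, scala: str, n: int = 20000) -> np.ndarray:
    sv, st = ph.scala_offset_curves(spec, np.linspace(0.0, 1.0, n))
    return sv if scala == "SV" else st


def tube_side_points(spec: ph.HelixSpec, scala: str = "SV",
                     n_t: int = 1000, n_ang: int = 64) -> np.ndarray:
    """Dense samples of the analytic swept tube (side) surface."""
    curve = scala_curve(spec, scala, n_t)
    d = np.gradient(curve, axis=0)
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    ref = np.asarray(spec.axis, dtype=float)
    n1 = np.cross(d, ref)
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(d, n1)
    a = np.linspace(0.0, 2.0 * np.pi, n_ang, endpoint=False)
    r = spec.tube_radius
    pts = (curve[:, None, :]
           + r * (np.cos(a)[None, :, None] * n1[:, None, :]
                  + np.sin(a)[None, :, None] * n2[:, None, :]))
    return pts.reshape(-1, 3)


def distance_to_tube_side(points: np.ndarray, spec: ph.HelixSpec,
                          scala: str = "SV", n: int = 40000) -> np.ndarray:
    """Distance from points to the bounded swept side surface of one scala.

    Interior points measure ``|dist_to_curve - r|``; points whose nearest
    curve sample is an end are measured against the end rim circle, which
    penalizes overshoot beyond the tube end correctly.
    """
    curve = scala_curve(spec, scala, n)
    tree = cKDTree(curve)
    d, idx = tree.query(np.asarray(points, dtype=float))
    r = spec.tube_radius
    out = np.abs(d - r)
    for end_idx in (0, n - 1):
        at_end = np.abs(idx - end_idx) < 3
        if not at_end.any():
            continue
        p_end = curve[end_idx]
        tan = curve[1] - curve[0] if end_idx == 0 else curve[-1] - curve[-2]
        tan = tan / np.linalg.norm(tan)
        if end_idx == 0:
            tan = -tan  # outward
        v = points[at_end] - p_end
        h = v @ tan
        radial = np.linalg.norm(v - np.outer(h, tan), axis=1)
        rim = np.sqrt(np.maximum(h, 0.0) ** 2 + (radial - r) ** 2)
        beyond = h > 0
        sub = out[at_end]
        sub[beyond] = rim[beyond]
        out[at_end] = sub
    return out


def mesh_surface_points(mesh, exclude_last_vertices: int = 0):
    """Vertices, face centroids and edge midpoints of a mesh (optionally
    dropping cap-centroid vertices and their faces)."""
    faces = mesh.faces
    if exclude_last_vertices:
        cut = len(mesh.vertices) - exclude_last_vertices
        faces = faces[(faces < cut).all(axis=1)]
    verts = mesh.vertices
    tri = verts[faces]
    cent = tri.mean(axis=1)
    mids = 0.5 * (tri + np.roll(tri, 1, axis=1)).reshape(-1, 3)
    used = np.unique(faces)
    return np.vstack([verts[used], cent, mids])


def polyline_arclength(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())
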