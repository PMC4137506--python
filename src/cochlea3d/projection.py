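"""Projection of annotated 2D contours into 3D along the cochlea centerline.

A single annotated cross-section supplies one closed (or open) contour per
anatomical structure.  Each contour is embedded at every centerline station
by a per-station similarity transform: the station point is the reference
(anchor), the centerline tangent is the section-plane normal, a
rotation-minimizing frame supplies the in-plane basis, and a linearly
interpolated scale profile — estimated from region areas at the base and
apex — shrinks the contour from base to apex.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from shapely.geometry import Polygon

from .centerline import Centerline

__all__ = [
    "Contour2D",
    "AnnotationSet",
    "FrameField",
    "ScaleProfile",
    "Curve3D",
    "contour_area",
    "estimate_scale_profile",
    "build_frames",
    "project_contour",
    "sweep_structure",
    "default_anchor",
]


# ---------------------------------------------------------------------------
# Annotation containers
# ---------------------------------------------------------------------------

@dataclass
class Contour2D:
    """Ordered 2D polyline for one labelled structure, in physical units."""

    label: str
    points: np.ndarray  # (K, 2)
    closed: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        k = len(self.points)
        if self.closed and k < 3:
            raise ValueError(f"closed contour {self.label!r} needs >= 3 points")
        if not self.closed and k < 2:
            raise ValueError(f"open contour {self.label!r} needs >= 2 points")
        d = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(d == 0):
            raise ValueError(f"contour {self.label!r} has consecutive "
                             "duplicate points")

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class AnnotationSet:
    """All labelled contours of one section, with its pixel spacing."""

    slice_id: str
    pixel_spacing: float
    contours: list[Contour2D] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        labels = [c.label for c in self.contours]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate contour labels in annotation set")

    def __getitem__(self, label: str) -> Contour2D:
        for c in self.contours:
            if c.label == label:
                return c
        raise KeyError(label)

    def __contains__(self, label: str) -> bool:
        return any(c.label == label for c in self.contours)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.contours]

    def to_json(self, path) -> None:
        payload = {
            "slice_id": self.slice_id,
            "pixel_spacing": self.pixel_spacing,
            "contours": [
                {"label": c.label, "closed": bool(c.closed),
                 "points": c.points.tolist()}
                for c in self.contours
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "AnnotationSet":
        with open(path) as fh:
            payload = json.load(fh)
        contours = [Contour2D(label=c["label"],
                              points=np.asarray(c["points"], dtype=float),
                              closed=bool(c["closed"]))
                    for c in payload["contours"]]
        return cls(slice_id=str(payload["slice_id"]),
                   pixel_spacing=float(payload["pixel_spacing"]),
                   contours=contours)


# ---------------------------------------------------------------------------
# Region areas and the scale profile
# ---------------------------------------------------------------------------

def contour_area(contour: Contour2D) -> float:
    """Enclosed area of a closed, simple contour by the shoelace formula."""
    if not contour.closed:
        raise ValueError(f"contour {contour.label!r} is open; area undefined")
    poly = Polygon(contour.points)
    if not poly.is_valid:
        raise ValueError(f"contour {contour.label!r} is self-intersecting")
    p = contour.points
    x, y = p[:, 0], p[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


@dataclass
class ScaleProfile:
    """Per-station length scale, linear in arc length from base to apex.

    ``s_i = s_max + (s_min - s_max) * (arclen_i / L)`` — the base (station 0)
    carries the maximum scale, the apex the minimum.
    """

    scales: np.ndarray  # (N,)
    s_max: float
    s_min: float

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        if np.any(self.scales <= 0):
            raise ValueError("scale profile must be strictly positive")

    def __getitem__(self, i: int) -> float:
        return float(self.scales[i])

    def __len__(self) -> int:
        return len(self.scales)

    @classmethod
    def constant(cls, value: float, n_stations: int) -> "ScaleProfile":
        return cls(np.full(n_stations, float(value)), value, value)


def estimate_scale_profile(
    hist_areas: Mapping[str, float],
    mct_areas_base: Mapping[str, float],
    mct_areas_apex: Mapping[str, float],
    centerline: Centerline,
) -> ScaleProfile:
    """Estimate the base->apex scale profile from matched region areas.

    For every label present in all three maps the length-scale ratio is
    ``sqrt(area_ref / area_annotated)``; ``s_max`` averages the base ratios,
    ``s_min`` the apex ratios, and stations in between are linearly
    interpolated in arc-length fraction.
    """
    common = (set(hist_areas) & set(mct_areas_base) & set(mct_areas_apex))
    if not common:
        raise ValueError("no common region label across the three area maps")
    for m in (hist_areas, mct_areas_base, mct_areas_apex):
        for lab in common:
            if m[lab] <= 0:
                raise ValueError(f"non-positive area for region {lab!r}")
    labels = sorted(common)
    s_max = float(np.mean([np.sqrt(mct_areas_base[l] / hist_areas[l])
                           for l in labels]))
    s_min = float(np.mean([np.sqrt(mct_areas_apex[l] / hist_areas[l])
                           for l in labels]))
    frac = centerline.station_arclengths / centerline.arc_length
    scales = s_max + (s_min - s_max) * frac
    return ScaleProfile(scales, s_max, s_min)


# ---------------------------------------------------------------------------
# Rotation-minimizing frames
# ---------------------------------------------------------------------------

@dataclass
class FrameField:
    """Per-station right-handed orthonormal triads (tangent, n1, n2).

    The tangent is the section-plane normal; (n1, n2) span the section plane
    with minimal twist between consecutive stations.
    """

    tangents: np.ndarray  # (N, 3)
    normals1: np.ndarray  # (N, 3)
    normals2: np.ndarray  # (N, 3)

    def __len__(self) -> int:
        return len(self.tangents)


def build_frames(centerline: Centerline, reference_direction) -> FrameField:
    """Rotation-minimizing frames along the centerline (double reflection).

    The first in-plane axis is the component of ``reference_direction``
    orthogonal to the first tangent; subsequent frames are transported by the
    double-reflection method, which approximates parallel transport without
    the flips a Frenet frame suffers at inflection points.
    """
    x = centerline.stations
    t = centerline.tangents
    ref = np.asarray(reference_direction, dtype=float)
    r0 = ref - (ref @ t[0]) * t[0]
    nrm = np.linalg.norm(r0)
    if nrm < 1e-6 * np.linalg.norm(ref):
        raise ValueError("reference_direction is parallel to the first tangent")
    n1 = np.empty_like(t)
    n1[0] = r0 / nrm
    for i in range(len(x) - 1):
        v1 = x[i + 1] - x[i]
        c1 = v1 @ v1
        if c1 == 0.0:
            n1[i + 1] = n1[i]
            continue
        rl = n1[i] - (2.0 / c1) * (v1 @ n1[i]) * v1
        tl = t[i] - (2.0 / c1) * (v1 @ t[i]) * v1
        v2 = t[i + 1] - tl
        c2 = v2 @ v2
        r_next = rl if c2 == 0.0 else rl - (2.0 / c2) * (v2 @ rl) * v2
        # re-orthogonalize against the exact tangent to stop drift
        r_next = r_next - (r_next @ t[i + 1]) * t[i + 1]
        n1[i + 1] = r_next / np.linalg.norm(r_next)
    n2 = np.cross(t, n1)
    return FrameField(tangents=t.copy(), normals1=n1, normals2=n2)


# ---------------------------------------------------------------------------
# Contour projection and sweeping
# ---------------------------------------------------------------------------

@dataclass
class Curve3D:
    """Per-station 3D rings of one structure swept along the centerline."""

    label: str
    rings: np.ndarray  # (R, K, 3)
    closed_ring: bool = True

    def __post_init__(self) -> None:
        self.rings = np.asarray(self.rings, dtype=float)
        if self.rings.ndim != 3 or self.rings.shape[2] != 3:
            raise ValueError("rings must have shape (R, K, 3)")

    def to_ply(self, path) -> None:
        """Polyline PLY (vertices + edges) for quick inspection."""
        r, k, _ = self.rings.shape
        verts = self.rings.reshape(-1, 3)
        edges = []
        for i in range(r):
            base = i * k
            last = k if self.closed_ring else k - 1
            for j in range(last):
                edges.append((base + j, base + (j + 1) % k))
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(verts)}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write(f"element edge {len(edges)}\n")
            fh.write("property int vertex1\nproperty int vertex2\n")
            fh.write("end_header\n")
            for v in verts:
                fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
            for a, b in edges:
                fh.write(f"{a} {b}\n")


def project_contour(
    contour: Contour2D,
    station_index: int,
    centerline: Centerline,
    frames: FrameField,
    scale: ScaleProfile,
    in_plane_offset=(0.0, 0.0),
) -> np.ndarray:
    """Embed a 2D contour in the section plane of one station.

    Each point ``(x, y)`` maps to
    ``station + s_i ((x - a_x) n1 + (y - a_y) n2)`` with anchor
    ``a = in_plane_offset``; a per-station similarity, so all pairwise
    distances scale by exactly ``s_i``.
    """
    i = station_index
    if not 0 <= i < len(centerline.stations):
        raise IndexError(f"station index {i} out of range")
    a = np.asarray(in_plane_offset, dtype=float)
    rel = contour.points - a
    s = scale[i]
    return (centerline.stations[i]
            + s * (rel[:, 0:1] * frames.normals1[i]
                   + rel[:, 1:2] * frames.normals2[i]))


def sweep_structure(
    contour: Contour2D,
    centerline: Centerline,
    frames: FrameField,
    scale: ScaleProfile,
    station_range: tuple[int, int] | None = None,
    in_plane_offset=(0.0, 0.0),
) -> Curve3D:
    """Project one contour at every station in range; rings ordered base->apex."""
    n = len(centerline.stations)
    first, last = (0, n - 1) if station_range is None else station_range
    if not (0 <= first <= last < n):
        raise ValueError(f"invalid station range ({first}, {last}) for {n} "
                         "stations")
    rings = np.stack([
        project_contour(contour, i, centerline, frames, scale, in_plane_offset)
        for i in range(first, last + 1)
    ])
    return Curve3D(label=contour.label, rings=rings,
                   closed_ring=contour.closed)


def default_anchor(annotation: AnnotationSet,
                   lamina_label: str = "osseous spiral lamina") -> np.ndarray:
    """Choose the 2D reference point that rides on the centerline.

    If an osseous-spiral-lamina contour is present, the anchor is the
    centroid of its quarter of points nearest the overall annotation centroid
    (its modiolar-side edge); otherwise the bounding-box center of all
    contours.
    """
    all_pts = np.vstack([c.points for c in annotation.contours])
    if lamina_label in annotation:
        lam = annotation[lamina_label].points
        overall = all_pts.mean(axis=0)
        d = np.linalg.norm(lam - overall, axis=1)
        k = max(len(lam) // 4, 1)
        nearest = lam[np.argsort(d)[:k]]
        return nearest.mean(axis=0)
    lo, hi = all_pts.min(axis=0), all_pts.max(axis=0)
    return 0.5 * (lo + hi)
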