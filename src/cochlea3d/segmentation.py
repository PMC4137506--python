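"""Hierarchical 2D segmentation of cross-section images.

Large structures with distinct boundaries (the scala lumina) are found first
by a circle Hough transform; the image is then cropped to the detections and
smaller, less distinct structures are refined by a region-based level set
(Chan-Vese energy).  Finally consecutive segmented slices are aligned by a
rigid least-squares registration of their contours.

Coordinates follow the image convention: origin at the top-left, x
rightward (columns), y downward (rows), 0-based.  Contours are closed and
ordered counter-clockwise (positive shoelace area in (x, y)).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import feature, measure, morphology
from skimage.filters import threshold_otsu
from skimage.segmentation import morphological_chan_vese
from skimage.transform import hough_circle, hough_circle_peaks

from .projection import AnnotationSet, Contour2D

logger = logging.getLogger(__name__)

__all__ = [
    "ImageSlice",
    "CircleDetection",
    "RigidTransform2D",
    "SegmentationError",
    "SegmentationStage",
    "preprocess",
    "detect_large_structures",
    "crop_to_detections",
    "segment_level_set",
    "hierarchical_segment",
    "register_slices",
]


class SegmentationError(RuntimeError):
    """A required structure could not be segmented."""


@dataclass
class ImageSlice:
    """One grayscale cross-section with its crop bookkeeping.

    ``origin_offset`` is the (x, y) pixel offset of this (possibly cropped)
    image relative to the uncropped original, so global coordinates are
    ``local + origin_offset``.
    """

    pixels: np.ndarray
    pixel_spacing: float = 1.0
    index: int = 0
    origin_offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class CircleDetection:
    center: tuple[float, float]  # (x, y) pixels, global coordinates
    radius: float
    score: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.score < 0:
            raise ValueError("score must be non-negative")

    def contour(self, n: int = 64) -> np.ndarray:
        a = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        return np.column_stack([self.center[0] + self.radius * np.cos(a),
                                self.center[1] + self.radius * np.sin(a)])


@dataclass(frozen=True)
class RigidTransform2D:
    """Rotation (counter-clockwise in (x, y)) followed by translation."""

    rotation_angle: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation_angle), np.sin(self.rotation_angle)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.matrix.T \
            + np.asarray(self.translation)

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """self after other: (self o other)(x) = self(other(x))."""
        t = self.apply(np.asarray(other.translation)[None, :])[0]
        return RigidTransform2D(self.rotation_angle + other.rotation_angle,
                                (float(t[0]), float(t[1])))

    def inverse(self) -> "RigidTransform2D":
        r = self.matrix.T
        t = -r @ np.asarray(self.translation)
        return RigidTransform2D(-self.rotation_angle,
                                (float(t[0]), float(t[1])))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(image: ImageSlice, smoothing_sigma: float = 0.0) -> ImageSlice:
    """Gaussian smoothing followed by a linear contrast stretch to [0, 1].

    The intensity mapping is monotone; a constant image is returned
    unchanged (the stretch is undefined there).
    """
    if smoothing_sigma < 0:
        raise ValueError("smoothing_sigma must be non-negative")
    px = image.pixels
    if smoothing_sigma > 0:
        px = gaussian_filter(px, smoothing_sigma)
    lo, hi = float(px.min()), float(px.max())
    if hi > lo:
        px = (px - lo) / (hi - lo)
    else:
        px = image.pixels.copy()
    return replace(image, pixels=px)


# ---------------------------------------------------------------------------
# Hough detection of large structures
# ---------------------------------------------------------------------------

def detect_large_structures(
    image: ImageSlice,
    radius_range: tuple[int, int],
    max_detections: int = 2,
    canny_sigma: float = 2.0,
) -> list[CircleDetection]:
    """Circle Hough transform on an edge map; strongest non-overlapping peaks.

    The image is contrast-normalized before edge detection, so detections
    (and their score order) are invariant to global intensity scaling.
    Results are sorted by score descending, ties broken by smaller radius
    then lexicographic center; accepted disks never overlap.
    """
    rmin, rmax = radius_range
    h, w = image.shape
    if not (0 < rmin < rmax < max(h, w)):
        raise ValueError(f"invalid radius range ({rmin}, {rmax})")
    px = preprocess(image).pixels
    edges = feature.canny(px, sigma=canny_sigma)
    radii = np.arange(int(rmin), int(rmax) + 1)
    accum = hough_circle(edges, radii)
    scores, cxs, cys, rads = hough_circle_peaks(
        accum, radii, total_num_peaks=max(10 * max_detections, 20),
        min_xdistance=int(rmin), min_ydistance=int(rmin))
    order = sorted(range(len(scores)),
                   key=lambda i: (-scores[i], rads[i], cxs[i], cys[i]))
    chosen: list[CircleDetection] = []
    for i in order:
        det = CircleDetection(center=(float(cxs[i]), float(cys[i])),
                              radius=float(rads[i]), score=float(scores[i]))
        overlaps = any(
            np.hypot(det.center[0] - d.center[0], det.center[1] - d.center[1])
            < det.radius + d.radius
            for d in chosen)
        if not overlaps:
            chosen.append(det)
        if len(chosen) == max_detections:
            break
    return chosen


def crop_to_detections(image: ImageSlice,
                       detections: Sequence[CircleDetection],
                       margin: int = 10) -> ImageSlice:
    """Crop to the margin-dilated bounding box of all detection disks.

    ``origin_offset`` is updated so global = local + offset holds exactly.
    Detection centers are interpreted in the image's own (local) frame.
    """
    if not detections:
        raise ValueError("need at least one detection to crop to")
    h, w = image.shape
    x0 = min(d.center[0] - d.radius for d in detections) - margin
    x1 = max(d.center[0] + d.radius for d in detections) + margin
    y0 = min(d.center[1] - d.radius for d in detections) - margin
    y1 = max(d.center[1] + d.radius for d in detections) + margin
    x0 = int(max(np.floor(x0), 0))
    y0 = int(max(np.floor(y0), 0))
    x1 = int(min(np.ceil(x1), w - 1))
    y1 = int(min(np.ceil(y1), h - 1))
    off = image.origin_offset
    return replace(image,
                   pixels=image.pixels[y0:y1 + 1, x0:x1 + 1].copy(),
                   origin_offset=(off[0] + x0, off[1] + y0))


# ---------------------------------------------------------------------------
# Level-set refinement
# ---------------------------------------------------------------------------

def _mask_to_contour(mask: np.ndarray) -> np.ndarray:
    """Longest closed iso-contour of a mask, CCW-ordered, in (x, y) pixels."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise SegmentationError("no contour in segmentation result")
    longest = max(contours, key=len)
    pts = longest[:, ::-1]  # (row, col) -> (x, y)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    x, y = pts[:, 0], pts[:, 1]
    area2 = np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
    if area2 < 0:
        pts = pts[::-1]
    return pts


def segment_level_set(image: ImageSlice, init_mask: np.ndarray,
                      iterations: int = 100,
                      smoothing_weight: float = 1.0) -> np.ndarray:
    """Region-based (Chan-Vese) level-set evolution from an initial mask.

    Returns the longest closed iso-contour of the final level set, ordered
    counter-clockwise, in the image's local (x, y) pixel coordinates.
    Raises :class:`SegmentationError` if the region collapses to nothing.
    """
    init_mask = np.asarray(init_mask, dtype=bool)
    if init_mask.shape != image.shape:
        raise ValueError("init_mask shape must match image")
    if not init_mask.any():
        raise ValueError("init_mask is empty")
    ls = morphological_chan_vese(
        image.pixels, num_iter=int(iterations),
        init_level_set=init_mask.astype(np.int8),
        smoothing=int(round(smoothing_weight)))
    mask = ls.astype(bool)
    # the bright phase is the structure; flip if the evolution inverted it
    if mask.any() and (image.pixels[mask].mean()
                       < image.pixels[~mask].mean() if (~mask).any() else False):
        mask = ~mask
    # keep only the component(s) seeded by the init mask
    lab = measure.label(mask)
    seeded = np.unique(lab[init_mask & mask])
    seeded = seeded[seeded != 0]
    if len(seeded) == 0:
        raise SegmentationError("level-set evolution collapsed to an empty "
                                "region")
    mask = np.isin(lab, seeded)
    return _mask_to_contour(mask)


# ---------------------------------------------------------------------------
# Hierarchical plan execution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentationStage:
    """One stage of the coarse-to-fine plan.

    ``strategy`` is ``"hough"`` (labels may list several circles to find,
    optionally guided by ``params['prior_centers']``, a label -> (x, y) map
    in global pixel coordinates) or ``"level_set"`` (one label; initialized
    from ``params['prior_disk'] = (cx, cy, r)`` in global coordinates, or by
    Otsu thresholding with previously claimed regions excluded).  After a
    hough stage the working image is cropped to the detections
    (``params['margin']``, default 10 px) for the following stages.
    """

    labels: tuple[str, ...]
    strategy: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strategy not in ("hough", "level_set"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not self.labels:
            raise ValueError("stage needs at least one label")
        if self.strategy == "level_set" and len(self.labels) != 1:
            raise ValueError("level_set stages handle one label at a time")


def _assign_detections(dets: list[CircleDetection], labels: Sequence[str],
                       priors: dict | None, offset: tuple[int, int]
                       ) -> dict[str, CircleDetection]:
    if len(dets) < len(labels):
        missing = labels[len(dets):]
        raise SegmentationError(
            f"hough stage found {len(dets)} circle(s); none left for "
            f"label(s) {list(missing)!r}")
    if not priors:
        return dict(zip(labels, dets))
    out: dict[str, CircleDetection] = {}
    remaining = list(dets)
    for lab in labels:
        px, py = priors[lab]
        local = (px - offset[0], py - offset[1])
        j = min(range(len(remaining)),
                key=lambda k: np.hypot(remaining[k].center[0] - local[0],
                                       remaining[k].center[1] - local[1]))
        out[lab] = remaining.pop(j)
    return out


def hierarchical_segment(image: ImageSlice,
                         plan: Sequence[SegmentationStage]) -> AnnotationSet:
    """Run a coarse-to-fine segmentation plan on one slice.

    Stages execute in order; hough stages crop the working image to their
    detections so later stages search a smaller region.  All contours are
    returned in uncropped global coordinates, scaled to physical units by
    the slice's pixel spacing.
    """
    if not plan:
        raise ValueError("empty segmentation plan")
    current = image
    contours: list[Contour2D] = []
    claimed = np.zeros(image.shape, dtype=bool)  # global-coordinate mask

    for stage in plan:
        p = stage.params
        current = preprocess(current, p.get("smoothing_sigma", 1.0))
        off = current.origin_offset
        if stage.strategy == "hough":
            dets = detect_large_structures(
                current, radius_range=p.get("radius_range", (10, 40)),
                max_detections=p.get("max_detections", len(stage.labels)),
                canny_sigma=p.get("canny_sigma", 2.0))
            if not dets:
                raise SegmentationError(
                    f"no circular structure found for label(s) "
                    f"{list(stage.labels)!r}")
            assigned = _assign_detections(dets, stage.labels,
                                          p.get("prior_centers"), off)
            for lab in stage.labels:
                det = assigned[lab]
                gdet = CircleDetection(
                    center=(det.center[0] + off[0], det.center[1] + off[1]),
                    radius=det.radius, score=det.score)
                if p.get("refine_level_set", False):
                    contour = _refine_disk(current, det, p) \
                        + np.asarray(off, dtype=float)
                else:
                    contour = gdet.contour(p.get("contour_points", 64))
                contours.append(Contour2D(label=lab, points=contour
                                          * image.pixel_spacing, closed=True))
                rr, cc = np.ogrid[:image.shape[0], :image.shape[1]]
                claimed |= ((cc - gdet.center[0]) ** 2
                            + (rr - gdet.center[1]) ** 2
                            <= (gdet.radius + 2) ** 2)
            current = crop_to_detections(current, list(assigned.values()),
                                         margin=p.get("margin", 10))
        else:  # level_set
            lab = stage.labels[0]
            init = _level_set_init(current, claimed, p)
            if init is None:
                raise SegmentationError(
                    f"no candidate region found for label {lab!r}")
            try:
                contour = segment_level_set(
                    current, init, iterations=p.get("iterations", 100),
                    smoothing_weight=p.get("smoothing_weight", 1.0))
            except SegmentationError as exc:
                raise SegmentationError(f"label {lab!r}: {exc}") from exc
            gcontour = contour + np.asarray(off, dtype=float)
            contours.append(Contour2D(label=lab,
                                      points=gcontour * image.pixel_spacing,
                                      closed=True))
            from skimage.draw import polygon as _poly
            rr, cc = _poly(gcontour[:, 1], gcontour[:, 0], shape=image.shape)
            claimed[rr, cc] = True

    return AnnotationSet(slice_id=f"slice-{image.index}",
                         pixel_spacing=image.pixel_spacing,
                         contours=contours)


def _refine_disk(image: ImageSlice, det: CircleDetection, p: dict
                 ) -> np.ndarray:
    """Level-set refinement seeded by an eroded Hough disk (local coords)."""
    h, w = image.shape
    rr, cc = np.ogrid[:h, :w]
    r_init = max(det.radius - 3, 2)
    init = ((cc - det.center[0]) ** 2 + (rr - det.center[1]) ** 2
            <= r_init ** 2)
    return segment_level_set(image, init,
                             iterations=p.get("iterations", 100),
                             smoothing_weight=p.get("smoothing_weight", 1.0))


def _level_set_init(image: ImageSlice, claimed_global: np.ndarray,
                    p: dict) -> np.ndarray | None:
    h, w = image.shape
    off = image.origin_offset
    if "prior_disk" in p:
        cx, cy, r = p["prior_disk"]
        rr, cc = np.ogrid[:h, :w]
        init = ((cc - (cx - off[0])) ** 2 + (rr - (cy - off[1])) ** 2
                <= r ** 2)
        return init if init.any() else None
    thr = threshold_otsu(image.pixels)
    binary = image.pixels > thr
    claimed_local = claimed_global[off[1]:off[1] + h, off[0]:off[0] + w]
    binary &= ~morphology.dilation(claimed_local, morphology.disk(3))
    lab0 = measure.label(binary)
    sizes0 = np.bincount(lab0.ravel())
    small = np.flatnonzero(sizes0 < 9)
    binary &= ~np.isin(lab0, small)
    if not binary.any():
        return None
    lab = measure.label(binary)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


# ---------------------------------------------------------------------------
# Rigid slice registration
# ---------------------------------------------------------------------------

def _resample_closed(points: np.ndarray, n: int,
                     joint_centroid: np.ndarray | None = None) -> np.ndarray:
    """Resample a closed polyline to n points equally spaced in arc length.

    The start point is canonicalized so that index correspondence between two
    rigidly displaced copies of the same contour survives even when their
    stored start points differ (as for traced level-set contours): the start
    is the vertex farthest along the direction from the slice's joint
    centroid to the contour centroid — a rigidly equivariant choice that
    stays well defined for circular contours off the slice center.  Without a
    joint centroid the vertex farthest from the contour's own centroid is
    used."""
    centroid = points.mean(axis=0)
    if joint_centroid is not None \
            and np.linalg.norm(centroid - joint_centroid) > 1e-9:
        direction = centroid - joint_centroid
        start = int(np.argmax((points - centroid) @ direction))
    else:
        start = int(np.argmax(np.linalg.norm(points - centroid, axis=1)))
    points = np.roll(points, -start, axis=0)
    pts = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    targets = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 2))
    for k, s in enumerate(targets):
        i = min(int(np.searchsorted(cum, s, side="right")) - 1, len(seg) - 1)
        f = (s - cum[i]) / seg[i] if seg[i] > 0 else 0.0
        out[k] = pts[i] + f * (pts[i + 1] - pts[i])
    return out


def register_slices(reference: AnnotationSet, moving: AnnotationSet,
                    labels: Sequence[str], n_samples: int = 200
                    ) -> RigidTransform2D:
    """Least-squares rigid registration of two annotated slices.

    Contours of the requested labels are resampled to a fixed count with
    arc-length-index correspondence; the rotation and translation minimizing
    the total squared point-to-point distance (the stacked-contour volume
    proxy) are solved in closed form (2D Procrustes / Kabsch).  The returned
    transform maps moving-slice coordinates into the reference slice.
    """
    ref_pts, mov_pts = [], []
    for lab in labels:
        if lab not in reference or lab not in moving:
            raise ValueError(f"label {lab!r} missing from one annotation set")
    ref_joint = np.mean([reference[lab].centroid() for lab in labels], axis=0)
    mov_joint = np.mean([moving[lab].centroid() for lab in labels], axis=0)
    for lab in labels:
        rc, mc = reference[lab], moving[lab]
        if len(rc.points) < 3 or len(mc.points) < 3:
            raise ValueError(f"label {lab!r} has fewer than 3 points")
        ref_pts.append(_resample_closed(rc.points, n_samples, ref_joint))
        mov_pts.append(_resample_closed(mc.points, n_samples, mov_joint))
    p = np.vstack(ref_pts)
    q = np.vstack(mov_pts)
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    cov = q0.T @ p0
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, d]) @ u.T
    angle = float(np.arctan2(r[1, 0], r[0, 0]))
    t = pc - r @ qc
    return RigidTransform2D(rotation_angle=angle,
                            translation=(float(t[0]), float(t[1])))
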