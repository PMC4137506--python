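"""Synthetic cochlea phantoms with known ground truth.

The real inputs to the reconstruction pipeline — a micro-CT stack of the
coiled cochlea and annotated histological cross-sections — are emulated here
by three generators with analytically known ground truth:

* a tapering helical mid-curve with two parallel "scala" tubes (scala
  vestibuli and scala tympani) offset symmetrically across it, sampled into a
  labelled 3D point cloud;
* rendered 2D cross-section images containing disk-like scala lumina, a thin
  basilar-membrane band and smaller blobs, together with exact contours and
  masks;
* an image stack of planar cuts through the two solid tubes.

All generators are deterministic under a fixed seed.
"""
from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
import tifffile
from scipy.spatial import cKDTree
from skimage import draw as skdraw

__all__ = [
    "HelixSpec",
    "PointCloud",
    "Disk",
    "Ellipse",
    "Band",
    "SectionSpec",
    "helix_curve",
    "helix_radial_direction",
    "scala_offset_curves",
    "generate_scala_cloud",
    "render_section",
    "render_stack",
    "default_phantom",
    "save_cloud_csv",
    "load_cloud_csv",
    "save_cloud_ply",
    "load_cloud_ply",
    "save_image",
    "load_image",
    "save_stack",
]

SCALA_LABELS = ("SV", "ST")


# ---------------------------------------------------------------------------
# Helix specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixSpec:
    """Tapering-helix model of the cochlear spiral.

    The mid-curve winds ``turns`` times around ``axis`` starting at radius
    ``radius_base`` and ending at ``radius_apex`` (linear taper in the curve
    parameter), climbing along the axis with a per-turn pitch that tapers
    linearly from ``pitch_base`` to ``pitch_apex``.  The two scala tubes of
    radius ``tube_radius`` run parallel to the mid-curve at a perpendicular
    offset of ``scala_separation / 2`` along the local radial direction
    (pointing away from the helix axis), mirrored across the mid-curve.
    All lengths are in abstract model units.
    """

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    radius_base: float = 4.0
    radius_apex: float = 1.5
    pitch_base: float = 1.5
    pitch_apex: float = 1.0
    turns: float = 2.5
    scala_separation: float = 0.9
    tube_radius: float = 0.4

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
            raise ValueError("axis must be a unit vector (|norm - 1| <= 1e-9)")
        if self.radius_apex > self.radius_base:
            raise ValueError("radius_apex must not exceed radius_base")
        if self.turns <= 0:
            raise ValueError("turns must be positive")
        if self.scala_separation < 0:
            raise ValueError("scala_separation must be non-negative")
        if self.tube_radius <= 0:
            raise ValueError("tube_radius must be positive")

    @property
    def frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Fixed right-handed orthonormal triad (u, v, axis)."""
        a = np.asarray(self.axis, dtype=float)
        seed = np.array([1.0, 0.0, 0.0])
        if abs(seed @ a) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        u = seed - (seed @ a) * a
        u /= np.linalg.norm(u)
        v = np.cross(a, u)
        return u, v, a


def _check_t(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < -1e-12) or np.any(t > 1 + 1e-12):
        raise ValueError("curve parameter t must lie in [0, 1]")
    return np.clip(t, 0.0, 1.0)


def helix_curve(spec: HelixSpec, t):
    """Evaluate the helix mid-curve c(t) for t in [0, 1].

    ``c(t) = center + r(t) (cos th(t) u + sin th(t) v) + z(t) axis`` with
    ``th`` sweeping ``turns * 2 pi``, ``r`` linear from base to apex radius
    and ``z`` the integral of the linearly tapering pitch.  Accepts scalar or
    array ``t``; vectorized and deterministic.
    """
    t = _check_t(t)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    u, v, a = spec.frame
    theta = 2.0 * np.pi * spec.turns * t
    r = spec.radius_base + (spec.radius_apex - spec.radius_base) * t
    # z(t) = turns * integral_0^t pitch(s) ds with pitch linear in s
    z = spec.turns * (spec.pitch_base * t
                      + 0.5 * (spec.pitch_apex - spec.pitch_base) * t ** 2)
    pts = (np.asarray(spec.center)
           + r[:, None] * (np.cos(theta)[:, None] * u
                           + np.sin(theta)[:, None] * v)
           + z[:, None] * a)
    return pts[0] if scalar else pts


def helix_radial_direction(spec: HelixSpec, t):
    """Unit vector pointing away from the helix axis at parameter t."""
    t = _check_t(t)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    u, v, _ = spec.frame
    theta = 2.0 * np.pi * spec.turns * t
    d = np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v
    return d[0] if scalar else d


def scala_offset_curves(spec: HelixSpec, t):
    """The two scala centerlines: mid-curve +- separation/2 radially.

    Returns ``(sv_points, st_points)``; SV is the outer (+radial) copy.
    """
    mid = np.atleast_2d(helix_curve(spec, t))
    rad = np.atleast_2d(helix_radial_direction(spec, t))
    off = 0.5 * spec.scala_separation * rad
    return mid + off, mid - off


def _assert_no_self_intersection(spec: HelixSpec, n_check: int = 400) -> None:
    """The two tubes must not intersect themselves or each other.

    Dense samples of both offset curves are checked pairwise: any two samples
    whose parameters differ by more than 0.1 must be at least 2*tube_radius
    apart, and the cross-scala gap at equal t must exceed 2*tube_radius.
    """
    if spec.scala_separation > 0 and spec.scala_separation < 2 * spec.tube_radius:
        raise ValueError("scala tubes overlap: separation < tube diameter")
    t = np.linspace(0.0, 1.0, n_check)
    sv, st = scala_offset_curves(spec, t)
    pts = np.vstack([sv, st])
    ts = np.concatenate([t, t])
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    far = np.abs(ts[:, None] - ts[None, :]) > 0.1
    min_d = np.sqrt(d2[far].min()) if far.any() else np.inf
    if min_d < 2 * spec.tube_radius:
        raise ValueError(
            f"helix tubes self-intersect: min inter-turn distance {min_d:.3g}"
            f" < tube diameter {2 * spec.tube_radius:.3g}")


def default_phantom() -> HelixSpec:
    """The default study phantom: 2.5 turns, tapering 4 -> 1.5 radius."""
    return HelixSpec()


# ---------------------------------------------------------------------------
# Point cloud
# ---------------------------------------------------------------------------

@dataclass
class PointCloud:
    """Labelled 3D samples from the two scala lumina."""

    points: np.ndarray  # (N, 3) float
    labels: np.ndarray  # (N,) str, each in {"SV", "ST"}

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.labels = np.asarray(self.labels)
        if len(self.points) != len(self.labels):
            raise ValueError("points and labels must have the same length")
        bad = set(np.unique(self.labels)) - set(SCALA_LABELS)
        if bad:
            raise ValueError(f"unknown scala labels: {sorted(bad)}")

    def subset(self, label: str) -> np.ndarray:
        return self.points[self.labels == label]

    def __len__(self) -> int:
        return len(self.points)


def generate_scala_cloud(
    spec: HelixSpec,
    n_per_scala: int,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[PointCloud, np.ndarray]:
    """Sample a labelled two-scala point cloud plus the ground-truth mid-curve.

    Each scala contributes ``n_per_scala`` samples drawn uniformly in the
    curve parameter on its offset curve, with isotropic Gaussian jitter of
    scale ``noise_sigma``.  Returns ``(cloud, mid_curve)`` where ``mid_curve``
    is the helix mid-curve densely sampled at 2048 points.
    """
    if n_per_scala < 1:
        raise ValueError("n_per_scala must be >= 1")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    _assert_no_self_intersection(spec)
    rng = np.random.default_rng(seed)
    parts, labels = [], []
    for label in SCALA_LABELS:
        t = rng.uniform(0.0, 1.0, n_per_scala)
        sv, st = scala_offset_curves(spec, t)
        base = sv if label == "SV" else st
        if noise_sigma > 0:
            base = base + rng.normal(0.0, noise_sigma, size=base.shape)
        parts.append(base)
        labels.append(np.full(n_per_scala, label))
    cloud = PointCloud(np.vstack(parts), np.concatenate(labels))
    mid = helix_curve(spec, np.linspace(0.0, 1.0, 2048))
    return cloud, mid


# ---------------------------------------------------------------------------
# 2D section rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Disk:
    center: tuple[float, float]  # (x, y) pixels
    radius: float

    def contour(self, n: int = 64) -> np.ndarray:
        a = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        return np.column_stack([
            self.center[0] + self.radius * np.cos(a),
            self.center[1] + self.radius * np.sin(a),
        ])

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        rr, cc = skdraw.disk((self.center[1], self.center[0]), self.radius,
                             shape=shape)
        m[rr, cc] = True
        return m

    closed = True


@dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]
    semiaxes: tuple[float, float]  # (along x, along y) before rotation
    angle: float = 0.0  # radians, counter-clockwise in (x, y)

    def contour(self, n: int = 64) -> np.ndarray:
        a = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        x = self.semiaxes[0] * np.cos(a)
        y = self.semiaxes[1] * np.sin(a)
        c, s = np.cos(self.angle), np.sin(self.angle)
        return np.column_stack([
            self.center[0] + c * x - s * y,
            self.center[1] + s * x + c * y,
        ])

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        # skimage's rotation convention in (row, col) is mirrored relative to
        # a counter-clockwise angle in (x, y); negate to match the contour
        rr, cc = skdraw.ellipse(self.center[1], self.center[0],
                                self.semiaxes[1], self.semiaxes[0],
                                shape=shape, rotation=-self.angle)
        m[rr, cc] = True
        return m

    closed = True


@dataclass(frozen=True)
class Band:
    """Thin rectangular band between two endpoints (basilar-membrane analog)."""

    endpoints: tuple[tuple[float, float], tuple[float, float]]
    thickness: float

    def _corners(self) -> np.ndarray:
        p0 = np.asarray(self.endpoints[0], dtype=float)
        p1 = np.asarray(self.endpoints[1], dtype=float)
        d = p1 - p0
        n = np.array([-d[1], d[0]])
        n /= np.linalg.norm(n)
        h = 0.5 * self.thickness * n
        return np.array([p0 + h, p1 + h, p1 - h, p0 - h])

    def contour(self, n: int = 64) -> np.ndarray:
        corners = self._corners()
        per_side = max(n // 4, 2)
        pts = []
        for i in range(4):
            a, b = corners[i], corners[(i + 1) % 4]
            frac = np.linspace(0.0, 1.0, per_side, endpoint=False)
            pts.append(a + frac[:, None] * (b - a))
        return np.vstack(pts)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        corners = self._corners()
        rr, cc = skdraw.polygon(corners[:, 1], corners[:, 0], shape=shape)
        m[rr, cc] = True
        return m

    closed = True


Shape = Disk | Ellipse | Band


@dataclass
class SectionSpec:
    """Parametric description of a synthetic cross-section image.

    Emulates an annotated histological slice / micro-CT frame: a list of
    labelled parametric shapes rasterized at ``foreground_intensity`` on a
    ``background_intensity`` canvas with additive Gaussian noise.
    """

    image_size: tuple[int, int] = (256, 256)  # (height, width)
    pixel_spacing: float = 1.0
    structures: Sequence[tuple[str, Shape]] = field(default_factory=list)
    foreground_intensity: float = 0.9
    background_intensity: float = 0.1
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.foreground_intensity, self.background_intensity):
            if not 0.0 <= v <= 1.0:
                raise ValueError("intensities must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        labels = [lab for lab, _ in self.structures]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate structure labels: ground truth would "
                             "be ambiguous")
        h, w = self.image_size
        for lab, shape in self.structures:
            c = shape.contour(64)
            if (c[:, 0].min() < 0 or c[:, 1].min() < 0
                    or c[:, 0].max() >= w or c[:, 1].max() >= h):
                raise ValueError(f"structure {lab!r} extends outside the image")


def render_section(spec: SectionSpec):
    """Rasterize a SectionSpec.

    Returns ``(image, annotation, masks)``: the noisy grayscale image in
    [0, 1], a ground-truth annotation (an ``AnnotationSet``; points in
    physical units), and exact boolean masks per label.
    """
    from .projection import AnnotationSet, Contour2D  # avoid import cycle

    h, w = spec.image_size
    img = np.full((h, w), spec.background_intensity, dtype=float)
    masks: dict[str, np.ndarray] = {}
    contours = []
    for label, shape in spec.structures:
        m = shape.mask((h, w))
        masks[label] = m
        img[m] = spec.foreground_intensity
        contours.append(Contour2D(
            label=label,
            points=shape.contour(64) * spec.pixel_spacing,
            closed=True,
        ))
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = np.clip(img + rng.normal(0.0, spec.noise_sigma, img.shape),
                      0.0, 1.0)
    annotation = AnnotationSet(
        slice_id="phantom-section",
        pixel_spacing=spec.pixel_spacing,
        contours=contours,
    )
    return img, annotation, masks


# ---------------------------------------------------------------------------
# Image-stack rendering (micro-CT analog)
# ---------------------------------------------------------------------------

def render_stack(
    spec: HelixSpec,
    n_slices: int,
    slice_axis=(0.0, 0.0, 1.0),
    image_size: tuple[int, int] = (128, 128),
    pixel_spacing: float = 0.1,
    seed: int = 0,
    noise_sigma: float = 0.0,
    curve_samples: int = 4096,
):
    """Planar cuts through the two solid scala tubes, perpendicular to
    ``slice_axis`` and equally spaced over the phantom's extent.

    Returns ``(stack, masks, meta)`` where ``stack`` is ``(n_slices, H, W)``
    float (foreground 1, background 0, plus optional noise), ``masks`` maps
    each scala label to a boolean ``(n_slices, H, W)`` array, and ``meta``
    records the slice geometry.
    """
    if n_slices < 2:
        raise ValueError("n_slices must be >= 2")
    a = np.asarray(slice_axis, dtype=float)
    a = a / np.linalg.norm(a)
    seed_vec = np.array([1.0, 0.0, 0.0])
    if abs(seed_vec @ a) > 0.9:
        seed_vec = np.array([0.0, 1.0, 0.0])
    p = seed_vec - (seed_vec @ a) * a
    p /= np.linalg.norm(p)
    q = np.cross(a, p)

    t = np.linspace(0.0, 1.0, curve_samples)
    sv, st = scala_offset_curves(spec, t)
    trees = {"SV": cKDTree(sv), "ST": cKDTree(st)}
    allpts = np.vstack([sv, st])
    along = allpts @ a
    lo = along.min() - spec.tube_radius
    hi = along.max() + spec.tube_radius
    positions = np.linspace(lo, hi, n_slices)

    h, w = image_size
    in_plane = allpts - np.outer(along, a)
    pc, qc = in_plane @ p, in_plane @ q
    center_p = 0.5 * (pc.min() + pc.max())
    center_q = 0.5 * (qc.min() + qc.max())
    cols = (np.arange(w) - (w - 1) / 2.0) * pixel_spacing + center_p
    rows = (np.arange(h) - (h - 1) / 2.0) * pixel_spacing + center_q
    grid_p, grid_q = np.meshgrid(cols, rows)

    stack = np.zeros((n_slices, h, w), dtype=float)
    masks = {lab: np.zeros((n_slices, h, w), dtype=bool)
             for lab in SCALA_LABELS}
    for i, d in enumerate(positions):
        pos = (grid_p[..., None] * p + grid_q[..., None] * q + d * a)
        flat = pos.reshape(-1, 3)
        for lab, tree in trees.items():
            dist, _ = tree.query(flat, k=1)
            inside = (dist <= spec.tube_radius).reshape(h, w)
            masks[lab][i] = inside
            stack[i][inside] = 1.0
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        stack = np.clip(stack + rng.normal(0.0, noise_sigma, stack.shape),
                        0.0, 1.0)
    meta = {
        "pixel_spacing": pixel_spacing,
        "slice_spacing": float(positions[1] - positions[0]),
        "slice_positions": positions.tolist(),
        "slice_axis": a.tolist(),
    }
    return stack, masks, meta


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def save_cloud_csv(cloud: PointCloud, path) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["x", "y", "z", "label"])
        for (x, y, z), lab in zip(cloud.points, cloud.labels):
            wr.writerow([repr(float(x)), repr(float(y)), repr(float(z)), lab])


def load_cloud_csv(path) -> PointCloud:
    pts, labs = [], []
    with open(path, newline="") as fh:
        rd = csv.DictReader(fh)
        for row in rd:
            pts.append([float(row["x"]), float(row["y"]), float(row["z"])])
            labs.append(row["label"].strip())
    return PointCloud(np.asarray(pts), np.asarray(labs))


def save_cloud_ply(cloud: PointCloud, path) -> None:
    """ASCII PLY with a per-vertex uchar ``label`` property (0=SV, 1=ST)."""
    codes = {"SV": 0, "ST": 1}
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(cloud)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property uchar label\n")
        fh.write("comment label 0=SV 1=ST\nend_header\n")
        for (x, y, z), lab in zip(cloud.points, cloud.labels):
            fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r} {codes[lab]}\n")


def load_cloud_ply(path) -> PointCloud:
    names = {0: "SV", 1: "ST"}
    pts, labs = [], []
    with open(path) as fh:
        line = fh.readline()
        if line.strip() != "ply":
            raise ValueError("not a PLY file")
        while True:
            line = fh.readline()
            if not line:
                raise ValueError("truncated PLY header")
            if line.strip() == "end_header":
                break
        for line in fh:
            if not line.strip():
                continue
            x, y, z, code = line.split()
            pts.append([float(x), float(y), float(z)])
            labs.append(names[int(code)])
    return PointCloud(np.asarray(pts), np.asarray(labs))


def save_image(image: np.ndarray, path, bit_depth: int = 16) -> None:
    """Write a [0, 1] float image as 16-bit TIFF or 8-bit PNG."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        if bit_depth != 16:
            raise ValueError("TIFF output is written as 16-bit")
        tifffile.imwrite(path, np.round(image * 65535).astype(np.uint16))
    elif path.suffix.lower() == ".png":
        Image.fromarray(np.round(image * 255).astype(np.uint8)).save(path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")


def load_image(path) -> tuple[np.ndarray, int]:
    """Read an image; returns ([0, 1] float array, source bit depth)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raw = tifffile.imread(path)
    else:
        raw = np.asarray(Image.open(path))
    if raw.dtype == np.uint8:
        return raw.astype(float) / 255.0, 8
    if raw.dtype == np.uint16:
        return raw.astype(float) / 65535.0, 16
    raise ValueError(f"unsupported bit depth {raw.dtype} in {path}")


def save_stack(stack: np.ndarray, meta: dict, out_dir, fmt: str = "tif") -> list[Path]:
    """Write a stack as numbered images plus a JSON sidecar with spacings."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for i, sl in enumerate(stack):
        f = out_dir / f"slice_{i:04d}.{fmt}"
        save_image(sl, f, bit_depth=16 if fmt in ("tif", "tiff") else 8)
        files.append(f)
    sidecar = out_dir / "stack_meta.json"
    with open(sidecar, "w") as fh:
        json.dump({"pixel_spacing": meta["pixel_spacing"],
                   "slice_spacing": meta["slice_spacing"]}, fh, indent=1)
    files.append(sidecar)
    return files


def numeric_sort_key(path) -> tuple:
    """Sort key ordering file names by embedded integer (1, 2, 10 not 1, 10, 2)."""
    name = Path(path).name
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)
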