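"""Centerline extraction from a two-scala point cloud.

The coiled cochlea's centerline is estimated by fitting a *mirrored*
Gaussian mixture to the labelled point cloud sampled from the scala
vestibuli and scala tympani: M pairs of isotropic Gaussian components are
laid along an initial helix, one pair member per scala, mirrored across the
helix at half the scala separation.  An EM loop updates the component means
through a single global affine transform of the initial layout followed by
ridge-regularized per-pair local affine corrections, so the geometry of the
initial model is maintained while the mixture snaps onto the data.  The two
per-scala polylines of fitted means are averaged pointwise into the cochlea
centerline, which is then interpolated by a cubic b-spline and resampled at
N stations equidistant in arc length, with unit tangents per station.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate
from scipy.optimize import brentq
from scipy.special import logsumexp

from .phantom import HelixSpec, PointCloud, scala_offset_curves

logger = logging.getLogger(__name__)

__all__ = [
    "MirroredGMM",
    "FitConfig",
    "Centerline",
    "init_mirrored_gmm",
    "fit_gmm",
    "extract_scala_centerlines",
    "average_centerlines",
    "extend_polyline_to_data",
    "build_centerline",
]


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class MirroredGMM:
    """M mirrored pairs of isotropic Gaussians, one member per scala.

    ``means_sv[i]`` and ``means_st[i]`` are pair i's two component means;
    all 2M components share the isotropic ``variance``.  ``pair_weights[i]``
    is the weight of *each* member of pair i, so weights sum to 1 over all
    2M components.  After fitting, ``global_affine`` holds the estimated
    (A, b) applied to the initial means and ``frozen`` flags pairs that
    received no responsibility.
    """

    means_sv: np.ndarray  # (M, 3)
    means_st: np.ndarray  # (M, 3)
    variance: float
    pair_weights: np.ndarray  # (M,)
    global_affine: tuple[np.ndarray, np.ndarray] | None = None
    frozen: np.ndarray | None = None  # (M,) bool

    def __post_init__(self) -> None:
        self.means_sv = np.asarray(self.means_sv, dtype=float).reshape(-1, 3)
        self.means_st = np.asarray(self.means_st, dtype=float).reshape(-1, 3)
        self.pair_weights = np.asarray(self.pair_weights, dtype=float)
        if len(self.means_sv) != len(self.means_st):
            raise ValueError("means_sv and means_st must pair up")
        if self.variance <= 0:
            raise ValueError("variance must be positive")
        if np.any(self.pair_weights <= 0):
            raise ValueError("weights must be positive")
        if abs(2.0 * self.pair_weights.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1 over all 2M")

    @property
    def n_pairs(self) -> int:
        return len(self.means_sv)

    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.means_sv + self.means_st)


@dataclass(frozen=True)
class FitConfig:
    """EM fit controls.

    ``local_affine_regularization`` is the ridge weight pulling each pair's
    local affine toward the identity; large values pin the locals so only the
    global affine acts.  ``tolerance`` is the relative log-likelihood change
    that stops the loop.
    """

    max_iterations: int = 50
    tolerance: float = 1e-7
    local_affine_regularization: float = 1.0
    update_variances: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.local_affine_regularization < 0:
            raise ValueError("regularization weight must be >= 0")


def init_mirrored_gmm(helix: HelixSpec, n_pairs: int,
                      variance: float) -> MirroredGMM:
    """Lay M mirrored component pairs along the initial helix.

    Pair i's means are the two scala offset-curve points at t_i, for t_i
    equally spaced in [0, 1]; all component weights equal 1/(2M).
    """
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    if variance <= 0:
        raise ValueError("variance must be positive")
    t = np.linspace(0.0, 1.0, n_pairs)
    sv, st = scala_offset_curves(helix, t)
    w = np.full(n_pairs, 1.0 / (2 * n_pairs))
    return MirroredGMM(means_sv=sv, means_st=st, variance=variance,
                       pair_weights=w)


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _group_estep(points: np.ndarray, means: np.ndarray, weights: np.ndarray,
                 variance: float) -> tuple[np.ndarray, float]:
    """Responsibilities and log-likelihood of one label group.

    Scala labels gate the mixture: SV points see only the M SV components
    (with their weights renormalized within the group), ST likewise.
    """
    d2 = np.sum((points[:, None, :] - means[None, :, :]) ** 2, axis=-1)
    log_w = np.log(weights / weights.sum())
    log_p = log_w[None, :] - 0.5 * d2 / variance \
        - 1.5 * np.log(2.0 * np.pi * variance)
    norm = logsumexp(log_p, axis=1)
    resp = np.exp(log_p - norm[:, None])
    return resp, float(norm.sum())


def _fit_global_affine(mu0: np.ndarray, targets: np.ndarray,
                       counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted least-squares affine (A, b): A mu0 + b ~= targets."""
    h = np.hstack([mu0, np.ones((len(mu0), 1))])
    w = counts / max(counts.sum(), 1e-300)
    hw = h * w[:, None]
    gram = h.T @ hw
    rhs = hw.T @ targets
    # tiny Tikhonov keeps degenerate layouts (coplanar means) solvable
    gram += 1e-12 * np.trace(gram) / 4.0 * np.eye(4)
    theta = np.linalg.solve(gram, rhs)  # (4, 3)
    return theta[:3].T, theta[3]


def _fit_local_affine(pts: np.ndarray, targets: np.ndarray,
                      counts: np.ndarray, lam: float) -> np.ndarray:
    """Ridge-regularized local affine of one pair, returning new means.

    Solves, about the pair centroid c, min over (L, t) of
    sum_j n_j |L (p_j - c) + t + c - y_j|^2 + lam (|L - I|_F^2 + |t|^2);
    with only two points per pair the problem is underdetermined and the
    ridge pulls the solution toward the identity.
    """
    c = pts.mean(axis=0)
    d = pts - c
    r = targets - c
    design = np.hstack([d, np.ones((len(d), 1))])  # (J, 4)
    gram = design.T @ (design * counts[:, None]) + lam * np.eye(4)
    new = np.empty_like(pts)
    sol = np.empty((4, 3))
    for m in range(3):
        prior = np.zeros(4)
        prior[m] = 1.0  # row of the identity, zero translation
        rhs = design.T @ (counts * r[:, m]) + lam * prior
        sol[:, m] = np.linalg.solve(gram, rhs)
    new = c + design @ sol
    return new


def fit_gmm(model: MirroredGMM, cloud: PointCloud,
            config: FitConfig | None = None
            ) -> tuple[MirroredGMM, np.ndarray]:
    """EM fit of the mirrored GMM to a labelled two-scala cloud.

    E-step: per-label responsibilities over the label's M components.
    M-step: a single global affine (12 parameters) of the *initial* means is
    fit to the responsibility-weighted barycenters, then each pair receives a
    shared ridge-regularized local affine correction.  A candidate update is
    only accepted if it does not increase the weighted squared distance to
    the barycenters (generalized EM), which makes the returned
    log-likelihood trace non-decreasing.

    Returns the fitted model and the per-iteration log-likelihood trace.
    """
    if config is None:
        config = FitConfig()
    if len(cloud) == 0:
        raise ValueError("cloud is empty")
    m = model.n_pairs
    x_sv = cloud.subset("SV")
    x_st = cloud.subset("ST")
    if len(x_sv) == 0 or len(x_st) == 0:
        raise ValueError("cloud must contain points of both scalae")

    mu0 = np.vstack([model.means_sv, model.means_st])  # (2M, 3) initial
    means = mu0.copy()
    # closed-form centroid pre-alignment: EM is local, so start the means at
    # the data's center of mass (exact for a purely translated cloud)
    shift = 0.5 * ((x_sv.mean(axis=0) - means[:m].mean(axis=0))
                   + (x_st.mean(axis=0) - means[m:].mean(axis=0)))
    means = means + shift
    weights = np.concatenate([model.pair_weights, model.pair_weights])
    variance = model.variance
    lam = config.local_affine_regularization
    frozen = np.zeros(m, dtype=bool)
    trace: list[float] = []
    glob: tuple[np.ndarray, np.ndarray] | None = None

    for _ in range(config.max_iterations):
        resp_sv, ll_sv = _group_estep(x_sv, means[:m], weights[:m], variance)
        resp_st, ll_st = _group_estep(x_st, means[m:], weights[m:], variance)
        ll = ll_sv + ll_st
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) \
                < config.tolerance * abs(trace[-2]):
            break

        counts = np.concatenate([resp_sv.sum(axis=0), resp_st.sum(axis=0)])
        starved = (counts[:m] < 1e-12) | (counts[m:] < 1e-12)
        newly = starved & ~frozen
        if newly.any():
            logger.warning("freezing %d starved mirrored pair(s) at their "
                           "current position", int(newly.sum()))
        frozen |= starved
        active = ~frozen
        act2 = np.concatenate([active, active])

        with np.errstate(invalid="ignore"):
            bary = np.vstack([
                resp_sv.T @ x_sv / np.maximum(counts[:m, None], 1e-300),
                resp_st.T @ x_st / np.maximum(counts[m:, None], 1e-300),
            ])

        if not active.any():
            break
        a_mat, b_vec = _fit_global_affine(mu0[act2], bary[act2], counts[act2])
        glob = (a_mat, b_vec)
        cand = means.copy()
        g_all = mu0 @ a_mat.T + b_vec
        for i in np.flatnonzero(active):
            idx = np.array([i, m + i])
            cand[idx] = _fit_local_affine(g_all[idx], bary[idx],
                                          counts[idx], lam)

        # generalized-EM guard: accept only if the expected complete-data
        # objective (weighted SSE to barycenters) does not get worse
        sse_new = np.sum(counts[act2] * np.sum((cand[act2] - bary[act2]) ** 2,
                                               axis=1))
        sse_old = np.sum(counts[act2] * np.sum((means[act2] - bary[act2]) ** 2,
                                               axis=1))
        if sse_new <= sse_old + 1e-12 * max(sse_old, 1.0):
            means = cand
        else:
            break

        if config.update_variances:
            tot = (np.sum(resp_sv * np.sum((x_sv[:, None, :]
                                            - means[None, :m]) ** 2, axis=-1))
                   + np.sum(resp_st * np.sum((x_st[:, None, :]
                                              - means[None, m:]) ** 2,
                                             axis=-1)))
            variance = max(tot / (3.0 * (len(x_sv) + len(x_st))), 1e-12)

    fitted = MirroredGMM(
        means_sv=means[:m], means_st=means[m:], variance=variance,
        pair_weights=model.pair_weights.copy(), global_affine=glob,
        frozen=frozen,
    )
    return fitted, np.asarray(trace)


# ---------------------------------------------------------------------------
# Scala centerlines and their average
# ---------------------------------------------------------------------------

def extract_scala_centerlines(model: MirroredGMM
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Ordered per-scala polylines of fitted component means (SV, ST)."""
    return model.means_sv.copy(), model.means_st.copy()


def average_centerlines(sv: np.ndarray, st: np.ndarray) -> np.ndarray:
    """Pointwise midpoint of the two scala polylines: the cochlea centerline."""
    sv = np.asarray(sv, dtype=float)
    st = np.asarray(st, dtype=float)
    if sv.shape != st.shape:
        raise ValueError("scala polylines must have equal point counts")
    return 0.5 * (sv + st)


def _fit_end_arc(pts: np.ndarray) -> tuple:
    """Fit a planar circular arc through ordered end vertices.

    Returns a sampler ``f(ds)`` giving 3D points at arc offset ``ds`` beyond
    the last vertex (negative ``ds`` walks back along the arc).  Falls back
    to the straight end direction when the points are nearly collinear.
    """
    c0 = pts.mean(axis=0)
    q = pts - c0
    _, sing, vt = np.linalg.svd(q, full_matrices=False)
    e1, e2 = vt[0], vt[1]
    xy = np.column_stack([q @ e1, q @ e2])
    span = np.linalg.norm(pts[-1] - pts[0])
    straight = sing[1] < 1e-6 * max(sing[0], 1e-300)
    if not straight:
        # Kasa algebraic circle fit in the local plane
        a_mat = np.column_stack([2 * xy, np.ones(len(xy))])
        rhs = (xy ** 2).sum(axis=1)
        sol, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
        cx, cy = sol[0], sol[1]
        rad = np.sqrt(max(sol[2] + cx * cx + cy * cy, 1e-300))
        straight = rad > 50.0 * span
    if straight:
        d = pts[-1] - pts[-2]
        d = d / np.linalg.norm(d)

        def line(ds, p_end=pts[-1].copy(), d=d):
            ds = np.atleast_1d(np.asarray(ds, dtype=float))
            return p_end + ds[:, None] * d

        return line
    ang = np.arctan2(xy[:, 1] - cy, xy[:, 0] - cx)
    ang = np.unwrap(ang)
    direction = np.sign(ang[-1] - ang[0]) or 1.0
    # linear out-of-plane drift in angle makes the fit a local helix, so the
    # extension follows the coil's pitch instead of flattening it
    e3 = np.cross(e1, e2)
    h = q @ e3
    h1, h0 = np.polyfit(ang, h, 1)
    speed = np.hypot(rad, h1)

    def arc(ds, cx=cx, cy=cy, rad=rad, a_end=ang[-1], direction=direction,
            c0=c0.copy(), e1=e1.copy(), e2=e2.copy(), e3=e3.copy(),
            h0=h0, h1=h1, speed=speed):
        ds = np.atleast_1d(np.asarray(ds, dtype=float))
        a = a_end + direction * ds / speed
        x = cx + rad * np.cos(a)
        y = cy + rad * np.sin(a)
        z = h0 + h1 * a
        return (c0 + x[:, None] * e1 + y[:, None] * e2 + z[:, None] * e3)

    return arc


def _end_extension(polyline: np.ndarray, data: np.ndarray, sigma: float,
                   capture_radius: float, max_ext: float, k: int,
                   side: int):
    """Propose one end's extension: (arc sampler, ML extension length).

    ``side`` 0 is the first-vertex end, 1 the last-vertex end.  Returns
    ``(sampler, None)`` when too few data points fall in the end window.
    """
    from scipy.optimize import minimize_scalar
    from scipy.spatial import cKDTree
    from scipy.stats import norm

    spacing = float(np.mean(np.linalg.norm(np.diff(polyline, axis=0),
                                           axis=1)))
    pts_end = polyline[:k][::-1] if side == 0 else polyline[-k:]
    sampler = _fit_end_arc(pts_end)
    # dense end-region curve: 2.5 spacings inward, then outward extrapolation
    ds = np.linspace(-2.5 * spacing, 1.5 * max_ext, 600)
    curve = sampler(ds)
    s_end = 2.5 * spacing  # arc coordinate of the end vertex
    s_of = ds + s_end
    tree = cKDTree(curve)
    dist, idx = tree.query(data, k=1)
    near = dist < capture_radius
    s = s_of[idx[near]]
    s = s[s > 0.0]
    if len(s) < 10:
        return sampler, None, 0.0
    grid = np.linspace(0.0, float(s_of[-1]), 400)

    def nll(t_cand):
        phi = norm.cdf((t_cand - s) / sigma)
        z = np.trapezoid(norm.cdf((t_cand - grid) / sigma), grid)
        return (-np.sum(np.log(np.maximum(phi, 1e-300)))
                + len(s) * np.log(max(z, 1e-300)))

    res = minimize_scalar(nll, bounds=(s_end - 0.5 * spacing,
                                       s_end + max_ext),
                          method="bounded",
                          options={"xatol": 1e-4 * spacing})
    plateau = s[(s > 0.5 * spacing) & (s < s_end - 0.5 * spacing)]
    window = max(s_end - spacing, 1e-300)
    rho = len(plateau) / window
    return sampler, float(res.x) - s_end, rho


def extend_polyline_to_data(polyline: np.ndarray, data: np.ndarray,
                            noise_sigma: float,
                            capture_radius: float | None = None,
                            max_extension_factor: float = 2.0,
                            end_fit_points: int = 8) -> np.ndarray:
    """Extend a fitted centerline polyline to the full extent of the data.

    The outermost mixture components sit at the barycenter of a one-sided
    responsibility window, so a fitted centerline systematically stops short
    of the tube ends.  For each end a local helical arc (planar circle plus
    linear out-of-plane drift) is fit through the last ``end_fit_points``
    vertices — robust to single-vertex noise, unlike extrapolating the
    interpolating spline — nearby data points receive an arc-length
    coordinate by nearest-point projection onto the arc-extended end curve,
    and the true tube-end position is estimated by maximum likelihood under
    the smoothed-step density ``f(s) ~ Phi((T - s)/sigma)`` (uniform tube
    occupancy convolved with the known isotropic sampling noise).  One extra
    vertex is appended per end at the estimated position.

    ``capture_radius`` limits which data points count as belonging to this
    tube end (default half the vertex spacing plus three noise sigmas);
    keep it below the gap to the neighboring coil turn or foreign points
    will masquerade as tube mass beyond the end.  ``max_extension_factor``
    bounds the extension to that multiple of the mean vertex spacing.  With
    ``noise_sigma`` 0 a tiny floor keeps the likelihood well defined.
    """
    polyline = np.asarray(polyline, dtype=float).reshape(-1, 3)
    data = np.asarray(data, dtype=float).reshape(-1, 3)
    if len(polyline) < 4:
        raise ValueError("need at least 4 polyline points")
    spacing = float(np.mean(np.linalg.norm(np.diff(polyline, axis=0),
                                           axis=1)))
    sigma = max(noise_sigma, 1e-3 * spacing)
    if capture_radius is None:
        capture_radius = 0.5 * spacing + 3.0 * sigma
    max_ext = max_extension_factor * spacing
    k = min(end_fit_points, len(polyline))

    from scipy.spatial import cKDTree

    out = [polyline]
    for side in (0, 1):
        sampler, ext, _ = _end_extension(polyline, data, sigma,
                                         capture_radius, max_ext, k, side)
        if ext is not None and ext > 0.0:
            p_new = sampler(ext)[0]
            # lateral refinement: the extrapolated arc drifts off the true
            # tube axis, but the data near the end pin it down to
            # sigma / sqrt(n); recenter the new vertex on the local medial
            # mean of the perpendicular offsets
            ds = np.linspace(ext - 1.5 * spacing, ext, 200)
            curve = sampler(ds)
            tree = cKDTree(curve)
            dist, idx = tree.query(data, k=1)
            near = dist < capture_radius
            if near.sum() >= 10:
                feet = curve[idx[near]]
                eps = 1e-4 * spacing
                tans = sampler(ds[idx[near]] + eps) - sampler(
                    ds[idx[near]] - eps)
                tans /= np.linalg.norm(tans, axis=1, keepdims=True)
                off = data[near] - feet
                perp = off - np.einsum("ij,ij->i", off, tans)[:, None] * tans
                p_new = p_new + perp.mean(axis=0)
            if side == 0:
                out.insert(0, p_new[None, :])
            else:
                out.append(p_new[None, :])
    return np.vstack(out)


# ---------------------------------------------------------------------------
# B-spline centerline with equidistant stations
# ---------------------------------------------------------------------------

@dataclass
class Centerline:
    """Arc-length-parameterized cubic b-spline curve with N stations.

    ``stations`` are points equidistant in arc length (both endpoints
    included); ``tangents`` are unit spline derivatives at the stations.
    """

    control_points: np.ndarray  # the input polyline
    tck: tuple
    stations: np.ndarray  # (N, 3)
    tangents: np.ndarray  # (N, 3)
    arc_length: float
    station_arclengths: np.ndarray  # (N,) cumulative arc length per station
    station_params: np.ndarray = field(default=None)  # (N,) spline parameter u

    def evaluate(self, u) -> np.ndarray:
        return np.asarray(interpolate.splev(u, self.tck), dtype=float).T

    def to_json(self, path) -> None:
        payload = {
            "control_points": self.control_points.tolist(),
            "stations": self.stations.tolist(),
            "tangents": self.tangents.tolist(),
            "arc_length": self.arc_length,
            "station_arclengths": self.station_arclengths.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def to_ply(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(self.stations)}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write(f"element edge {len(self.stations) - 1}\n")
            fh.write("property int vertex1\nproperty int vertex2\n")
            fh.write("end_header\n")
            for v in self.stations:
                fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
            for i in range(len(self.stations) - 1):
                fh.write(f"{i} {i + 1}\n")


# 8-point Gauss-Legendre nodes/weights on [0, 1]
_GL_X, _GL_W = np.polynomial.legendre.leggauss(8)
_GL_X = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W


def _speed(tck, u):
    d = np.asarray(interpolate.splev(u, tck, der=1), dtype=float)
    return np.linalg.norm(d, axis=0)


def _segment_length(tck, u0: float, u1: float) -> float:
    """Gauss-Legendre quadrature of the speed over [u0, u1]."""
    if u1 <= u0:
        return 0.0
    u = u0 + (u1 - u0) * _GL_X
    return float((u1 - u0) * np.sum(_GL_W * _speed(tck, u)))


def build_centerline(points: np.ndarray, n_stations: int = 200,
                     spline_smoothing: float = 0.0) -> Centerline:
    """Cubic b-spline through a polyline, resampled equidistantly in arc length.

    With ``spline_smoothing`` 0 the spline interpolates the input points.
    Arc length is accumulated by composite Gauss-Legendre quadrature of the
    spline speed; station parameters are found by bisection on the
    cumulative length with tolerance 1e-9 of the total length.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if n_stations < 2:
        raise ValueError("n_stations must be >= 2")
    keep = np.ones(len(points), dtype=bool)
    keep[1:] = np.any(np.diff(points, axis=0) != 0.0, axis=1)
    if not keep.all():
        warnings.warn("duplicate consecutive centerline points removed",
                      stacklevel=2)
        points = points[keep]
    if len(points) < 4:
        raise ValueError("need at least 4 unique points for a cubic b-spline")

    tck, _ = interpolate.splprep(points.T, s=spline_smoothing, k=3)

    n_sub = max(256, 8 * len(points))
    grid = np.linspace(0.0, 1.0, n_sub + 1)
    seg = np.array([_segment_length(tck, grid[i], grid[i + 1])
                    for i in range(n_sub)])
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(cum[-1])
    tol = 1e-9 * total

    targets = np.linspace(0.0, total, n_stations)
    params = np.empty(n_stations)
    params[0], params[-1] = 0.0, 1.0
    for j in range(1, n_stations - 1):
        tgt = targets[j]
        i = int(np.searchsorted(cum, tgt, side="right") - 1)
        i = min(i, n_sub - 1)
        rem = tgt - cum[i]

        def f(u, _i=i, _rem=rem):
            return _segment_length(tck, grid[_i], u) - _rem

        lo, hi = grid[i], grid[i + 1]
        if f(hi) < 0:  # guard against quadrature round-off at the seam
            params[j] = hi
        else:
            params[j] = brentq(f, lo, hi, xtol=max(tol / max(total, 1e-300),
                                                   1e-14))

    stations = np.asarray(interpolate.splev(params, tck), dtype=float).T
    deriv = np.asarray(interpolate.splev(params, tck, der=1), dtype=float).T
    tangents = deriv / np.linalg.norm(deriv, axis=1, keepdims=True)
    return Centerline(
        control_points=points, tck=tck, stations=stations, tangents=tangents,
        arc_length=total, station_arclengths=targets, station_params=params,
    )
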