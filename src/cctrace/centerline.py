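"""Distance-map representation and active-contour extraction of the centerline.

The centerline is represented implicitly by the Euclidean distance map of the
segmented callosum: each foreground pixel carries its distance to the nearest
boundary pixel, so the ridge of the (normalised) map runs along the medial
axis.  An open active contour (snake) with its two endpoints clamped at the
detected anterior/posterior endpoints is initialised by a cubic spline through
the maximal-distance points on the four partition divider rays and evolved
semi-implicitly under

* internal tension/rigidity forces (weights ``alpha``, ``beta``) discretised
  with the standard pentadiagonal operator, endpoints as Dirichlet rows, and
* an external force ``c(D) * grad D`` ascending the normalised distance map,
  where the modulation coefficient ``c(d) = (e - e^d)/(e - 1)`` is 1 at the
  boundary and 0 on the ridge, stabilising convergence near the centerline.

Interior points are redistributed at equal arc length every few iterations;
the endpoints are never touched, so the output endpoints are bit-identical to
the detected ones and the whole pipeline is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import linalg, ndimage

from .errors import CenterlineError
from .geometry import BinaryMask, Partition, boundary_pixels
from .shape_context import (ANTERIOR, POSTERIOR, EndpointModel, analyze_mask,
                            localize_endpoint)


@dataclass(frozen=True, eq=False)
class DistanceMap:
    """Per-pixel Euclidean distance to the nearest boundary pixel.

    ``values`` is zero on the background and on boundary pixels themselves;
    ``normalized`` is ``values / values.max()``.
    """

    values: np.ndarray
    normalized: np.ndarray
    foreground: np.ndarray

    def interp(self, points) -> np.ndarray:
        """Bilinear interpolation of ``values`` at subpixel (x, y) points."""
        pts = np.asarray(points, float).reshape(-1, 2)
        return ndimage.map_coordinates(self.values, [pts[:, 1], pts[:, 0]],
                                       order=1, mode="nearest")


@dataclass(frozen=True)
class SnakeConfig:
    """Active-contour parameters (tension alpha, rigidity beta)."""

    alpha: float = 0.1
    beta: float = 0.5
    n_points: int = 100
    time_step: float = 1.0
    max_iter: int = 500
    tol_px: float = 0.01
    resample_every: int = 10

    def __post_init__(self):
        if min(self.alpha, self.beta, self.time_step, self.tol_px) <= 0:
            raise CenterlineError("alpha, beta, time_step, tol_px must be > 0")
        if self.n_points < 5:
            raise CenterlineError("need at least 5 snake points")


@dataclass(frozen=True, eq=False)
class Centerline:
    """Open subpixel polyline from the anterior to the posterior endpoint."""

    points: np.ndarray
    pixel_size_mm: float = 1.0

    def __post_init__(self):
        pts = np.asarray(self.points, float).reshape(-1, 2)
        if len(pts) >= 2:
            dup = np.all(np.diff(pts, axis=0) == 0, axis=1)
            if dup.any():
                pts = np.vstack([pts[:1], pts[1:][~dup]])
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def anterior(self) -> np.ndarray:
        return self.points[0]

    @property
    def posterior(self) -> np.ndarray:
        return self.points[-1]


class SnakeSolution(NamedTuple):
    centerline: Centerline
    iterations: int
    converged: bool
    final_step_px: float


def distance_map(mask: BinaryMask) -> DistanceMap:
    """Exact Euclidean distance of every foreground pixel to the boundary."""
    fg = mask.foreground()
    if not fg.any():
        raise CenterlineError("empty mask")
    boundary = boundary_pixels(mask)
    values = ndimage.distance_transform_edt(~boundary)
    values[~fg] = 0.0
    vmax = float(values.max())
    if vmax == 0.0:
        raise CenterlineError("no interior")
    return DistanceMap(values=values, normalized=values / vmax, foreground=fg)


def modulation_coefficient(d_norm):
    """Force modulation ``c(d) = (e - e^d)/(e - 1)`` on the normalised distance.

    Continuous and strictly decreasing with ``c(0) = 1`` (boundary) and
    ``c(1) = 0`` (centerline ridge).  Inputs outside [0, 1] are clamped with a
    warning.
    """
    d = np.asarray(d_norm, float)
    if np.any(d < 0) or np.any(d > 1):
        warnings.warn("distance values outside [0, 1] clamped", stacklevel=2)
        d = np.clip(d, 0.0, 1.0)
    out = (np.e - np.exp(d)) / (np.e - 1.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True, eq=False)
class ForceField:
    """External snake force ``c(D) * grad D`` sampled on the pixel grid."""

    fx: np.ndarray
    fy: np.ndarray
    foreground: np.ndarray = None

    def at(self, points) -> np.ndarray:
        pts = np.asarray(points, float).reshape(-1, 2)
        coords = [pts[:, 1], pts[:, 0]]
        return np.column_stack([
            ndimage.map_coordinates(self.fx, coords, order=1, mode="nearest"),
            ndimage.map_coordinates(self.fy, coords, order=1, mode="nearest"),
        ])


def external_force(dm: DistanceMap) -> ForceField:
    """Modulated gradient-ascent force of the normalised distance map.

    Central differences (one-sided at image borders).  The force vanishes on
    the ridge plateau through ``c(1) = 0`` and on background farther than one
    pixel from the object (flat ``D = 0``); background pixels touching the
    boundary keep the inward pull their central difference picks up from the
    interior, which recaptures snake points that stray outside.
    """
    gy, gx = np.gradient(dm.normalized)
    c = modulation_coefficient(dm.normalized)
    return ForceField(fx=c * gx, fy=c * gy, foreground=dm.foreground)


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample an open polyline to ``n`` points at equal arc length.

    The first and last points are preserved exactly.
    """
    pts = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] == 0:
        return np.repeat(pts[:1], n, axis=0)
    targets = np.linspace(0.0, cum[-1], n)
    out = np.column_stack([np.interp(targets, cum, pts[:, 0]),
                           np.interp(targets, cum, pts[:, 1])])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


class _Confiner:
    """Projects stray snake points back onto the nearest foreground pixel.

    The external force has no reach on flat background, so a curve segment
    that leaves the object (e.g. a spline chord cutting the concave pocket
    under the genu) would otherwise relax only through slow internal tension.
    Projection keeps every point inside the foreground, where the
    distance-map force is defined, without touching the clamped endpoints.
    """

    def __init__(self, fg: np.ndarray):
        self.fg = fg
        _, idx = ndimage.distance_transform_edt(~fg, return_indices=True)
        self.nearest_row, self.nearest_col = idx

    def project(self, points: np.ndarray) -> np.ndarray:
        pts = points.copy()
        h, w = self.fg.shape
        cols = np.clip(np.round(pts[:, 0]).astype(int), 0, w - 1)
        rows = np.clip(np.round(pts[:, 1]).astype(int), 0, h - 1)
        outside = ~self.fg[rows, cols]
        if outside.any():
            r, c = rows[outside], cols[outside]
            pts[outside, 0] = self.nearest_col[r, c]
            pts[outside, 1] = self.nearest_row[r, c]
        return pts


def _ray_control_point(origin: np.ndarray, angle_deg: float, dm: DistanceMap):
    """Foreground pixel of maximal distance value on a rasterised divider ray.

    Ties on the distance value go to the pixel nearest the fan origin (then
    lexicographically by row, column, for full determinism).
    """
    h, w = dm.values.shape
    rad = np.radians(angle_deg)
    direction = np.array([np.cos(rad), -np.sin(rad)])   # y-up angle -> image coords
    t = np.arange(0.0, float(np.hypot(h, w)), 0.05)
    xs = np.round(origin[0] + t * direction[0]).astype(int)
    ys = np.round(origin[1] + t * direction[1]).astype(int)
    inside = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
    xs, ys = xs[inside], ys[inside]
    on_ray = dm.foreground[ys, xs]
    xs, ys = xs[on_ray], ys[on_ray]
    if len(xs) == 0:
        raise CenterlineError("ray misses mask")
    vals = dm.values[ys, xs]
    dist = np.hypot(xs - origin[0], ys - origin[1])
    order = np.lexsort((xs, ys, dist, -vals))
    return np.array([xs[order[0]], ys[order[0]]], dtype=float)


def initialize_snake(mask: BinaryMask, partition: Partition, dm: DistanceMap,
                     anterior, posterior, config: SnakeConfig) -> Centerline:
    """Spline initialisation through the divider-ray maximal-distance points.

    One control point per divider ray (the on-ray foreground pixel with
    maximal distance value, nearest the fan origin on ties); a cubic
    interpolating spline through anterior endpoint, the four control points
    ordered anterior to posterior, and the posterior endpoint is resampled to
    ``n_points`` at equal arc length.
    """
    from scipy.interpolate import CubicSpline

    anterior = np.asarray(anterior, float)
    posterior = np.asarray(posterior, float)
    controls = [_ray_control_point(partition.divider_origin, a, dm)
                for a in sorted(partition.ray_angles_deg, reverse=True)]
    knots = np.vstack([anterior, controls, posterior])
    chord = np.linalg.norm(np.diff(knots, axis=0), axis=1)
    if np.any(chord == 0):
        keep = np.concatenate([[True], chord > 0])
        knots = knots[keep]
        chord = np.linalg.norm(np.diff(knots, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(chord)])
    spline = CubicSpline(u, knots, bc_type="natural")
    dense = spline(np.linspace(0.0, u[-1], 1500))
    pts = resample_polyline(dense, config.n_points)
    pts[0] = anterior
    pts[-1] = posterior
    return Centerline(points=pts, pixel_size_mm=mask.pixel_size_mm)


def _internal_matrix(n: int, config: SnakeConfig) -> np.ndarray:
    """Semi-implicit system matrix with Dirichlet endpoint rows."""
    K = np.zeros((n, n))
    for i in range(1, n - 1):
        K[i, i - 1], K[i, i], K[i, i + 1] = 1.0, -2.0, 1.0
    A = -config.alpha * K + config.beta * (K @ K)
    M = np.eye(n) + config.time_step * A
    M[0, :] = 0.0
    M[0, 0] = 1.0
    M[-1, :] = 0.0
    M[-1, -1] = 1.0
    return M


def evolve_snake(init: Centerline, force: ForceField,
                 config: SnakeConfig) -> SnakeSolution:
    """Evolve the snake to convergence with bit-fixed endpoints.

    Implicit internal / explicit external time stepping; interior points are
    redistributed at equal arc length every ``resample_every`` iterations.
    The external force is applied along the curve normal only: its tangential
    component merely reparametrises the curve (a perpetual slide along the
    distance ridge toward thicker regions) and is superseded by the arc-length
    redistribution, so discarding it leaves the limit geometry unchanged while
    letting the iteration actually reach a fixed point.  Stops when the
    per-iteration maximal point displacement falls below ``tol_px`` or after
    ``max_iter`` iterations.
    """
    x = init.points.astype(float).copy()
    n = len(x)
    if n < 5:
        raise CenterlineError("need at least 5 snake points")
    p_ant = x[0].copy()
    p_post = x[-1].copy()
    lu = linalg.lu_factor(_internal_matrix(n, config))
    dt = config.time_step
    confiner = (_Confiner(force.foreground)
                if force.foreground is not None else None)

    step = np.inf
    it = 0
    converged = False
    for it in range(1, config.max_iter + 1):
        f = force.at(x)
        # keep only the component normal to the curve (central-difference tangent)
        tang = x[2:] - x[:-2]
        norm = np.linalg.norm(tang, axis=1, keepdims=True)
        tang = np.divide(tang, norm, out=np.zeros_like(tang), where=norm > 0)
        f[1:-1] -= np.sum(f[1:-1] * tang, axis=1, keepdims=True) * tang
        f[0] = 0.0
        f[-1] = 0.0
        rhs = x + dt * f
        rhs[0] = p_ant
        rhs[-1] = p_post
        if not np.all(np.isfinite(rhs)):
            raise CenterlineError(f"diverged at iteration {it}")
        x_new = linalg.lu_solve(lu, rhs, check_finite=False)
        if not np.all(np.isfinite(x_new)):
            raise CenterlineError(f"diverged at iteration {it}")
        if confiner is not None:
            x_new[1:-1] = confiner.project(x_new[1:-1])
        x_new[0] = p_ant
        x_new[-1] = p_post
        step = float(np.max(np.linalg.norm(x_new - x, axis=1)))
        x = x_new
        if config.resample_every and it % config.resample_every == 0:
            x = resample_polyline(x, n)
            x[0] = p_ant
            x[-1] = p_post
        if step < config.tol_px:
            converged = True
            break
    cl = Centerline(points=x, pixel_size_mm=init.pixel_size_mm)
    return SnakeSolution(centerline=cl, iterations=it, converged=converged,
                         final_step_px=step)


def extract_centerline(mask: BinaryMask, model: EndpointModel,
                       config: SnakeConfig | None = None,
                       candidate_mode: str = "subregion",
                       full_output: bool = False):
    """Full pipeline: endpoints, distance map, initialisation, evolution.

    Deterministic for fixed inputs and configuration.  Stage errors are
    re-raised with the failing stage's name prefixed.
    """
    config = config or SnakeConfig()

    def stage(name, fn):
        try:
            return fn()
        except Exception as e:
            raise type(e)(f"{name}: {e}") from e

    analysis = stage("analysis", lambda: analyze_mask(mask, model.config))
    anterior = stage("localize anterior", lambda: localize_endpoint(
        mask, model, ANTERIOR, candidate_mode, analysis))
    posterior = stage("localize posterior", lambda: localize_endpoint(
        mask, model, POSTERIOR, candidate_mode, analysis))
    dm = stage("distance map", lambda: distance_map(mask))
    force = stage("external force", lambda: external_force(dm))
    init = stage("initialization", lambda: initialize_snake(
        mask, analysis.partition, dm, anterior, posterior, config))
    sol = stage("evolution", lambda: evolve_snake(init, force, config))
    if full_output:
        return {"centerline": sol.centerline, "solution": sol,
                "anterior": anterior, "posterior": posterior,
                "analysis": analysis, "distance_map": dm, "init": init}
    return sol.centerline
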