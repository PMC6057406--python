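"""Binary-mask geometry for the segmented corpus callosum.

Coordinate convention (used package-wide): images are indexed ``grid[row, col]``;
a point is an ``(x, y)`` pair with ``x`` the column increasing rightward and
``y`` the row increasing downward, both 0-based.  Masks are expected in
canonical anatomical orientation: anterior at low ``x``, superior at low ``y``.
Angles reported in degrees are measured in the "y-up" sense, i.e. a major axis
rising toward the right of the image has a positive orientation.

The module provides boundary tracing, the oriented bounding frame (principal
axes of the second central moments plus the tightest axis-aligned box in that
frame), the radial five-subregion partition of the callosum (rostrum+genu CC1
through splenium CC5, fanned from the midpoint of the inferior rectangle side),
and the anatomical region-selection filter used to pick the callosum among
candidate segmented regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import GeometryError

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=int)

# clockwise-on-screen Moore neighbourhood as (dy, dx), starting east
_MOORE = (
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1),
)


@dataclass(frozen=True, eq=False)
class BinaryMask:
    """A 2D binary raster with isotropic physical pixel size in mm."""

    grid: np.ndarray
    pixel_size_mm: float = 1.0

    def __post_init__(self):
        g = np.asarray(self.grid)
        if g.ndim != 2:
            raise GeometryError("mask grid must be 2D")
        if self.pixel_size_mm <= 0:
            raise GeometryError("pixel size must be positive")
        object.__setattr__(self, "grid", (g != 0).astype(np.uint8))

    @property
    def foreground_count(self) -> int:
        return int(self.grid.sum())

    @property
    def area_mm2(self) -> float:
        return self.foreground_count * self.pixel_size_mm ** 2

    def foreground(self) -> np.ndarray:
        return self.grid.astype(bool)


@dataclass(frozen=True, eq=False)
class Contour:
    """Ordered pixel chain along the object boundary.

    ``points`` is an ``(n, 2)`` integer array of ``(x, y)`` pixels; consecutive
    entries are 8-neighbours and, when ``closed``, so are the first and last.
    """

    points: np.ndarray
    closed: bool = True

    def __post_init__(self):
        object.__setattr__(self, "points",
                           np.asarray(self.points, dtype=np.int64).reshape(-1, 2))

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True, eq=False)
class OrientedFrame:
    """Principal-axis frame and tight bounding rectangle of the foreground."""

    centroid: np.ndarray          # (x, y) subpixel
    major_dir: np.ndarray         # unit vector, image coords, x-component >= 0
    minor_dir: np.ndarray         # unit vector perpendicular to major_dir
    rect_corners: np.ndarray      # (4, 2): (tmin,umin),(tmax,umin),(tmax,umax),(tmin,umax)
    rect_length_mm: float         # extent along major_dir
    rect_height_mm: float         # extent along minor_dir
    orientation_deg: float        # angle of major axis vs horizontal, y-up sense

    def inferior_midpoint(self) -> np.ndarray:
        """Midpoint of the long rectangle side on the inferior (larger-y) side."""
        m0 = 0.5 * (self.rect_corners[0] + self.rect_corners[1])
        m1 = 0.5 * (self.rect_corners[3] + self.rect_corners[2])
        return m0 if m0[1] > m1[1] else m1


@dataclass(frozen=True, eq=False)
class Partition:
    """Radial five-subregion labelling of the callosum (CC1..CC5).

    ``labels`` maps each pixel to 0 (background) or 1..5, anterior to
    posterior.  Angles are degrees about ``divider_origin`` in the y-up sense;
    the four divider rays split the fan between the rays through the
    anterior-most and posterior-most foreground pixels at equal intervals.
    """

    labels: np.ndarray
    divider_origin: np.ndarray
    ray_angles_deg: np.ndarray          # 4 interior rays, ascending
    fan_angles_deg: tuple               # (posterior-most, anterior-most) fan limits
    subregion_centroids: np.ndarray     # (5, 2)
    subregion_major_dirs: np.ndarray    # (5, 2); NaN rows mark degenerate moments

    def label_at(self, point) -> int:
        x, y = point
        r = int(round(float(y)))
        c = int(round(float(x)))
        h, w = self.labels.shape
        if not (0 <= r < h and 0 <= c < w):
            return 0
        return int(self.labels[r, c])


def _single_component(mask: BinaryMask) -> np.ndarray:
    fg = mask.foreground()
    if not fg.any():
        raise GeometryError("empty mask")
    _, n = ndimage.label(fg, structure=_EIGHT)
    if n != 1:
        raise GeometryError("not a single component")
    return fg


def boundary_pixels(mask: BinaryMask) -> np.ndarray:
    """Boolean image of boundary pixels: foreground with a 4-neighbour background."""
    fg = mask.foreground()
    padded = np.pad(fg, 1, constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                & padded[1:-1, :-2] & padded[1:-1, 2:])
    return fg & ~interior


def trace_boundary(mask: BinaryMask) -> Contour:
    """Trace the closed outer boundary of a single-component mask.

    Returns the ordered boundary chain (Moore-neighbour tracing), oriented
    counterclockwise in the y-up sense and starting at the lexicographically
    smallest boundary pixel (row first, then column).
    """
    fg = _single_component(mask)
    rows, cols = np.nonzero(fg)
    h, w = fg.shape

    def is_fg(r, c):
        return 0 <= r < h and 0 <= c < w and fg[r, c]

    r0 = int(rows.min())
    c0 = int(cols[rows == r0].min())
    start = (r0, c0)
    back0 = (r0, c0 - 1)  # west neighbour is background or outside by scan order

    chain = [start]
    cur, back = start, back0
    max_steps = 8 * (mask.foreground_count + 2) + 16
    for _ in range(max_steps):
        dy, dx = back[0] - cur[0], back[1] - cur[1]
        i0 = _MOORE.index((dy, dx))
        nxt = None
        for k in range(1, 9):
            oy, ox = _MOORE[(i0 + k) % 8]
            cand = (cur[0] + oy, cur[1] + ox)
            if is_fg(*cand):
                py, px = _MOORE[(i0 + k - 1) % 8]
                nxt, back = cand, (cur[0] + py, cur[1] + px)
                break
        if nxt is None:           # isolated pixel
            break
        cur = nxt
        if cur == start and back == back0:
            break
        chain.append(cur)
    else:
        raise GeometryError("boundary tracing did not terminate")

    pts = np.array([(c, r) for r, c in chain], dtype=np.int64)
    if len(pts) >= 3:
        x, y = pts[:, 0].astype(float), -pts[:, 1].astype(float)
        area2 = np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
        if area2 < 0:
            pts = np.vstack([pts[:1], pts[1:][::-1]])
    return Contour(points=pts, closed=True)


def oriented_frame(mask: BinaryMask) -> OrientedFrame:
    """Principal-axis bounding frame from second central moments of the pixels."""
    fg = mask.foreground()
    rows, cols = np.nonzero(fg)
    if len(rows) < 3:
        raise GeometryError("degenerate orientation")
    coords = np.column_stack([cols, rows]).astype(float)
    centroid = coords.mean(axis=0)
    d = coords - centroid
    cov = d.T @ d / len(d)
    evals, evecs = np.linalg.eigh(cov)      # ascending
    lam_min, lam_max = float(evals[0]), float(evals[1])
    if lam_min <= 1e-12 * max(lam_max, 1.0):
        raise GeometryError("collinear foreground")
    if (lam_max - lam_min) / lam_max <= 1e-6:
        raise GeometryError("degenerate orientation")
    major = evecs[:, 1].copy()
    if major[0] < 0 or (major[0] == 0 and major[1] > 0):
        major = -major
    minor = np.array([-major[1], major[0]])

    t = coords @ major
    u = coords @ minor
    tmin, tmax = float(t.min()), float(t.max())
    umin, umax = float(u.min()), float(u.max())
    corners = np.array([
        tmin * major + umin * minor,
        tmax * major + umin * minor,
        tmax * major + umax * minor,
        tmin * major + umax * minor,
    ])
    orientation = float(np.degrees(np.arctan2(-major[1], major[0])))
    if orientation <= -90.0:
        orientation += 180.0
    px = mask.pixel_size_mm
    return OrientedFrame(
        centroid=centroid,
        major_dir=major,
        minor_dir=minor,
        rect_corners=corners,
        rect_length_mm=(tmax - tmin) * px,
        rect_height_mm=(umax - umin) * px,
        orientation_deg=orientation,
    )


def _angles_about(origin: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Angle (deg, y-up sense) of each (x, y) coordinate about origin."""
    dx = coords[:, 0] - origin[0]
    dy_up = origin[1] - coords[:, 1]
    return np.degrees(np.arctan2(dy_up, dx))


def partition_cc(mask: BinaryMask, frame: OrientedFrame) -> Partition:
    """Split the callosum into five radial subregions (CC1 anterior .. CC5).

    Four rays from the midpoint of the inferior rectangle side divide, at equal
    angular interval, the fan spanned by the rays through the anterior-most and
    posterior-most foreground pixels (extremes along the major axis).  Pixels
    whose angle falls outside the fan (possible because the fan limits follow
    the major-axis extremes, not the angular extremes) are clamped into the
    first or last sector.
    """
    fg = mask.foreground()
    rows, cols = np.nonzero(fg)
    if len(rows) == 0:
        raise GeometryError("empty mask")
    coords = np.column_stack([cols, rows]).astype(float)
    origin = frame.inferior_midpoint()

    t = coords @ frame.major_dir
    anterior_px = coords[int(np.argmin(t))]
    posterior_px = coords[int(np.argmax(t))]
    theta = _angles_about(origin, coords)
    theta_a = float(_angles_about(origin, anterior_px[None])[0])
    theta_p = float(_angles_about(origin, posterior_px[None])[0])
    # fan measured counterclockwise from the posterior ray; unwrap so the
    # rostrum may dip below the fan origin's horizontal without wrapping
    span = (theta_a - theta_p) % 360.0
    if span <= 1e-9:
        raise GeometryError("empty subregion")
    delta = span / 5.0
    # relative angle in (-(360-span)/2, span + (360-span)/2]; [0, span] = fan
    margin = (360.0 - span) / 2.0
    phi = (theta - theta_p + margin) % 360.0 - margin

    k = np.floor((span - phi) / delta).astype(int)
    k = np.clip(k, 0, 4)
    labels = np.zeros(fg.shape, dtype=np.int8)
    labels[rows, cols] = (k + 1).astype(np.int8)

    centroids = np.zeros((5, 2))
    dirs = np.full((5, 2), np.nan)
    for lab in range(1, 6):
        sel = coords[k == lab - 1]
        if len(sel) == 0:
            raise GeometryError("empty subregion")
        centroids[lab - 1] = sel.mean(axis=0)
        if len(sel) >= 3:
            d = sel - sel.mean(axis=0)
            cov = d.T @ d / len(d)
            evals, evecs = np.linalg.eigh(cov)
            if evals[1] > 0 and (evals[1] - evals[0]) / evals[1] > 1e-6:
                v = evecs[:, 1]
                if v @ frame.major_dir < 0:
                    v = -v
                dirs[lab - 1] = v

    rays = np.array([theta_p + delta * i for i in (1, 2, 3, 4)])
    return Partition(
        labels=labels,
        divider_origin=origin,
        ray_angles_deg=rays,
        fan_angles_deg=(theta_p, theta_p + span),
        subregion_centroids=centroids,
        subregion_major_dirs=dirs,
    )


def select_cc_region(regions) -> int:
    """Pick the callosum among candidate ``(BinaryMask, OrientedFrame)`` regions.

    A candidate qualifies when its oriented rectangle satisfies all of:
    length 7–9 cm, width 2–4 cm, |orientation| 5–40 degrees, area > 2 cm².
    Among qualifiers the largest-area one wins (first on ties).
    """
    if not regions:
        raise GeometryError("no CC candidate")
    best, best_area = None, -1.0
    for i, (mask, frame) in enumerate(regions):
        length_cm = frame.rect_length_mm / 10.0
        width_cm = frame.rect_height_mm / 10.0
        area_cm2 = mask.area_mm2 / 100.0
        ok = (7.0 <= length_cm <= 9.0
              and 2.0 <= width_cm <= 4.0
              and 5.0 <= abs(frame.orientation_deg) <= 40.0
              and area_cm2 > 2.0)
        if ok and area_cm2 > best_area:
            best, best_area = i, area_cm2
    if best is None:
        raise GeometryError("no CC candidate")
    return best
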