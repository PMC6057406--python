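"""Synthetic corpus-callosum masks with known centerline ground truth.

Clinical mid-sagittal segmentations are not distributable, so the test and
acceptance suites run on generated look-alikes: an arched backbone with an
anterior hook (rostrum/genu), a thinner mid-body and isthmus and a bulbous
splenium, swept with an arc-length thickness profile and rasterised as a
union of disks.  Smooth low-frequency radial noise emulates segmentation
irregularity without breaking the single-component topology.  The backbone is
recorded before noise, so every sample carries its true centerline and true
endpoints (backbone tips projected onto the noisy mask boundary).

Samples are drawn at the anatomical conditions of the clinical selection
filter (length 7-9 cm, width 2-4 cm, orientation 5-40 degrees, area > 2 cm2,
at a canonical tilt of ~22.5 degrees); a draw failing the filter or the
topology check is rejected and redrawn, mirroring how the clinical pipeline
selected callosum candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator

from .centerline import Centerline
from .errors import SyntheticError
from .geometry import (BinaryMask, boundary_pixels, oriented_frame,
                       select_cc_region, trace_boundary)

# Canonical backbone control points (mm, y-up, anterior at low x) including the
# ~22.5 degree anatomical tilt applied at build time.
DEFAULT_BACKBONE_MM = np.array([
    (13.5, 1.0),    # rostrum tip (s = 0)
    (4.8, 4.0),     # rostrum underside
    (2.9, 14.0),    # genu anterior
    (15.4, 24.0),   # anterior body rise
    (36.5, 29.0),   # body apex
    (55.8, 25.5),   # posterior body
    (71.2, 14.0),   # isthmus -> splenium
    (77.9, 1.0),    # splenium posterior-inferior pole (s = 1)
])

BASE_TILT_DEG = 22.5

# (normalised arc length, half-width in mm): genu and splenium are thick,
# the isthmus thin, tapering to zero exactly at both tips.
_THICKNESS_KNOTS = np.array([
    (0.0, 0.0), (0.15, 5.0), (0.5, 3.0),
    (0.75, 2.0), (0.95, 5.5), (1.0, 0.0),
])

_N_BACKBONE = 600
_N_NOISE_HARMONICS = 8
_JITTER_MM = 1.0
_MAX_ATTEMPTS = 12


def default_thickness_profile(s):
    """Half-width (mm) as a shape-preserving interpolant of the knot table."""
    interp = PchipInterpolator(_THICKNESS_KNOTS[:, 0], _THICKNESS_KNOTS[:, 1])
    return np.maximum(interp(np.clip(s, 0.0, 1.0)), 0.0)


@dataclass(frozen=True, eq=False)
class SyntheticSpec:
    """Generation parameters; ``None`` for rotation/scale means draw per sample
    (uniform in [-20, 20] degrees and [0.9, 1.1] respectively)."""

    backbone_template: np.ndarray = field(
        default_factory=lambda: DEFAULT_BACKBONE_MM.copy())
    thickness_profile: object = None        # callable s -> half-width (mm)
    boundary_noise_sigma_px: float = 0.5
    rotation_deg: float | None = None
    scale: float | None = None
    pixel_size_mm: float = 1.0
    grid_shape: tuple = (128, 160)
    seed: int = 0

    def profile(self):
        return self.thickness_profile or default_thickness_profile


@dataclass(frozen=True, eq=False)
class SyntheticSample:
    mask: BinaryMask
    true_centerline: Centerline
    true_anterior: np.ndarray
    true_posterior: np.ndarray
    spec: SyntheticSpec
    rotation_deg: float = 0.0
    scale: float = 1.0
    backbone_px: np.ndarray = None    # dense swept-disk centres (pixel coords)
    radii_px: np.ndarray = None       # per-centre disk radii actually rasterised


def _rotate(points: np.ndarray, deg: float) -> np.ndarray:
    """Rotate y-up points counterclockwise by ``deg``."""
    rad = np.radians(deg)
    c, s = np.cos(rad), np.sin(rad)
    return points @ np.array([[c, s], [-s, c]])


def _backbone_from_controls(controls: np.ndarray, n: int) -> np.ndarray:
    chord = np.linalg.norm(np.diff(controls, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(chord)])
    spline = CubicSpline(u, controls, bc_type="natural")
    dense = spline(np.linspace(0.0, u[-1], 6 * n))
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, cum[-1], n)
    return np.column_stack([np.interp(targets, cum, dense[:, 0]),
                            np.interp(targets, cum, dense[:, 1])])


def _smooth_noise(s: np.ndarray, sigma: float, rng) -> np.ndarray:
    """Zero-mean Fourier-smooth noise along arc length, RMS about ``sigma``."""
    coeffs = rng.normal(0.0, sigma / np.sqrt(_N_NOISE_HARMONICS),
                        (_N_NOISE_HARMONICS, 2))
    out = np.zeros_like(s)
    for k, (a, b) in enumerate(coeffs, start=1):
        out += a * np.cos(2 * np.pi * k * s) + b * np.sin(2 * np.pi * k * s)
    return out


def rasterize_swept_disks(backbone_px: np.ndarray, radii_px: np.ndarray,
                          grid_shape) -> np.ndarray:
    """Union-of-disks rasterisation: pixel centres within some sweep disk."""
    h, w = grid_shape
    grid = np.zeros((h, w), dtype=bool)
    for (x, y), r in zip(backbone_px, radii_px):
        if r <= 0:
            continue
        x0 = max(int(np.ceil(x - r)), 0)
        x1 = min(int(np.floor(x + r)), w - 1)
        y0 = max(int(np.ceil(y - r)), 0)
        y1 = min(int(np.floor(y + r)), h - 1)
        if x0 > x1 or y0 > y1:
            continue
        xs = np.arange(x0, x1 + 1)
        ys = np.arange(y0, y1 + 1)
        grid[y0:y1 + 1, x0:x1 + 1] |= \
            (xs - x)[None, :] ** 2 + (ys - y)[:, None] ** 2 <= r * r
    return grid


def _passes_filter(mask: BinaryMask) -> bool:
    from scipy import ndimage
    fg = mask.foreground()
    if not fg.any():
        return False
    _, n = ndimage.label(fg, structure=np.ones((3, 3), int))
    if n != 1:
        return False
    try:
        frame = oriented_frame(mask)
        select_cc_region([(mask, frame)])
    except Exception:
        return False
    return True


def generate_cc(spec: SyntheticSpec) -> SyntheticSample:
    """Generate one synthetic callosum mask with ground truth, deterministically."""
    rng = np.random.default_rng(spec.seed)
    profile = spec.profile()
    h, w = spec.grid_shape
    px = spec.pixel_size_mm

    for _ in range(_MAX_ATTEMPTS):
        rotation = (spec.rotation_deg if spec.rotation_deg is not None
                    else float(rng.uniform(-20.0, 20.0)))
        scale = (spec.scale if spec.scale is not None
                 else float(rng.uniform(0.9, 1.1)))
        jitter = rng.normal(0.0, _JITTER_MM, spec.backbone_template.shape)
        controls = (spec.backbone_template + jitter) * scale
        controls = _rotate(controls, BASE_TILT_DEG + rotation)

        backbone_mm = _backbone_from_controls(controls, _N_BACKBONE)
        s = np.linspace(0.0, 1.0, _N_BACKBONE)
        widths_mm = np.asarray(profile(s), float) * scale

        # to image pixel coordinates (y flips down), centred on the grid
        bb_px = backbone_mm / px
        wd_px = widths_mm / px
        xy = np.column_stack([bb_px[:, 0], -bb_px[:, 1]])
        lo = (xy - wd_px[:, None]).min(axis=0)
        hi = (xy + wd_px[:, None]).max(axis=0)
        center_shift = np.array([w, h]) / 2.0 - (lo + hi) / 2.0
        xy = xy + center_shift
        if np.any((xy - wd_px[:, None]).min(axis=0) < 1) or \
           np.any((xy + wd_px[:, None]).max(axis=0) > np.array([w, h]) - 2):
            continue

        noise = _smooth_noise(s, spec.boundary_noise_sigma_px, rng)
        envelope = np.clip(wd_px / 2.0, 0.0, 1.0)
        noisy_w = np.maximum(wd_px + envelope * noise, 0.0)

        grid = rasterize_swept_disks(xy, noisy_w, (h, w))
        mask = BinaryMask(grid=grid.astype(np.uint8), pixel_size_mm=px)
        if not _passes_filter(mask):
            continue

        bpix = np.argwhere(boundary_pixels(mask))          # (row, col)
        bxy = np.column_stack([bpix[:, 1], bpix[:, 0]]).astype(float)

        def project(p):
            return bxy[int(np.argmin(np.linalg.norm(bxy - p, axis=1)))]

        true_a = project(xy[0])
        true_p = project(xy[-1])
        inside = grid[np.clip(np.round(xy[:, 1]).astype(int), 0, h - 1),
                      np.clip(np.round(xy[:, 0]).astype(int), 0, w - 1)]
        interior = xy[inside]
        truth_pts = np.vstack([true_a, interior, true_p])
        truth = Centerline(points=truth_pts, pixel_size_mm=px)
        return SyntheticSample(mask=mask, true_centerline=truth,
                               true_anterior=true_a, true_posterior=true_p,
                               spec=spec, rotation_deg=rotation, scale=scale,
                               backbone_px=xy, radii_px=noisy_w)
    raise SyntheticError(
        f"could not generate a valid mask for seed {spec.seed} "
        f"after {_MAX_ATTEMPTS} attempts")


def generate_dataset(n: int, base_seed: int, outdir=None,
                     spec: SyntheticSpec | None = None):
    """Generate ``n`` samples with seeds ``base_seed .. base_seed + n - 1``.

    With ``outdir`` set, writes ``mask_###.png`` (+ pixel-size sidecar JSON),
    a ``labels.csv`` consumable by model training, and per-sample ground-truth
    centerline CSVs.
    """
    if n < 1:
        raise SyntheticError("need n >= 1")
    base = spec or SyntheticSpec()
    samples = [generate_cc(replace_seed(base, base_seed + i)) for i in range(n)]
    if outdir is not None:
        from . import io as ccio
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, smp in enumerate(samples):
            name = f"mask_{i:03d}.png"
            ccio.write_mask(smp.mask, outdir / name)
            ccio.write_centerline_csv(smp.true_centerline,
                                      outdir / f"truth_{i:03d}.csv")
            rows.append((name, *smp.true_anterior, *smp.true_posterior))
        ccio.write_labels_csv(rows, outdir / "labels.csv")
    return samples


def replace_seed(spec: SyntheticSpec, seed: int) -> SyntheticSpec:
    return replace(spec, seed=seed)
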