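"""Log-polar shape-context descriptors and statistical endpoint localization.

The anterior and posterior endpoints of the callosal centerline are detected by
matching a *statistical shape context* model against candidate boundary
points.  The shape context of a boundary point is a coarse log-polar histogram
of where the other (uniformly resampled) boundary points lie relative to it;
radii are normalised by the height of the callosum's oriented bounding
rectangle (scale invariance) and angles are measured from a local reference
direction — the principal axis of the rostrum+genu (CC1) or splenium (CC5)
subregion — which makes the descriptor tolerant to in-plane rotation up to
about one angular bin (360/15 = 24 degrees with the default binning).

The statistical model is simply the elementwise mean histogram over a labelled
training set; localization returns the candidate minimising the L1 distance
between its histogram and the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeContextError
from .geometry import (BinaryMask, Contour, OrientedFrame, Partition,
                       oriented_frame, partition_cc, trace_boundary)

logger = logging.getLogger(__name__)

ANTERIOR = "anterior"
POSTERIOR = "posterior"
_END_LABEL = {ANTERIOR: 1, POSTERIOR: 5}


@dataclass(frozen=True)
class LogPolarConfig:
    """Binning of the log-polar histogram.

    Radii are expressed as fractions of the callosum bounding-rectangle height;
    the log-radial bin edges run geometrically from ``r_min_norm`` to
    ``r_max_norm`` with under/overflow clamped into the extreme bins so every
    histogram sums to one.
    """

    n_angular: int = 15
    n_radial: int = 10
    r_min_norm: float = 1.0 / 16.0
    r_max_norm: float = 2.0
    contour_samples: int = 200

    def __post_init__(self):
        if self.n_angular < 2 or self.n_radial < 2:
            raise ShapeContextError("need at least 2 bins per axis")
        if not (0 < self.r_min_norm < self.r_max_norm):
            raise ShapeContextError("invalid radial range")
        if self.contour_samples < 2:
            raise ShapeContextError("need at least 2 contour samples")

    @property
    def angular_bin_deg(self) -> float:
        return 360.0 / self.n_angular

    def radial_edges(self) -> np.ndarray:
        return np.geomspace(self.r_min_norm, self.r_max_norm, self.n_radial + 1)

    def to_dict(self) -> dict:
        return {
            "n_angular": self.n_angular,
            "n_radial": self.n_radial,
            "r_min_norm": self.r_min_norm,
            "r_max_norm": self.r_max_norm,
            "contour_samples": self.contour_samples,
        }


@dataclass(frozen=True, eq=False)
class ShapeContextHist:
    """Normalized log-polar histogram, ``bins[angular, radial]``."""

    bins: np.ndarray
    config: LogPolarConfig

    def l1(self, other: "ShapeContextHist") -> float:
        return float(np.abs(self.bins - other.bins).sum())


@dataclass(frozen=True, eq=False)
class LocalFrame:
    """Local reference frame attached to the CC1 or CC5 subregion."""

    end: str
    reference_dir: np.ndarray   # unit vector, image coords, anterior->posterior
    norm_height_mm: float       # whole-CC bounding-rectangle height


@dataclass(frozen=True, eq=False)
class EndpointModel:
    """Pair of mean shape-context histograms for the two centerline endpoints."""

    anterior_hist: ShapeContextHist
    posterior_hist: ShapeContextHist
    n_training: int
    config: LogPolarConfig
    format_version: str = "1"

    def hist(self, end: str) -> ShapeContextHist:
        if end == ANTERIOR:
            return self.anterior_hist
        if end == POSTERIOR:
            return self.posterior_hist
        raise ShapeContextError(f"unknown end {end!r}")


def resample_contour(contour: Contour, n: int) -> np.ndarray:
    """Resample a closed contour to ``n`` points at uniform arc length.

    The first sample coincides with the contour's start point; samples are
    subpixel points on the closed polyline through the boundary pixels.
    """
    pts = contour.points.astype(float)
    if len(pts) == 1:
        return np.repeat(pts, n, axis=0)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    targets = np.arange(n) * total / n
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    return np.column_stack([x, y])


def local_frame(partition: Partition, frame: OrientedFrame, end: str) -> LocalFrame:
    """Reference frame of the CC1 (anterior) or CC5 (posterior) subregion.

    The reference direction is the subregion's principal axis, sign-fixed to
    point anterior-to-posterior (positive component along the whole-CC major
    axis).  Degenerate subregion moments fall back to the whole-CC major axis.
    """
    if end not in _END_LABEL:
        raise ShapeContextError(f"unknown end {end!r}")
    idx = _END_LABEL[end] - 1
    ref = partition.subregion_major_dirs[idx]
    if np.any(np.isnan(ref)):
        logger.warning("degenerate %s subregion moments; falling back to "
                       "whole-CC major axis", end)
        ref = frame.major_dir
    ref = np.asarray(ref, float)
    if ref @ frame.major_dir < 0:
        ref = -ref
    return LocalFrame(end=end, reference_dir=ref / np.linalg.norm(ref),
                      norm_height_mm=frame.rect_height_mm)


def compute_shape_context(p, points, frame: LocalFrame, config: LogPolarConfig,
                          pixel_size_mm: float = 1.0) -> ShapeContextHist:
    """Shape context of point ``p`` relative to the resampled contour ``points``.

    ``points`` is the ``(n, 2)`` uniformly resampled contour (``p`` may be one
    of them; coincident points are excluded).  Radii are in units of the
    normalisation height; angles are measured counterclockwise (y-up sense)
    from the local reference direction.
    """
    pts = np.asarray(points, float).reshape(-1, 2)
    if len(pts) < 2:
        raise ShapeContextError("insufficient contour")
    p = np.asarray(p, float)
    d = pts - p
    d = d[(d[:, 0] != 0) | (d[:, 1] != 0)]
    if len(d) == 0:
        raise ShapeContextError("insufficient contour")

    r = np.hypot(d[:, 0], d[:, 1]) * pixel_size_mm / frame.norm_height_mm
    dxu, dyu = d[:, 0], -d[:, 1]
    rxu, ryu = float(frame.reference_dir[0]), -float(frame.reference_dir[1])
    theta = np.degrees(np.arctan2(rxu * dyu - ryu * dxu,
                                  rxu * dxu + ryu * dyu)) % 360.0
    ang = np.floor(theta / config.angular_bin_deg).astype(int) % config.n_angular
    rad = np.clip(np.searchsorted(config.radial_edges(), r, side="right") - 1,
                  0, config.n_radial - 1)
    bins = np.zeros((config.n_angular, config.n_radial))
    np.add.at(bins, (ang, rad), 1.0)
    return ShapeContextHist(bins=bins / len(d), config=config)


@dataclass(frozen=True, eq=False)
class MaskAnalysis:
    """Cached per-mask geometry shared by training and localization."""

    mask: BinaryMask
    contour: Contour
    frame: OrientedFrame
    partition: Partition
    samples: np.ndarray          # (contour_samples, 2) resampled boundary
    sample_labels: np.ndarray    # subregion label of each sample's pixel
    frames: dict                 # end -> LocalFrame
    config: LogPolarConfig


def analyze_mask(mask: BinaryMask, config: LogPolarConfig) -> MaskAnalysis:
    contour = trace_boundary(mask)
    frame = oriented_frame(mask)
    partition = partition_cc(mask, frame)
    samples = resample_contour(contour, config.contour_samples)
    labels = np.array([partition.label_at(s) for s in samples], dtype=np.int8)
    frames = {end: local_frame(partition, frame, end) for end in _END_LABEL}
    return MaskAnalysis(mask=mask, contour=contour, frame=frame,
                        partition=partition, samples=samples,
                        sample_labels=labels, frames=frames, config=config)


def _snap_to_boundary(point, analysis: MaskAnalysis) -> np.ndarray:
    """Labelled endpoint snapped to the nearest traced boundary pixel."""
    point = np.asarray(point, float)
    d = np.linalg.norm(analysis.contour.points - point, axis=1)
    if d.min() > 2.0:
        raise ShapeContextError("endpoint not on boundary")
    return analysis.contour.points[int(np.argmin(d))].astype(float)


def build_model(samples, config: LogPolarConfig | None = None) -> EndpointModel:
    """Mean shape-context model from labelled training masks.

    ``samples`` is a sequence of ``(mask, anterior_point, posterior_point)``
    with the labelled endpoints on (within 2 px of) each mask's boundary.  The
    model histograms are the elementwise means over the training set.
    """
    config = config or LogPolarConfig()
    samples = list(samples)
    if not samples:
        raise ShapeContextError("need at least one training sample")
    sums = {ANTERIOR: None, POSTERIOR: None}
    for mask, a_pt, p_pt in samples:
        analysis = analyze_mask(mask, config)
        for end, pt in ((ANTERIOR, a_pt), (POSTERIOR, p_pt)):
            snapped = _snap_to_boundary(pt, analysis)
            h = compute_shape_context(snapped, analysis.samples,
                                      analysis.frames[end], config,
                                      mask.pixel_size_mm)
            sums[end] = h.bins if sums[end] is None else sums[end] + h.bins
    k = len(samples)
    return EndpointModel(
        anterior_hist=ShapeContextHist(bins=sums[ANTERIOR] / k, config=config),
        posterior_hist=ShapeContextHist(bins=sums[POSTERIOR] / k, config=config),
        n_training=k,
        config=config,
    )


def localize_endpoint(mask: BinaryMask, model: EndpointModel, end: str,
                      candidate_mode: str = "subregion",
                      analysis: MaskAnalysis | None = None) -> np.ndarray:
    """Locate one centerline endpoint by L1 histogram matching.

    Candidates are the resampled boundary points lying in the CC1 (anterior)
    or CC5 (posterior) subregion (``candidate_mode="all"`` lifts the
    restriction).  Returns the candidate whose shape context has minimal sum
    of absolute bin differences to the model; ties go to the candidate
    earliest in contour order.
    """
    if analysis is None:
        analysis = analyze_mask(mask, model.config)
    elif analysis.config != model.config:
        raise ShapeContextError("analysis/model config mismatch")
    if candidate_mode == "subregion":
        cand = np.nonzero(analysis.sample_labels == _END_LABEL[end])[0]
    elif candidate_mode == "all":
        cand = np.nonzero(analysis.sample_labels > 0)[0]
    else:
        raise ShapeContextError(f"unknown candidate mode {candidate_mode!r}")
    if len(cand) == 0:
        raise ShapeContextError("no candidates")
    target = model.hist(end)
    costs = np.empty(len(cand))
    for i, j in enumerate(cand):
        h = compute_shape_context(analysis.samples[j], analysis.samples,
                                  analysis.frames[end], model.config,
                                  analysis.mask.pixel_size_mm)
        costs[i] = target.l1(h)
    return analysis.samples[cand[int(np.argmin(costs))]].copy()
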