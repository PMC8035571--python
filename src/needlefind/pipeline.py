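"""Per-slice needle detection: successive multi-needle extraction and
intensity-profile tip localisation.

Multiple needles are pulled out of one candidate point set by successive
deletion: the needle count per slice is a known input, the expected inlier
count per needle is

    nen = floor(N0 * (1 - eps_noise) / n_needles),

and before every round the outlier ratio is recomputed from the points that
remain, eps_j = (Nj - nen) / Nj.  After an accepted detection its inliers
are deleted and the next round runs on the remainder; rounds stop early when
a model's support falls below ``accept_frac * nen``.

The needle tip is the distal end of the bright plateau in the intensity
profile sampled along the fitted axis: samples above a threshold T (trained
from needle/background intensity samples, or fixed) form runs, short runs
are discarded as noise, and the last surviving run's far end is the tip.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy import ndimage

from .geometry import LineModel, Point2D, PointSet
from .preprocess import ContrastParams, Roi, SliceImage, enhance_contrast, \
    roi_from_contour, threshold_candidates
from .ransac import RansacConfig, RansacResult, detect_single_needle

__all__ = [
    "MultiNeedleConfig",
    "NeedleDetection",
    "IntensityProfile",
    "TipResult",
    "expected_inliers_per_needle",
    "current_outlier_ratio",
    "extract_profile",
    "train_tip_threshold",
    "localize_tip",
    "detect_needles",
]


@dataclass(frozen=True)
class MultiNeedleConfig:
    """Per-slice detection settings.

    n_needles      -- implanted needle count on this slice (a known input)
    eps_noise      -- fraction of candidate points that are noise, not any
                      needle; 0.15 by default (empirical operating point)
    tip_threshold  -- fixed profile threshold T in [0, 1]; None = use the
                      candidate threshold alpha (or train one explicitly via
                      train_tip_threshold and pass it here)
    accept_frac    -- a round's model is accepted iff support >= accept_frac * nen
    min_run        -- minimum consecutive supra-threshold samples for a
                      plateau (rejects isolated bright artifact pixels)
    insertion_edge -- 'top' | 'bottom' | 'left' | 'right' | 'auto'; which ROI
                      side the needles enter from ('auto' picks the profile
                      end whose bright run starts nearer)
    """

    n_needles: int = 1
    eps_noise: float = 0.15
    tip_threshold: float | None = None
    accept_frac: float = 0.5
    min_run: int = 3
    insertion_edge: str = "auto"

    def __post_init__(self) -> None:
        if self.n_needles < 1:
            raise ValueError("n_needles must be >= 1")
        if not 0.0 <= self.eps_noise < 1.0:
            raise ValueError("eps_noise must be in [0, 1)")
        if not 0.0 < self.accept_frac <= 1.0:
            raise ValueError("accept_frac must be in (0, 1]")
        if self.insertion_edge not in ("top", "bottom", "left", "right", "auto"):
            raise ValueError("invalid insertion_edge")


@dataclass
class IntensityProfile:
    """Intensity sampled along an axis: arc length t (mm) vs intensity."""

    t: np.ndarray
    intensity: np.ndarray
    origin: Point2D
    direction: tuple[float, float]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.intensity.shape:
            raise ValueError("t and intensity must be matching 1D arrays")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")

    def point_at(self, t: float) -> Point2D:
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        p = o + t * d
        return Point2D(float(p[0]), float(p[1]))

    def flipped(self) -> "IntensityProfile":
        t_max = self.t[-1]
        d = np.asarray(self.direction, dtype=float)
        return IntensityProfile((t_max - self.t)[::-1].copy(),
                                self.intensity[::-1].copy(),
                                self.point_at(t_max), tuple(-d))


@dataclass
class TipResult:
    t_tip: float
    index: int
    at_profile_end: bool  # needle exits the ROI through the far side


@dataclass
class NeedleDetection:
    """One detected needle: fitted axis, endpoints, inliers, diagnostics."""

    axis: LineModel
    tip: Point2D
    entry: Point2D
    inlier_indices: np.ndarray
    order: int
    sigma: float
    tip_at_roi_edge: bool = False
    tip_from_profile: bool = True

    @property
    def support(self) -> int:
        return int(len(self.inlier_indices))


def expected_inliers_per_needle(N0: int, eps_noise: float, n_needles: int) -> int:
    """floor(N0 * (1 - eps_noise) / n_needles): expected inliers per needle."""
    if n_needles < 1:
        raise ValueError("n_needles must be >= 1")
    if not 0.0 <= eps_noise < 1.0:
        raise ValueError("eps_noise must be in [0, 1)")
    return int(math.floor(N0 * (1.0 - eps_noise) / n_needles))


def current_outlier_ratio(Nj: int, nen: int) -> float:
    """(Nj - nen) / Nj: outlier ratio for the next round, given Nj points.

    Late-stage depletion (nen > Nj) clamps to 0 with a warning rather than
    producing a negative ratio.
    """
    if Nj <= 0:
        raise ValueError("Nj must be positive")
    if nen > Nj:
        warnings.warn("expected inlier count exceeds remaining points; "
                      "clamping outlier ratio to 0")
        return 0.0
    return (Nj - nen) / Nj


# ---------------------------------------------------------------------------
# Tip localisation
# ---------------------------------------------------------------------------

def _clip_line_to_rect(axis: LineModel, bounds) -> tuple[float, float] | None:
    """Liang-Barsky clip of the axis to an (x0, y0, x1, y1) mm rectangle;
    returns the arc-length interval (t0, t1) or None if the axis misses."""
    x0, y0, x1, y1 = bounds
    a = np.asarray(axis.anchor, dtype=float)
    d = np.asarray(axis.direction, dtype=float)
    t_lo, t_hi = -np.inf, np.inf
    for p, q in ((-d[0], a[0] - x0), (d[0], x1 - a[0]),
                 (-d[1], a[1] - y0), (d[1], y1 - a[1])):
        if abs(p) < 1e-15:
            if q < 0:
                return None
            continue
        r = q / p
        if p < 0:
            t_lo = max(t_lo, r)
        else:
            t_hi = min(t_hi, r)
    if t_lo >= t_hi:
        return None
    return float(t_lo), float(t_hi)


def extract_profile(image: SliceImage, axis: LineModel, roi: Roi,
                    insertion_edge: str = "auto",
                    step_mm: float | None = None) -> IntensityProfile:
    """Sample the image intensity along the axis across the ROI.

    Sub-pixel sampling with bilinear interpolation; the step defaults to
    half the smaller pixel spacing.  For a named insertion edge the profile
    starts at the axis endpoint nearest that edge; with 'auto' the
    orientation is the sign-normalised axis direction and callers orient it
    against the threshold afterwards.
    """
    sy, sx = image.pixel_spacing
    span = _clip_line_to_rect(axis, roi.bounds_mm(image.pixel_spacing))
    if span is None:
        raise ValueError("axis does not intersect the ROI")
    t0, t1 = span
    if step_mm is None:
        step_mm = 0.5 * min(sy, sx)
    n = max(2, int(math.floor((t1 - t0) / step_mm)) + 1)
    ts = t0 + np.arange(n) * step_mm
    pts = axis.point_at(ts)
    vals = ndimage.map_coordinates(image.raster,
                                   [pts[:, 1] / sy, pts[:, 0] / sx],
                                   order=1, mode="nearest")
    prof = IntensityProfile(ts - t0, vals, axis.point_at(t0), axis.direction)
    if insertion_edge != "auto":
        start, end = pts[0], pts[-1]
        xlo, ylo, xhi, yhi = roi.bounds_mm(image.pixel_spacing)
        key = {"top": (1, ylo), "bottom": (1, yhi),
               "left": (0, xlo), "right": (0, xhi)}[insertion_edge]
        ax_i, edge_val = key
        if abs(end[ax_i] - edge_val) < abs(start[ax_i] - edge_val):
            prof = prof.flipped()
    return prof


def train_tip_threshold(needle_samples, background_samples) -> float:
    """Threshold T where needle and background intensity densities cross.

    Both classes are modelled as Gaussians fitted by moments; T is the
    density-crossing point between the two means (for equal variances, their
    midpoint).  Zero-variance degenerate samples fall back to the midpoint;
    inverted means (needle not brighter than background) raise, signalling
    bad training data.
    """
    ne = np.asarray(needle_samples, dtype=float)
    bg = np.asarray(background_samples, dtype=float)
    if ne.size == 0 or bg.size == 0:
        raise ValueError("both sample sets must be nonempty")
    mu_n, mu_b = float(ne.mean()), float(bg.mean())
    if mu_n <= mu_b:
        raise ValueError("needle samples must be brighter than background")
    sd_n, sd_b = float(ne.std()), float(bg.std())
    mid = 0.5 * (mu_n + mu_b)
    if sd_n < 1e-9 or sd_b < 1e-9:
        return mid
    if abs(sd_n - sd_b) < 1e-12:
        return mid
    # Equate Gaussian log-densities: quadratic in T.
    a = 1.0 / sd_b**2 - 1.0 / sd_n**2
    b = 2.0 * (mu_n / sd_n**2 - mu_b / sd_b**2)
    c = mu_b**2 / sd_b**2 - mu_n**2 / sd_n**2 + 2.0 * math.log(sd_b / sd_n)
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return mid
    roots = [(-b + s * math.sqrt(disc)) / (2.0 * a) for s in (+1.0, -1.0)]
    between = [r for r in roots if mu_b <= r <= mu_n]
    return float(between[0]) if between else mid


def localize_tip(profile: IntensityProfile, T: float,
                 min_run: int = 3) -> TipResult:
    """Distal end of the last supra-threshold plateau along the profile.

    The profile must be oriented from the entry side.  Runs of consecutive
    samples with intensity >= T shorter than ``min_run`` are ignored as
    isolated bright noise.  If every sample is above T, the needle exits the
    ROI: the profile end is returned and flagged.
    """
    if len(profile.t) == 0:
        raise ValueError("empty profile")
    above = profile.intensity >= T
    runs = _runs(above, min_run)
    if not runs:
        raise ValueError("needle not present on axis (no sample above T)")
    start, end = runs[-1]
    t_tip = float(profile.t[end])
    at_end = end == len(profile.t) - 1
    if not at_end:
        # Sub-sample refinement: interpolate the T-crossing on the trailing
        # edge to remove the sampling-step quantisation of the tip.
        i0, i1 = profile.intensity[end], profile.intensity[end + 1]
        if i0 > i1:
            frac = (i0 - T) / (i0 - i1)
            t_tip += float(np.clip(frac, 0.0, 1.0)) * float(profile.t[end + 1] - profile.t[end])
    return TipResult(t_tip, int(end), at_profile_end=at_end)


def _runs(mask: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    """Maximal True runs of length >= min_run as (first, last) index pairs."""
    out = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for s, e in zip(starts, ends):
        if idx[e] - idx[s] + 1 >= min_run:
            out.append((int(idx[s]), int(idx[e])))
    return out


def _orient_for_entry(profile: IntensityProfile, T: float,
                      min_run: int) -> IntensityProfile:
    """Flip the profile so the bright run begins nearer the start (entry)."""
    above = profile.intensity >= T
    runs = _runs(above, min_run)
    if not runs:
        return profile
    lead = runs[0][0]
    trail = (len(profile.t) - 1) - runs[-1][1]
    return profile if lead <= trail else profile.flipped()


# ---------------------------------------------------------------------------
# Multi-needle orchestration
# ---------------------------------------------------------------------------

def detect_needles(image: SliceImage, cfg: RansacConfig,
                   mcfg: MultiNeedleConfig,
                   contrast: ContrastParams | None = None,
                   alpha: float = 0.85,
                   margin_mm: float = 3.0) -> list[NeedleDetection]:
    """Detect up to n_needles needles in one slice by successive deletion.

    Preprocess (ROI from the contour if present, contrast enhancement,
    thresholding at ``alpha``), then per round: recompute the outlier ratio
    from the remaining candidate count, run the pretest + locally optimised
    estimator, accept the model if its support reaches accept_frac * nen,
    localise the tip along the axis, and delete the accepted inliers.
    Fewer detections than needles is a valid outcome (missed needles).
    """
    enhanced = enhance_contrast(image, contrast)
    roi = (roi_from_contour(enhanced, margin_mm) if enhanced.contour is not None
           else Roi(0, 0, *enhanced.shape))
    cands = threshold_candidates(enhanced, alpha, roi)
    N0 = len(cands)
    if N0 == 0:
        return []
    T = (mcfg.tip_threshold if mcfg.tip_threshold is not None
         else _slice_tip_threshold(enhanced, roi, cands, alpha))
    nen = expected_inliers_per_needle(N0, mcfg.eps_noise, mcfg.n_needles)
    rng = np.random.default_rng(cfg.rng_seed)

    detections: list[NeedleDetection] = []
    remaining = np.arange(N0)
    for j in range(mcfg.n_needles):
        Nj = len(remaining)
        if Nj < max(cfg.pretest_size, 2 * cfg.min_sample):
            break
        eps_j = current_outlier_ratio(Nj, nen)
        # Raster candidates quantise residuals to the pixel grid: a diagonal
        # of pixel centres is exactly collinear and parallel grid rows of the
        # same shaft sit up to one pixel diagonal apart.  Floor the robust
        # scale so the gate spans adjacent grid rows instead of snapping to a
        # single zero-residual row.
        sigma_floor = max(cfg.min_sigma_mm,
                          0.6 * math.hypot(*image.pixel_spacing) / cfg.inlier_gate_z)
        cfg_j = dc_replace(cfg, outlier_ratio=eps_j, min_sigma_mm=sigma_floor)
        try:
            res = detect_single_needle(cands.subset(remaining), cfg_j, rng=rng)
        except ValueError:
            break
        if res.support < mcfg.accept_frac * nen:
            break  # no remaining subset satisfies the model conditions
        det = _assemble_detection(enhanced, roi, res, mcfg, T,
                                  cands, remaining, order=j)
        detections.append(det)
        keep = np.ones(Nj, dtype=bool)
        keep[res.inlier_indices] = False
        remaining = remaining[keep]
    return detections


def _slice_tip_threshold(image: SliceImage, roi: Roi, cands: PointSet,
                         alpha: float) -> float:
    """Train the profile threshold from this slice's own pixels.

    Candidate (supra-alpha) pixels stand in for known needle positions and
    the remaining ROI pixels for background; their Gaussian density crossing
    separates shaft plateau from background along the axis profile.  Falls
    back to alpha when the slice gives no usable training split.
    """
    sub = image.raster[roi.as_slices()].ravel()
    bg = sub[sub < alpha]
    ne = cands.intensity if cands.intensity is not None else None
    if ne is None or len(ne) == 0 or len(bg) == 0:
        return alpha
    try:
        return train_tip_threshold(ne, bg)
    except ValueError:
        return alpha


def _assemble_detection(image: SliceImage, roi: Roi, res: RansacResult,
                        mcfg: MultiNeedleConfig, T: float, cands: PointSet,
                        remaining: np.ndarray, order: int) -> NeedleDetection:
    axis = res.model
    global_inliers = remaining[res.inlier_indices]
    inlier_xy = cands.xy[global_inliers]
    try:
        prof = extract_profile(image, axis, roi, mcfg.insertion_edge)
        if mcfg.insertion_edge == "auto":
            prof = _orient_for_entry(prof, T, mcfg.min_run)
        tip_res = localize_tip(prof, T, mcfg.min_run)
        entry_idx = _runs(prof.intensity >= T, mcfg.min_run)[0][0]
        tip = prof.point_at(tip_res.t_tip)
        entry = prof.point_at(float(prof.t[entry_idx]))
        at_edge = tip_res.at_profile_end
        from_profile = True
    except ValueError:
        # Profile-based tip failed (weak signal): fall back to the extreme
        # projections of the inlier points onto the axis.
        tip, entry = _span_endpoints(axis, inlier_xy)
        at_edge, from_profile = False, False
    if tip == entry:
        tip, entry = _span_endpoints(axis, inlier_xy)
        from_profile = False
    return NeedleDetection(axis, tip, entry, global_inliers, order,
                           res.sigma, at_edge, from_profile)


def _span_endpoints(axis: LineModel, inlier_xy: np.ndarray) -> tuple[Point2D, Point2D]:
    """Distal/proximal axis points spanned by the inlier projections."""
    a = np.asarray(axis.anchor, dtype=float)
    d = np.asarray(axis.direction, dtype=float)
    if len(inlier_xy) == 0:
        return axis.point_at(1.0), axis.point_at(-1.0)
    t_vals = (inlier_xy - a) @ d
    return axis.point_at(float(t_vals.max())), axis.point_at(float(t_vals.min()))
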