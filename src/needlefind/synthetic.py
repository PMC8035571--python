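"""Synthetic data: planted-line point clouds and needle-phantom slices.

The planted-line generator reproduces the simulation design used to
characterise the estimator: datasets of 1500 points at outlier ratios
0.1-0.8, inliers drawn uniformly along a known line segment with
perpendicular Gaussian jitter, the remainder scattered as Gaussian clusters
with uniform-random centres over the field.  The phantom generator renders
needles of known angle, depth and width into a noisy slice image, emulating
a printed needle phantom: ground-truth axes and tips are returned exactly.

Default geometry (declared here, not inferred from any source): a
100 x 100 mm field, a 90 mm segment through the field centre at a
seed-random orientation, inlier jitter sigma 0.5 mm, and 6 outlier clusters
of sigma 6 mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .geometry import LineModel, Point2D, PointSet, angular_deviation
from .preprocess import SliceImage
from .ransac import RansacConfig, ransac_baseline, detect_single_needle

__all__ = [
    "PlantedLineSpec",
    "PlantedSample",
    "PhantomSliceSpec",
    "generate_planted_points",
    "generate_phantom_slice",
    "simulation_sweep",
]


@dataclass(frozen=True)
class PlantedLineSpec:
    """Recipe for one planted-line dataset.

    ``line=None`` plants a segment through the field centre at an
    orientation drawn uniformly from the seeded generator.
    """

    n_points: int = 1500
    outlier_ratio: float = 0.5
    line: LineModel | None = None
    inlier_jitter_sigma: float = 0.5       # mm, perpendicular
    field_extent: tuple[float, float] = (100.0, 100.0)  # (width, height) mm
    segment_length: float = 90.0           # mm
    n_outlier_clusters: int = 6
    outlier_cluster_sigma: float = 6.0     # mm
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.outlier_ratio < 1.0:
            raise ValueError("outlier_ratio must be in [0, 1)")
        if self.field_extent[0] <= 0 or self.field_extent[1] <= 0:
            raise ValueError("field extent must be positive")
        if self.n_points < 0:
            raise ValueError("n_points must be >= 0")


@dataclass
class PlantedSample:
    points: PointSet
    line: LineModel            # ground-truth axis
    tip: Point2D               # distal segment endpoint
    inlier_indices: np.ndarray # indices of generated inliers


def generate_planted_points(spec: PlantedLineSpec) -> PlantedSample:
    """Generate a planted-line dataset with known ground truth.

    round((1 - eps) * n) inliers are placed uniformly along the segment with
    perpendicular N(0, jitter^2) offsets; outliers are assigned to Gaussian
    clusters whose centres are uniform over the field.  Fully reproducible
    from the seed; the random stream order is (orientation, inlier
    positions, inlier offsets, cluster centres, assignments, scatter).
    """
    rng = np.random.default_rng(spec.rng_seed)
    w, h = spec.field_extent
    center = np.array([w / 2.0, h / 2.0])
    if spec.line is None:
        theta = rng.uniform(0.0, math.pi)
        line = LineModel(Point2D(*center), (math.cos(theta), math.sin(theta)))
    else:
        line = spec.line
    d = np.asarray(line.direction, dtype=float)
    nvec = line.normal
    a = np.asarray(line.anchor, dtype=float)

    n_in = int(round((1.0 - spec.outlier_ratio) * spec.n_points))
    n_out = spec.n_points - n_in
    t = rng.uniform(-spec.segment_length / 2.0, spec.segment_length / 2.0, n_in)
    off = rng.normal(0.0, spec.inlier_jitter_sigma, n_in)
    inliers = a + np.outer(t, d) + np.outer(off, nvec)

    centers = rng.uniform([0.0, 0.0], [w, h], size=(spec.n_outlier_clusters, 2))
    assign = rng.integers(spec.n_outlier_clusters, size=n_out)
    scatter = rng.normal(0.0, spec.outlier_cluster_sigma, size=(n_out, 2))
    outliers = centers[assign] + scatter
    # Truncate clusters to the field by redrawing, never by projection:
    # projecting onto the boundary would plant spurious straight lines.
    for _ in range(100):
        bad = np.flatnonzero((outliers < 0).any(axis=1)
                             | (outliers[:, 0] > w) | (outliers[:, 1] > h))
        if bad.size == 0:
            break
        outliers[bad] = (centers[assign[bad]]
                         + rng.normal(0.0, spec.outlier_cluster_sigma,
                                      size=(bad.size, 2)))
    else:
        outliers = np.clip(outliers, [0.0, 0.0], [w, h])

    xy = np.vstack([inliers, outliers])
    tip = line.point_at(spec.segment_length / 2.0)
    return PlantedSample(PointSet(xy), line, tip, np.arange(n_in))


# ---------------------------------------------------------------------------
# Phantom slices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSliceSpec:
    """Recipe for a synthetic needle-phantom slice.

    Needles enter from the top edge at ``entry_x_mm`` abscissae (auto-spaced
    at ``pitch_mm`` when None), tilted ``insertion_angles`` degrees from
    vertical, inserted ``insertion_depths`` mm.  An 18-gauge shaft is about
    1.3 mm wide.  Angles within [0, 60] and positive depths are enforced.
    """

    n_needles: int = 1
    insertion_angles: tuple[float, ...] = (15.0,)
    insertion_depths: tuple[float, ...] = (60.0,)
    entry_x_mm: tuple[float, ...] | None = None
    pitch_mm: float = 10.0
    needle_width_mm: float = 1.3
    # Metal saturates the per-slice min-max normalisation, so the shaft sits
    # at the top of the intensity scale.
    needle_intensity: float = 1.0
    background_intensity: float = 0.2
    noise_sigma: float = 0.03
    artifact_amplitude: float = 0.0
    pixel_spacing: tuple[float, float] = (0.7, 0.7)
    image_shape: tuple[int, int] = (168, 168)
    entry_margin_mm: float = 4.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_needles < 1:
            raise ValueError("n_needles must be >= 1")
        if len(self.insertion_angles) not in (1, self.n_needles):
            raise ValueError("insertion_angles must have 1 or n_needles entries")
        if len(self.insertion_depths) not in (1, self.n_needles):
            raise ValueError("insertion_depths must have 1 or n_needles entries")
        if any(not 0.0 <= th <= 60.0 for th in self.insertion_angles):
            raise ValueError("insertion angles must lie in [0, 60] degrees")
        if any(hh <= 0 for hh in self.insertion_depths):
            raise ValueError("insertion depths must be positive")


def _needle_geometry(spec: PhantomSliceSpec):
    """Per-needle (entry, direction, tip) in mm; entries on the top edge."""
    angles = (list(spec.insertion_angles) * spec.n_needles)[: spec.n_needles]
    depths = (list(spec.insertion_depths) * spec.n_needles)[: spec.n_needles]
    if spec.entry_x_mm is not None:
        xs = list(spec.entry_x_mm)
        if len(xs) != spec.n_needles:
            raise ValueError("entry_x_mm must have n_needles entries")
    else:
        xs = [spec.entry_margin_mm + i * spec.pitch_mm
              for i in range(spec.n_needles)]
    geoms = []
    for x0, th, hh in zip(xs, angles, depths):
        entry = np.array([x0, spec.entry_margin_mm])
        d = np.array([math.sin(math.radians(th)), math.cos(math.radians(th))])
        tip = entry + hh * d
        geoms.append((entry, d, tip, hh))
    return geoms


def _segment_distance(px: np.ndarray, py: np.ndarray, p0, p1) -> np.ndarray:
    seg = p1 - p0
    L2 = float(seg @ seg)
    tt = ((px - p0[0]) * seg[0] + (py - p0[1]) * seg[1]) / L2
    tt = np.clip(tt, 0.0, 1.0)
    return np.hypot(px - (p0[0] + tt * seg[0]), py - (p0[1] + tt * seg[1]))


def generate_phantom_slice(spec: PhantomSliceSpec) -> tuple[SliceImage, list[tuple[LineModel, Point2D]]]:
    """Render a phantom slice and return it with exact ground truth.

    Needles are bright anti-aliased segments on a uniform background with
    additive Gaussian pixel noise and optional streak artifacts radiating
    from the shafts.  Raises if two needle shafts overlap.
    """
    H, W = spec.image_shape
    sy, sx = spec.pixel_spacing
    geoms = _needle_geometry(spec)
    for i in range(len(geoms)):
        for j in range(i + 1, len(geoms)):
            d_min = _min_segment_separation(geoms[i], geoms[j])
            if d_min < spec.needle_width_mm:
                raise ValueError(f"needles {i} and {j} overlap")
    for entry, d, tip, hh in geoms:
        for p in (entry, tip):
            if not (0 <= p[0] <= (W - 1) * sx and 0 <= p[1] <= (H - 1) * sy):
                raise ValueError("needle does not fit within the image")

    yy, xx = np.mgrid[0:H, 0:W]
    px = xx * sx
    py = yy * sy
    img = np.full((H, W), spec.background_intensity, dtype=float)
    aa = 0.5 * min(sy, sx)  # anti-aliasing ramp half-width
    for entry, d, tip, hh in geoms:
        dist = _segment_distance(px, py, entry, tip)
        cov = np.clip((spec.needle_width_mm / 2.0 + aa - dist) / (2.0 * aa), 0.0, 1.0)
        img = img + cov * (spec.needle_intensity - spec.background_intensity)

    rng = np.random.default_rng(spec.rng_seed)
    if spec.artifact_amplitude > 0:
        for entry, d, tip, hh in geoms:
            for _ in range(3):  # faint streaks radiating from the shaft
                t0 = rng.uniform(0.2, 0.8) * hh
                origin = entry + t0 * d
                phi = rng.uniform(0.0, 2.0 * math.pi)
                sdir = np.array([math.cos(phi), math.sin(phi)])
                send = origin + rng.uniform(5.0, 15.0) * sdir
                dist = _segment_distance(px, py, origin, send)
                img += spec.artifact_amplitude * np.exp(-(dist / 0.8) ** 2)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)

    truth = [(LineModel(Point2D(*entry), tuple(d)), Point2D(*tip))
             for entry, d, tip, hh in geoms]
    return SliceImage(np.clip(img, 0.0, 1.0), spec.pixel_spacing), truth


def _min_segment_separation(g1, g2) -> float:
    e1, d1, t1, _ = g1
    e2, d2, t2, _ = g2
    ts = np.linspace(0.0, 1.0, 64)
    p1 = e1 + np.outer(ts, t1 - e1)
    best = np.inf
    for p in p1:
        best = min(best, float(np.min(_segment_distance(
            np.full(64, p[0]), np.full(64, p[1]),
            e2, t2))))
    return best


# ---------------------------------------------------------------------------
# Simulation sweep
# ---------------------------------------------------------------------------

def simulation_sweep(eps_grid, reps: int, cfg: RansacConfig,
                     spec: PlantedLineSpec | None = None) -> pd.DataFrame:
    """Angular-deviation sweep over outlier ratios, baseline vs improved.

    For each ratio, ``reps`` independent planted datasets are generated and
    both estimators run; the summary holds mean/sd of the angular deviation
    beta per variant plus mean full-verification counts (the hardware-free
    efficiency measure).  With reps = 1 the sd columns are NaN.  All
    per-run seeds derive from ``cfg.rng_seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    base_spec = spec or PlantedLineSpec()
    rows = []
    for eps in eps_grid:
        betas_b, betas_p, ver_b, ver_p, rej_p = [], [], [], [], []
        for rep in range(reps):
            ss = np.random.SeedSequence(
                (int(cfg.rng_seed), int(round(eps * 1000)), int(rep)))
            s_data, s_base, s_pre = ss.spawn(3)
            sample = generate_planted_points(dc_replace(
                base_spec, outlier_ratio=float(eps),
                rng_seed=int(s_data.generate_state(1)[0] % (2**31))))
            cfg_eps = dc_replace(cfg, outlier_ratio=float(eps))
            rb = ransac_baseline(sample.points, cfg_eps,
                                 rng=np.random.default_rng(s_base))
            rp = detect_single_needle(sample.points, cfg_eps,
                                      rng=np.random.default_rng(s_pre))
            betas_b.append(angular_deviation(rb.model, sample.line))
            betas_p.append(angular_deviation(rp.model, sample.line))
            ver_b.append(rb.full_verifications)
            ver_p.append(rp.full_verifications)
            rej_p.append(rp.pretest_rejections)
        sd = (lambda v: float(np.std(v, ddof=1)) if reps > 1 else float("nan"))
        rows.append({
            "outlier_ratio": float(eps),
            "beta_mean_baseline": float(np.mean(betas_b)),
            "beta_sd_baseline": sd(betas_b),
            "beta_mean_improved": float(np.mean(betas_p)),
            "beta_sd_improved": sd(betas_p),
            "verifications_baseline_mean": float(np.mean(ver_b)),
            "verifications_improved_mean": float(np.mean(ver_p)),
            "pretest_rejections_mean": float(np.mean(rej_p)),
        })
    return pd.DataFrame(rows)
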