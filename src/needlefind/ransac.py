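"""Robust single-line estimation: baseline RANSAC, binomial-pretest screening,
and local optimisation with a PCA (total-least-squares) finish.

The estimator targets a single needle axis in a 2D candidate point cloud with
a *known* outlier ratio ``eps`` (in the multi-needle pipeline, eps is supplied
analytically from the needle count and the residual-noise fraction).

Scale and selection
-------------------
Each candidate minimal-sample model is scored with a robust residual scale

    sigma = 1.4826 * (1 + 5/(n - m)) * Q_q(|d_i|),   q = (1 - eps) / 2,

the median-absolute-deviation scale of Rousseeuw-Leroy with a small-sample
correction, generalised from the median to the (1-eps)/2 quantile so that it
tracks the *inlier* residual spread even past 50% contamination (at eps = 0
the quantile is the median and the printed formula is recovered; the public
:func:`robust_sigma` keeps the median form).  Candidates are ranked by
*minimum* robust scale -- the least-quantile-of-squares criterion native to
this scale estimate.  Support counted under a per-model scale is not
comparable between models (a bad model inflates its own gate), so support is
reported, and used as a tie-break, but not maximised.

Inliers of the selected model are classified once with the gate
``d <= z * sigma`` (z = 1.96 by default).

Pretest
-------
Before full verification each candidate is scored on a fresh random subset of
``pretest_size`` points: models with fewer than ``nf`` subset inliers (``nf``
the largest value whose binomial pass probability for a correct model stays
above ``pretest_confidence``) are rejected without touching the full dataset.
The subset gate uses the best-so-far model's refined sigma, so the first few
candidates are always fully verified to bootstrap it.  The iteration budget
grows from k >= log(1-P)/log(1-(1-eps)^m) to the pretest-adjusted
k >= log(1-P)/log(1-(1-eps)^m * Pt).

Randomness: every operation is a pure function of (data, config, seed).  Per
iteration the stream order is (1) minimal-sample draw, with redraws for
degenerate pairs, then (2) the pretest subset draw.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import LineModel, PointSet, fit_line_pca, point_line_distance

__all__ = [
    "RansacConfig",
    "RansacResult",
    "min_samples",
    "pretest_pass_probability",
    "select_nf",
    "robust_sigma",
    "robust_sigma_quantile",
    "gate_inliers",
    "ransac_baseline",
    "ransac_pretest",
    "local_optimize",
    "detect_single_needle",
]

#: Distance tolerance (mm) used as the inlier gate when sigma == 0: only
#: points numerically on the line are then inliers.
ZERO_SIGMA_TOL = 1e-9

_MAD_SCALE = 1.4826  # 1 / Phi^-1(3/4): normal-consistency factor


@dataclass(frozen=True)
class RansacConfig:
    """Tunables for the needle-axis estimator.

    Defaults follow the method's stated operating point: confidence P = 0.99,
    pretest sample n = 15 with minimum pass probability 0.80, 15 local
    iterations, and the 1.96-sigma inlier gate.
    """

    confidence: float = 0.99          # P
    outlier_ratio: float = 0.5        # eps, known or supplied by the pipeline
    min_sample: int = 2               # m; 2 for a 2D line
    pretest_size: int = 15            # n
    pretest_confidence: float = 0.80  # minimum Pt
    local_iters: int = 15             # kL, usually in [10, 20]
    inlier_gate_z: float = 1.96
    rng_seed: int = 0
    # implementation knobs
    min_pair_separation_mm: float = 0.35   # ~0.5 px at 0.7 mm spacing
    min_sigma_mm: float = 0.0              # scale floor (pixel-grid quantisation)
    bootstrap_verifications: int = 3       # full verifications before pretesting
    refine_max_iter: int = 10              # gate->PCA refit iterations in LO
    adaptive_outlier_ratio: bool = False   # update eps from best support so far
    max_iterations: int = 100_000
    # A needle is a thin elongated structure: a consensus whose principal
    # variance ratio falls below this is a failed (blob) fit and triggers a
    # fresh sampling round, up to max_restarts times.
    min_elongation: float = 50.0
    support_surplus_max: float = 1.2       # support beyond (1-eps)N that flags a loose fit
    max_restarts: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must be in (0, 1)")
        if not 0.0 <= self.outlier_ratio < 1.0:
            raise ValueError("outlier_ratio must be in [0, 1)")
        if not 0.0 < self.pretest_confidence <= 1.0:
            raise ValueError("pretest_confidence must be in (0, 1]")
        if self.min_sample < 2:
            raise ValueError("min_sample must be >= 2")
        if self.pretest_size < 2 * self.min_sample:
            raise ValueError("pretest_size must be >= 2 * min_sample")
        if self.local_iters < 1:
            raise ValueError("local_iters must be >= 1")
        if self.inlier_gate_z <= 0:
            raise ValueError("inlier_gate_z must be positive")


@dataclass
class RansacResult:
    """Outcome of one single-needle estimation."""

    model: LineModel
    inlier_indices: np.ndarray
    sigma: float
    iterations_run: int
    pretest_rejections: int = 0
    full_verifications: int = 0
    degenerate_warning: bool = False

    @property
    def support(self) -> int:
        return int(len(self.inlier_indices))


# ---------------------------------------------------------------------------
# Analytic pieces
# ---------------------------------------------------------------------------

def min_samples(P: float, eps: float, m: int, Pt: float = 1.0) -> int:
    """Smallest iteration count k with confidence P of one clean sample.

    With pretesting, a clean sample must also pass the pretest (probability
    Pt), so the per-iteration success probability is (1-eps)^m * Pt; Pt = 1
    recovers the classical bound.
    """
    if not 0.0 < P < 1.0:
        raise ValueError("P must be in (0, 1)")
    if not 0.0 <= eps < 1.0:
        raise ValueError("eps must be in [0, 1)")
    if not 0.0 < Pt <= 1.0:
        raise ValueError("Pt must be in (0, 1]")
    w = (1.0 - eps) ** m * Pt
    if w >= 1.0:
        return 1
    k = math.log(1.0 - P) / math.log(1.0 - w)
    return max(1, math.ceil(k - 1e-12))


def pretest_pass_probability(n: int, nf: int, eps: float) -> float:
    """Probability that a correct model shows >= nf inliers among n points.

    Upper binomial tail P(#inliers >= nf) with per-point inlier probability
    (1 - eps); nf = 0 gives 1 by the empty-sum convention.
    """
    if not 0 <= nf <= n:
        raise ValueError("need 0 <= nf <= n")
    if not 0.0 <= eps <= 1.0:
        raise ValueError("eps must be in [0, 1]")
    # sum_{i=0}^{nf-1} C(n,i) (1-eps)^i eps^(n-i): at most nf-1 inliers
    miss = 0.0
    for i in range(nf):
        miss += math.comb(n, i) * (1.0 - eps) ** i * eps ** (n - i)
    return min(1.0, max(0.0, 1.0 - miss))


def select_nf(n: int, eps: float, Pt_min: float) -> tuple[int, float]:
    """Largest pretest inlier demand nf whose pass probability stays >= Pt_min.

    Returns ``(nf, Pt)``; nf = 0 (pass everything, Pt = 1) is always feasible.
    """
    if not 0.0 < Pt_min <= 1.0:
        raise ValueError("Pt_min must be in (0, 1]")
    for nf in range(n, -1, -1):
        pt = pretest_pass_probability(n, nf, eps)
        if pt >= Pt_min:
            return nf, pt
    return 0, 1.0  # unreachable: nf = 0 always passes


def robust_sigma(residuals, m: int) -> float:
    """Robust residual scale 1.4826 * (1 + 5/(n-m)) * median(|d|).

    Valid for n >= 2m (raises otherwise); scale-equivariant.
    """
    r = np.abs(np.asarray(residuals, dtype=float))
    n = r.size
    if n < 2 * m:
        raise ValueError(f"robust_sigma needs n >= 2m (got n={n}, m={m})")
    return float(_MAD_SCALE * (1.0 + 5.0 / (n - m)) * np.median(r))


def robust_sigma_quantile(residuals, m: int, outlier_ratio: float) -> float:
    """Known-contamination robust scale: the (1-eps)/2 residual quantile.

    With outlier fraction eps known, the median of the *inlier* residual
    magnitudes sits near the (1-eps)/2 quantile of all |d| (outliers having
    larger residuals), so substituting that quantile for the median keeps the
    estimator consistent past 50% contamination.  eps = 0 reduces exactly to
    :func:`robust_sigma`.
    """
    if not 0.0 <= outlier_ratio < 1.0:
        raise ValueError("outlier_ratio must be in [0, 1)")
    r = np.abs(np.asarray(residuals, dtype=float))
    n = r.size
    if n < 2 * m:
        raise ValueError(f"robust_sigma_quantile needs n >= 2m (got n={n}, m={m})")
    q = (1.0 - outlier_ratio) / 2.0
    return float(_MAD_SCALE * (1.0 + 5.0 / (n - m)) * np.quantile(r, q))


def gate_inliers(points: PointSet, model: LineModel, sigma: float,
                 z: float = 1.96) -> np.ndarray:
    """Indices with perpendicular distance <= z * sigma (Eq. 6 gate).

    sigma = 0 degrades to a numerical on-the-line test (tolerance 1e-9 mm).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    d = point_line_distance(points.xy, model)
    return np.flatnonzero(d <= max(z * sigma, ZERO_SIGMA_TOL))


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _sample_pair(rng: np.random.Generator, xy: np.ndarray, min_sep: float,
                 pool: np.ndarray | None = None, tries: int = 100):
    """Draw a non-degenerate index pair (separation >= min_sep), or None."""
    n = len(xy) if pool is None else len(pool)
    for _ in range(tries):
        i, j = rng.choice(n, size=2, replace=False)
        if pool is not None:
            i, j = pool[i], pool[j]
        if np.hypot(*(xy[i] - xy[j])) >= max(min_sep, 1e-12):
            return int(i), int(j)
    return None


def _score_full(xy: np.ndarray, model: LineModel, eps: float, m: int,
                z: float, min_sigma: float = 0.0) -> tuple[float, float, np.ndarray]:
    """(selection sigma, refined sigma, inlier indices) for one model.

    Selection sigma is the known-eps quantile scale on all residuals; the
    inlier gate is applied once at z * sigma; the refined sigma re-estimates
    the scale from the gated residuals (single classification step, no
    iterated reweighting).
    """
    r = point_line_distance(xy, model)
    sigma_sel = max(robust_sigma_quantile(r, m, eps), min_sigma)
    inl = np.flatnonzero(r <= max(z * sigma_sel, ZERO_SIGMA_TOL))
    if len(inl) >= 2 * m:
        sigma_ref = max(robust_sigma(r[inl], m), min_sigma)
    else:
        sigma_ref = sigma_sel
    return sigma_sel, sigma_ref, inl


def _better(cand: tuple, best: tuple | None) -> bool:
    """Candidate ranking: smaller selection sigma, then more support, then
    the earlier iteration (keys are (sigma_sel, -support, iteration))."""
    return best is None or cand < best


def ransac_baseline(points: PointSet, cfg: RansacConfig,
                    rng: np.random.Generator | None = None) -> RansacResult:
    """General RANSAC: k two-point hypotheses, every one fully verified.

    k follows the classical bound (no pretest, Pt = 1).  The returned model
    is the best-ranked hypothesis itself -- no local optimisation and no PCA
    polish -- so this is the degradation reference for the improved variant.
    """
    xy = points.xy
    N, m = len(xy), cfg.min_sample
    if N < m:
        raise ValueError(f"need at least {m} points, got {N}")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    eps = cfg.outlier_ratio
    k = min(min_samples(cfg.confidence, eps, m), cfg.max_iterations)

    best_key = None
    best: RansacResult | None = None
    full = 0
    i = 0
    while i < k:
        pair = _sample_pair(rng, xy, cfg.min_pair_separation_mm)
        i += 1
        if pair is None:
            continue
        model = LineModel.through(points.point(pair[0]), points.point(pair[1]))
        sigma_sel, sigma_ref, inl = _score_full(xy, model, eps, m, cfg.inlier_gate_z, cfg.min_sigma_mm)
        full += 1
        key = (sigma_sel, -len(inl), i)
        if _better(key, best_key):
            best_key = key
            best = RansacResult(model, inl, sigma_ref, i, 0, full)
            if cfg.adaptive_outlier_ratio and len(inl) > 0:
                eps_est = min(eps, 1.0 - len(inl) / N)
                k = min(k, max(i, min_samples(cfg.confidence, eps_est, m)))
    if best is None:
        raise ValueError("all minimal samples degenerate; cannot fit a line")
    best.iterations_run = i
    best.full_verifications = full
    return best


def ransac_pretest(points: PointSet, cfg: RansacConfig,
                   rng: np.random.Generator | None = None) -> RansacResult:
    """RANSAC with preview model parameter evaluation (binomial pretest).

    Each hypothesis is first checked on a fresh random subset of
    ``pretest_size`` points against the best-so-far gate; hypotheses with
    fewer than nf subset inliers skip full verification.  The iteration
    budget uses the pretest-adjusted bound.
    """
    xy = points.xy
    N, m, n = len(xy), cfg.min_sample, cfg.pretest_size
    if N < m:
        raise ValueError(f"need at least {m} points, got {N}")
    if N < n:
        raise ValueError(f"pretest size {n} exceeds dataset size {N}")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    eps = cfg.outlier_ratio
    nf, pt = select_nf(n, eps, cfg.pretest_confidence)
    k = min(min_samples(cfg.confidence, eps, m, pt), cfg.max_iterations)

    best_key = None
    best: RansacResult | None = None
    rejections = 0
    full = 0
    i = 0
    while i < k:
        pair = _sample_pair(rng, xy, cfg.min_pair_separation_mm)
        i += 1
        if pair is None:
            continue
        model = LineModel.through(points.point(pair[0]), points.point(pair[1]))
        if best is not None and full >= cfg.bootstrap_verifications and nf > 0:
            sub = rng.choice(N, size=n, replace=False)
            d_sub = point_line_distance(xy[sub], model)
            t = max(cfg.inlier_gate_z * best.sigma, ZERO_SIGMA_TOL)
            if int(np.count_nonzero(d_sub <= t)) < nf:
                rejections += 1
                continue
        sigma_sel, sigma_ref, inl = _score_full(xy, model, eps, m, cfg.inlier_gate_z, cfg.min_sigma_mm)
        full += 1
        key = (sigma_sel, -len(inl), i)
        if _better(key, best_key):
            best_key = key
            best = RansacResult(model, inl, sigma_ref, i, rejections, full)
            if cfg.adaptive_outlier_ratio and len(inl) > 0:
                eps_est = min(eps, 1.0 - len(inl) / N)
                k = min(k, max(i, min_samples(cfg.confidence, eps_est, m, pt)))
    if best is None:
        raise ValueError("all minimal samples degenerate; cannot fit a line")
    best.iterations_run = i
    best.pretest_rejections = rejections
    best.full_verifications = full
    return best


def local_optimize(points: PointSet, seed_result: RansacResult,
                   cfg: RansacConfig,
                   rng: np.random.Generator | None = None) -> RansacResult:
    """Local RANSAC inside the seed consensus, then iterated PCA refinement.

    Stage 1 draws ``local_iters`` two-point hypotheses from the seed inlier
    set, ranking them by the median robust scale of the consensus residuals.
    Stage 2 alternates (gate on all N points with the known-eps quantile
    scale) -> (total-least-squares PCA refit on the gated set) to a fixed
    point, at most ``refine_max_iter`` times.  The final model is the PCA fit
    of the final consensus.

    The improved model never loses support when counted at the seed model's
    own gate; if that ever failed the seed result would be returned instead.
    A degenerate consensus returns the seed result with a warning flag.
    """
    xy = points.xy
    m, z, eps = cfg.min_sample, cfg.inlier_gate_z, cfg.outlier_ratio
    inl = np.asarray(seed_result.inlier_indices)
    if len(inl) < m:
        return replace_result(seed_result, degenerate_warning=True)
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)

    sub_xy = xy[inl]
    spread = np.ptp(sub_xy, axis=0)
    if float(np.hypot(*spread)) < max(cfg.min_pair_separation_mm, 1e-12):
        return replace_result(seed_result, degenerate_warning=True)

    # Stage 1: local resampling on the consensus set, scored on the consensus.
    def _local_sigma(model: LineModel) -> float:
        r = point_line_distance(sub_xy, model)
        if len(r) >= 2 * m:
            return robust_sigma(r, m)
        return float(np.max(np.abs(r)))

    best_model = seed_result.model
    best_sigma = _local_sigma(best_model)
    for _ in range(cfg.local_iters):
        pair = _sample_pair(rng, xy, cfg.min_pair_separation_mm, pool=inl)
        if pair is None:
            continue
        model = LineModel.through(points.point(pair[0]), points.point(pair[1]))
        s = _local_sigma(model)
        if s < best_sigma:
            best_sigma, best_model = s, model

    # Stage 2: gate (all N, known-eps quantile scale) -> PCA refit, iterated.
    model = best_model
    consensus: np.ndarray | None = None
    for _ in range(cfg.refine_max_iter):
        r_all = point_line_distance(xy, model)
        sigma_sel = max(robust_sigma_quantile(r_all, m, eps), cfg.min_sigma_mm)
        cur = np.flatnonzero(r_all <= max(z * sigma_sel, ZERO_SIGMA_TOL))
        if len(cur) < max(m, 2):
            break
        if consensus is not None and np.array_equal(cur, consensus):
            break
        try:
            model = fit_line_pca(points.subset(cur))
        except ValueError:
            break
        consensus = cur
    if consensus is None:
        return replace_result(seed_result, degenerate_warning=True)

    r_fin = point_line_distance(xy, model)
    sigma_sel_fin = max(robust_sigma_quantile(r_fin, m, eps), cfg.min_sigma_mm)
    inl_fin = np.flatnonzero(r_fin <= max(z * sigma_sel_fin, ZERO_SIGMA_TOL))
    sigma_fin = (robust_sigma(r_fin[inl_fin], m) if len(inl_fin) >= 2 * m
                 else float(np.max(np.abs(r_fin[inl_fin]))) if len(inl_fin) else 0.0)

    # Accept the refinement only if it improves the selection criterion (the
    # robust residual scale on the full dataset); otherwise keep the seed.
    r_seed = point_line_distance(xy, seed_result.model)
    sigma_sel_seed = max(robust_sigma_quantile(r_seed, m, eps), cfg.min_sigma_mm)
    if len(inl_fin) < m or sigma_sel_fin > sigma_sel_seed * (1.0 + 1e-12):
        warnings.warn("local optimization did not improve the seed model; "
                      "keeping the seed result")
        return replace_result(seed_result, degenerate_warning=True)

    return RansacResult(model, inl_fin, sigma_fin,
                        seed_result.iterations_run,
                        seed_result.pretest_rejections,
                        seed_result.full_verifications)


def replace_result(res: RansacResult, **kw) -> RansacResult:
    out = RansacResult(res.model, np.asarray(res.inlier_indices).copy(),
                       res.sigma, res.iterations_run, res.pretest_rejections,
                       res.full_verifications, res.degenerate_warning)
    for k, v in kw.items():
        setattr(out, k, v)
    return out


def _consensus_elongation(points: PointSet, res: RansacResult) -> float:
    """Principal-variance ratio of the consensus cloud (inf when thin)."""
    if res.support < 3:
        return float("inf")
    xy = points.xy[res.inlier_indices]
    rel = xy - xy.mean(axis=0)
    evals = np.linalg.eigvalsh(rel.T @ rel)
    if evals[0] <= 1e-12 * max(evals[1], 1.0):
        return float("inf")
    return float(evals[1] / evals[0])


def detect_single_needle(points: PointSet, cfg: RansacConfig,
                         rng: np.random.Generator | None = None) -> RansacResult:
    """Pretest-accelerated RANSAC followed by local optimisation.

    The composition of :func:`ransac_pretest` and :func:`local_optimize`,
    sharing one random stream (pretest first, local resamples after).

    The sampling budget carries a 1-P residual failure probability; when it
    strikes, the winner is a cluster artefact: its consensus is either not
    needle-shaped (low elongation) or carries an implausible support surplus
    over the (1-eps)N points a correct model can have (its gate is inflated).
    Either symptom triggers a fresh sampling round on the same stream (up to
    ``max_restarts``); the attempt with the best robust scale is returned,
    with counters summed over attempts.  A false alarm merely costs one
    extra round and returns the same fit.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    m, eps = cfg.min_sample, cfg.outlier_ratio
    best: RansacResult | None = None
    best_sig = float("inf")
    iters = rej = full = 0
    for _ in range(max(1, cfg.max_restarts + 1)):
        seed = ransac_pretest(points, cfg, rng=rng)
        res = local_optimize(points, seed, cfg, rng=rng)
        iters += res.iterations_run
        rej += res.pretest_rejections
        full += res.full_verifications
        sig = max(robust_sigma_quantile(
            point_line_distance(points.xy, res.model), m, eps), cfg.min_sigma_mm)
        if best is None or sig < best_sig:
            best, best_sig = res, sig
        expected_inliers = (1.0 - eps) * len(points)
        plausible = (_consensus_elongation(points, best) >= cfg.min_elongation
                     and best.support <= cfg.support_surplus_max * expected_inliers)
        if plausible:
            break
    best.iterations_run = iters
    best.pretest_rejections = rej
    best.full_verifications = full
    return best
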