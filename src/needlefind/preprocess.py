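"""CT slice preprocessing: ROI extraction, contrast enhancement, thresholding.

Turns a grayscale slice plus a target contour into the candidate needle
point set that the robust line estimator consumes.  Intensities are
normalised to [0, 1] per slice (min-max by default, or a fixed window at
load time); all downstream geometry is in millimetres via the pixel spacing.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import PointSet

__all__ = [
    "SliceImage",
    "ContrastParams",
    "Roi",
    "roi_from_contour",
    "expand_roi_if_needed",
    "enhance_contrast",
    "threshold_candidates",
    "load_dicom",
    "load_image",
    "load_contour",
    "save_candidates_csv",
    "save_roi_png",
]


@dataclass
class SliceImage:
    """A 2D slice: normalised raster, pixel spacing, optional target contour.

    raster        -- (H, W) float array, clipped to [0, 1] on construction
    pixel_spacing -- (mm per px along rows, mm per px along columns)
    contour       -- optional (K, 2) array of [row, col] vertices (pixels)
    """

    raster: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    contour: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raster = np.clip(np.asarray(self.raster, dtype=float), 0.0, 1.0)
        if self.raster.ndim != 2:
            raise ValueError("raster must be 2D")
        sy, sx = self.pixel_spacing
        if sy <= 0 or sx <= 0:
            raise ValueError("pixel spacing must be positive")
        self.pixel_spacing = (float(sy), float(sx))
        if self.contour is not None:
            self.contour = np.atleast_2d(np.asarray(self.contour, dtype=float))
            if self.contour.shape[1] != 2:
                raise ValueError("contour must be (K, 2) [row, col]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape


@dataclass(frozen=True)
class ContrastParams:
    """Power-law intensity mapping parameters.

    The input saturation window defaults to [0.15, 1.0] and the output span
    to [0, 1]; gamma > 1 compresses low intensities and expands high ones,
    boosting needle-to-background contrast.  gamma itself is empirical (the
    method only requires gamma > 1); 2.0 is this package's default.
    """

    ilow_in: float = 0.15
    ihigh_in: float = 1.0
    ilow_out: float = 0.0
    ihigh_out: float = 1.0
    gamma: float = 2.0

    def __post_init__(self) -> None:
        vals = (self.ilow_in, self.ihigh_in, self.ilow_out, self.ihigh_out)
        if not all(0.0 <= v <= 1.0 for v in vals):
            raise ValueError("intensity bounds must lie in [0, 1]")
        if self.ilow_in >= self.ihigh_in:
            raise ValueError("need ilow_in < ihigh_in")
        if self.ilow_out >= self.ihigh_out:
            raise ValueError("need ilow_out < ihigh_out")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class Roi:
    """Axis-aligned pixel rectangle, half-open: rows [row_min, row_max)."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_max <= self.row_min or self.col_max <= self.col_min:
            raise ValueError("ROI must be nonempty")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_max - self.row_min, self.col_max - self.col_min)

    def as_slices(self) -> tuple[slice, slice]:
        return (slice(self.row_min, self.row_max),
                slice(self.col_min, self.col_max))

    def contains(self, rows, cols) -> np.ndarray:
        rows = np.asarray(rows, dtype=float)
        cols = np.asarray(cols, dtype=float)
        return ((rows >= self.row_min) & (rows <= self.row_max - 1)
                & (cols >= self.col_min) & (cols <= self.col_max - 1))

    def bounds_mm(self, pixel_spacing) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of contained pixel centres, mm."""
        sy, sx = pixel_spacing
        return (self.col_min * sx, self.row_min * sy,
                (self.col_max - 1) * sx, (self.row_max - 1) * sy)


def roi_from_contour(image: SliceImage, margin_mm: float = 3.0) -> Roi:
    """Bounding box of the target contour, expanded by a safety margin.

    The margin (3 mm by default) is converted to pixels per axis and rounded
    *outward* so the guarantee holds under anisotropic spacing; the box is
    clipped to the image.
    """
    if image.contour is None or len(image.contour) < 3:
        raise ValueError("need a contour with at least 3 vertices")
    H, W = image.shape
    rows, cols = image.contour[:, 0], image.contour[:, 1]
    if rows.min() < 0 or cols.min() < 0 or rows.max() > H - 1 or cols.max() > W - 1:
        raise ValueError("contour lies outside the image")
    sy, sx = image.pixel_spacing
    dr = math.ceil(margin_mm / sy)
    dc = math.ceil(margin_mm / sx)
    return Roi(
        max(0, math.floor(rows.min()) - dr),
        max(0, math.floor(cols.min()) - dc),
        min(H, math.ceil(rows.max()) + dr + 1),
        min(W, math.ceil(cols.max()) + dc + 1),
    )


def expand_roi_if_needed(roi: Roi, candidates: PointSet, step_mm: float,
                         pixel_spacing=(1.0, 1.0),
                         image_shape: tuple[int, int] | None = None) -> Roi:
    """Grow the ROI in step_mm increments until all candidates fall inside.

    Growth is bounded by the image when ``image_shape`` is given; candidate
    points beyond the image itself are reported via a warning and the box is
    clipped.
    """
    if len(candidates) == 0:
        return roi
    sy, sx = pixel_spacing
    rows = candidates.xy[:, 1] / sy
    cols = candidates.xy[:, 0] / sx
    H = image_shape[0] if image_shape else None
    W = image_shape[1] if image_shape else None
    dr = max(1, math.ceil(step_mm / sy))
    dc = max(1, math.ceil(step_mm / sx))
    while not np.all(roi.contains(rows, cols)):
        grown = Roi(roi.row_min - dr, roi.col_min - dc,
                    roi.row_max + dr, roi.col_max + dc)
        if image_shape is not None:
            grown = Roi(max(0, grown.row_min), max(0, grown.col_min),
                        min(H, grown.row_max), min(W, grown.col_max))
            if grown == roi:  # cannot grow further: points beyond the image
                n_out = int(np.count_nonzero(~roi.contains(rows, cols)))
                warnings.warn(f"{n_out} candidate point(s) lie outside the "
                              "image; ROI clipped to image bounds")
                break
        roi = grown
    return roi


def enhance_contrast(image: SliceImage, params: ContrastParams | None = None) -> SliceImage:
    """Apply the saturating power-law intensity map.

    Pixels below the input window map to ilow_out, above it to ihigh_out,
    and in between through ((i - ilow_in)/(ihigh_in - ilow_in))^gamma scaled
    to the output span.  Monotone nondecreasing in the input.
    """
    p = params or ContrastParams()
    u = (image.raster - p.ilow_in) / (p.ihigh_in - p.ilow_in)
    mapped = (p.ihigh_out - p.ilow_out) * np.clip(u, 0.0, 1.0) ** p.gamma + p.ilow_out
    return SliceImage(mapped, image.pixel_spacing, image.contour)


def threshold_candidates(image: SliceImage, alpha: float,
                         roi: Roi | None = None) -> PointSet:
    """Candidate needle points: pixels with intensity >= alpha inside the ROI.

    Returns pixel-centre coordinates converted to mm (x = col * spacing,
    y = row * spacing) with the pixel intensities attached; an empty result
    is valid.  alpha is empirical -- the needle intensity distribution
    differs per case -- and defaults to 0.85 post-enhancement elsewhere in
    the package.
    """
    if not 0.0 <= alpha:
        raise ValueError("alpha must be >= 0")
    sy, sx = image.pixel_spacing
    if roi is None:
        roi = Roi(0, 0, *image.shape)
    sub = image.raster[roi.as_slices()]
    rr, cc = np.nonzero(sub >= alpha)
    rows = rr + roi.row_min
    cols = cc + roi.col_min
    xy = np.column_stack([cols * sx, rows * sy])
    return PointSet(xy, sub[rr, cc])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def load_dicom(path, window: tuple[float, float] | None = None,
               contour: np.ndarray | None = None) -> SliceImage:
    """Read a single-frame DICOM slice; spacing comes from the metadata.

    Stored values are rescaled (slope/intercept) and normalised to [0, 1]
    either by a fixed window (lo, hi) or per-slice min-max.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    spacing = getattr(ds, "PixelSpacing", [1.0, 1.0])
    return SliceImage(_normalize(arr, window),
                      (float(spacing[0]), float(spacing[1])), contour)


def load_image(path, pixel_spacing=(1.0, 1.0),
               window: tuple[float, float] | None = None,
               contour: np.ndarray | None = None) -> SliceImage:
    """Read a PNG/TIFF slice; spacing must be supplied (mm/px row, col)."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(str(path)), dtype=float)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    return SliceImage(_normalize(arr, window), pixel_spacing, contour)


def _normalize(arr: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    if window is not None:
        lo, hi = window
        if hi <= lo:
            raise ValueError("window must satisfy lo < hi")
    else:
        lo, hi = float(arr.min()), float(arr.max())
        if hi <= lo:
            return np.zeros_like(arr)
    return np.clip((arr - lo) / (hi - lo), 0.0, 1.0)


def load_contour(path) -> np.ndarray:
    """Read a closed-polygon contour: JSON {"vertices": [[row, col], ...]}."""
    with open(path) as fh:
        obj = json.load(fh)
    if not isinstance(obj, dict) or "vertices" not in obj:
        raise ValueError("contour JSON must be an object with a 'vertices' key")
    verts = np.asarray(obj["vertices"], dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("contour needs at least 3 [row, col] vertices")
    return verts


def save_candidates_csv(points: PointSet, path) -> None:
    import pandas as pd

    inten = points.intensity if points.intensity is not None else np.full(len(points), np.nan)
    pd.DataFrame({"x_mm": points.xy[:, 0], "y_mm": points.xy[:, 1],
                  "intensity": inten}).to_csv(path, index=False)


def save_roi_png(image: SliceImage, roi: Roi, path) -> None:
    """Write the (enhanced) ROI crop as an 8-bit PNG for quality control."""
    import imageio.v3 as iio

    crop = image.raster[roi.as_slices()]
    iio.imwrite(str(path), (np.clip(crop, 0, 1) * 255).astype(np.uint8))
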