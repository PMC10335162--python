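"""Iris segmentation, circle fitting, and pixel-to-millimeter calibration.

The in-image metric ruler is the corneal white-to-white (WTW) diameter: the
pigmented iris is segmented with a region-based (two-phase, piecewise
constant) active contour seeded from the canthi, the boundary is fitted with
a least-squares circle, left/right diameters are averaged, and the mean WTW
pixel diameter is pinned to a published reference diameter in millimeters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import find_contours
from skimage.segmentation import disk_level_set, morphological_chan_vese

from .errors import GeometryError, ParameterError, SegmentationError
from .landmarks import Point2D

__all__ = [
    "WTW_REFERENCE_MM",
    "SegmentationConfig",
    "BoundaryPointSet",
    "CircleFit",
    "CalibrationContext",
    "segment_iris",
    "trim_occlusion",
    "fit_circle",
    "wtw_mean",
    "make_calibration",
    "measure_wtw",
]

#: Published mean horizontal corneal diameter used as the default metric
#: reference (mm).
WTW_REFERENCE_MM = 11.71


@dataclass
class SegmentationConfig:
    """Settings for the active-contour iris segmentation.

    ``iterations`` and ``smoothing`` map directly onto the morphological
    Chan-Vese evolution; ``occlusion_fraction`` is the vertical fraction of
    the contour's extent trimmed at top and bottom before circle fitting
    (eyelids occlude the superior/inferior limbus, while WTW is a horizontal
    diameter); ``min_contrast`` is the minimum interior/exterior intensity
    separation (as a fraction of the image range) below which segmentation
    is declared failed.
    """

    iterations: int = 200
    smoothing: int = 1
    trim_occlusion: bool = True
    occlusion_fraction: float = 0.25
    min_contrast: float = 0.05
    min_area_px: int = 8


@dataclass
class BoundaryPointSet:
    """Ordered points on the detected iris boundary (closed contour)."""

    points: np.ndarray  # (n, 2) array of (x, y)
    side: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ParameterError("boundary points must be an (n, 2) array")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CircleFit:
    """Least-squares circle fitted to a boundary point set."""

    center: Point2D
    diameter_px: float
    rms_residual_px: float

    @property
    def radius_px(self) -> float:
        return self.diameter_px / 2.0


@dataclass
class CalibrationContext:
    """Pixel-to-millimeter conversion derived from the mean WTW diameter."""

    wtw_px_mean: float
    wtw_reference_mm: float = WTW_REFERENCE_MM
    wtw_px_left: float | None = None
    wtw_px_right: float | None = None

    def __post_init__(self) -> None:
        if self.wtw_px_mean <= 0:
            raise ParameterError(f"wtw_px_mean must be > 0, got {self.wtw_px_mean}")
        if self.wtw_reference_mm <= 0:
            raise ParameterError(
                f"wtw_reference_mm must be > 0, got {self.wtw_reference_mm}"
            )

    @property
    def mm_per_px(self) -> float:
        return self.wtw_reference_mm / self.wtw_px_mean

    def px_to_mm(self, px: float) -> float:
        return px * self.mm_per_px

    def px_to_cm(self, px: float) -> float:
        return self.px_to_mm(px) / 10.0

    def to_dict(self) -> dict:
        return {
            "wtw_px_left": self.wtw_px_left,
            "wtw_px_right": self.wtw_px_right,
            "wtw_px_mean": self.wtw_px_mean,
            "reference_mm": self.wtw_reference_mm,
            "mm_per_px": self.mm_per_px,
        }


def segment_iris(
    img: np.ndarray,
    endocanthion: Point2D,
    exocanthion: Point2D,
    cfg: SegmentationConfig | None = None,
    side: str = "",
) -> BoundaryPointSet:
    """Segment the iris with a canthus-seeded region-based active contour.

    The evolution is initialized with a disk centered at the canthal midpoint
    with radius 0.25x the inter-canthal distance, then evolved as a two-phase
    piecewise-constant active contour separating the dark iris foreground
    from the bright scleral background.

    Raises
    ------
    SegmentationError
        If the image is featureless, the contour collapses below
        ``cfg.min_area_px`` pixels, or the segmented region is not darker
        than its exterior.
    """
    cfg = cfg or SegmentationConfig()
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ParameterError("segment_iris expects a 2D grayscale image")
    h, w = img.shape
    for p in (endocanthion, exocanthion):
        if not (0 <= p.x < w and 0 <= p.y < h):
            raise GeometryError(f"canthus {p} outside image of shape {(h, w)}")

    span = endocanthion.distance(exocanthion)
    if span <= 0:
        raise GeometryError("coincident canthi")
    cx = 0.5 * (endocanthion.x + exocanthion.x)
    cy = 0.5 * (endocanthion.y + exocanthion.y)
    radius = 0.25 * span

    init = disk_level_set(img.shape, center=(cy, cx), radius=radius)
    mask = morphological_chan_vese(
        img, num_iter=cfg.iterations, init_level_set=init, smoothing=cfg.smoothing
    ).astype(bool)

    area = int(mask.sum())
    if area < cfg.min_area_px or area == mask.size:
        raise SegmentationError(
            f"segmentation collapsed (foreground area {area} px of {mask.size})"
        )
    inside = img[mask].mean()
    outside = img[~mask].mean()
    rng = float(img.max() - img.min())
    if rng <= 0 or abs(inside - outside) < cfg.min_contrast * rng:
        raise SegmentationError(
            "no foreground/background contrast "
            f"(inside {inside:.3g}, outside {outside:.3g})"
        )
    if inside > outside:  # two-phase labels can flip; iris must be the dark phase
        mask = ~mask
        if int(mask.sum()) < cfg.min_area_px:
            raise SegmentationError("dark phase smaller than minimum area")

    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        raise SegmentationError("no closed boundary found")
    contour = max(contours, key=len)  # (row, col) -> (x, y)
    pts = np.column_stack([contour[:, 1], contour[:, 0]])
    if len(pts) < 8:
        raise SegmentationError(f"boundary has only {len(pts)} points")
    return BoundaryPointSet(points=pts, side=side)


def trim_occlusion(boundary: BoundaryPointSet, fraction: float = 0.25) -> BoundaryPointSet:
    """Drop boundary points in the top/bottom ``fraction`` of the vertical extent.

    Eyelids occlude the superior and inferior limbus; the retained lateral
    arcs still determine the horizontal (white-to-white) diameter.
    """
    if not 0 <= fraction < 0.5:
        raise ParameterError("occlusion fraction must be in [0, 0.5)")
    y = boundary.points[:, 1]
    lo, hi = y.min(), y.max()
    extent = hi - lo
    if extent <= 0:
        return boundary
    keep = (y > lo + fraction * extent) & (y < hi - fraction * extent)
    if keep.sum() < 3:
        return boundary
    return BoundaryPointSet(points=boundary.points[keep], side=boundary.side)


def _kasa_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    # Algebraic fit: minimize sum((x^2 + y^2 + D x + E y + F)^2).
    A = np.column_stack([x, y, np.ones_like(x)])
    b = -(x**2 + y**2)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise GeometryError("degenerate (collinear) boundary points")
    D, E, F = sol
    cx, cy = -D / 2.0, -E / 2.0
    r2 = cx * cx + cy * cy - F
    if r2 <= 0 or not np.isfinite(r2):
        raise GeometryError("degenerate circle fit (non-positive radius)")
    return cx, cy, math.sqrt(r2)


def fit_circle(points: BoundaryPointSet | np.ndarray, gn_steps: int = 1) -> CircleFit:
    """Least-squares circle: Kåsa algebraic fit plus Gauss-Newton refinement.

    Exact (residual ~ machine epsilon) for points lying on a true circle;
    ``gn_steps`` geometric refinement steps reduce the algebraic fit's bias
    on noisy or partial arcs.
    """
    pts = points.points if isinstance(points, BoundaryPointSet) else np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise GeometryError("circle fit needs at least 3 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise GeometryError("all points coincident")
    cx, cy, r = _kasa_fit(x, y)

    for _ in range(max(0, gn_steps)):
        dx, dy = x - cx, y - cy
        d = np.hypot(dx, dy)
        if np.any(d == 0):
            break
        resid = d - r
        # Jacobian of residual wrt (cx, cy, r)
        J = np.column_stack([-dx / d, -dy / d, -np.ones_like(d)])
        try:
            step, *_ = np.linalg.lstsq(J, -resid, rcond=None)
        except np.linalg.LinAlgError:
            break
        cx, cy, r = cx + step[0], cy + step[1], r + step[2]
        if r <= 0:
            raise GeometryError("refinement produced non-positive radius")

    rms = float(np.sqrt(np.mean((np.hypot(x - cx, y - cy) - r) ** 2)))
    return CircleFit(center=Point2D(float(cx), float(cy)), diameter_px=2.0 * r,
                     rms_residual_px=rms)


def wtw_mean(left: CircleFit | float, right: CircleFit | float) -> float:
    """Arithmetic mean of left/right WTW pixel diameters."""
    dl = left.diameter_px if isinstance(left, CircleFit) else float(left)
    dr = right.diameter_px if isinstance(right, CircleFit) else float(right)
    if dl <= 0 or dr <= 0:
        raise ParameterError(f"diameters must be > 0, got ({dl}, {dr})")
    return 0.5 * (dl + dr)


def make_calibration(
    wtw_px_mean: float,
    wtw_reference_mm: float = WTW_REFERENCE_MM,
    wtw_px_left: float | None = None,
    wtw_px_right: float | None = None,
) -> CalibrationContext:
    """Build a calibration so a WTW-long pixel segment maps to the reference mm."""
    return CalibrationContext(
        wtw_px_mean=float(wtw_px_mean),
        wtw_reference_mm=float(wtw_reference_mm),
        wtw_px_left=wtw_px_left,
        wtw_px_right=wtw_px_right,
    )


def measure_wtw(
    img: np.ndarray,
    endocanthion: Point2D,
    exocanthion: Point2D,
    cfg: SegmentationConfig | None = None,
    side: str = "",
) -> CircleFit:
    """Segment one eye crop and return the fitted WTW circle."""
    cfg = cfg or SegmentationConfig()
    boundary = segment_iris(img, endocanthion, exocanthion, cfg, side=side)
    if cfg.trim_occlusion:
        boundary = trim_occlusion(boundary, cfg.occlusion_fraction)
    return fit_circle(boundary)
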