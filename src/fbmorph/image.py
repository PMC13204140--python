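"""2D silhouette morphometry of calibrated photographs.

A planar photo of an object next to a ruler yields, after pixel-to-mm
calibration and segmentation, the silhouette descriptor block: area,
perimeter, max/min Feret diameters (rotating calipers on the convex
hull), aspect ratio, circularity, solidity and the minimum osculating
circle radius along the contour (tip sharpness).

Coordinate convention: pixel centers at integer coordinates, origin
top-left, x right / y down; all outputs are mm after calibration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy.spatial import ConvexHull, QhullError
from skimage import filters, measure, morphology
from skimage.color import rgb2gray

from .errors import (
    CalibrationError,
    ContourError,
    CurvatureError,
    SegmentationError,
    UndefinedDescriptorError,
)

__all__ = [
    "ScaleCalibration",
    "SilhouetteMask",
    "Contour",
    "Shape2DDescriptors",
    "load_image",
    "calibrate",
    "segment_silhouette",
    "contour_and_measures",
    "feret_diameters",
    "shape_ratios",
    "min_curvature_radius",
    "describe_2d",
]


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF raster into an (H, W, 3) uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def _as_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 2:
        image = np.repeat(image[:, :, None], 3, axis=2)
    return image


# ---------------------------------------------------------------------------
# calibration


@dataclass
class ScaleCalibration:
    """Pixel-to-mm scale with the reference geometry it came from."""

    mm_per_px: float
    method: str  # "manual-two-point" | "tick-detection"
    reference_points: list = field(default_factory=list)  # ((px, py), mm)

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise CalibrationError(f"mm_per_px must be > 0, got {self.mm_per_px}")
        if len(self.reference_points) < 2:
            raise CalibrationError("need >= 2 reference points")


def _yellow_mask(rgb: np.ndarray) -> np.ndarray:
    r = rgb[:, :, 0].astype(float)
    g = rgb[:, :, 1].astype(float)
    b = rgb[:, :, 2].astype(float)
    return (r > 140) & (g > 110) & (b < 140) & (r + g - 2 * b > 80)


def calibrate(
    image: np.ndarray,
    mode: str = "ticks",
    manual_points: list | None = None,
    tick_spacing_mm: float = 1.0,
    max_spacing_dispersion: float = 0.10,
) -> ScaleCalibration:
    """Establish the mm-per-pixel scale of a photograph.

    ``manual`` mode fits a least-squares scale through the origin from all
    pairwise pixel distances vs mm distances of the supplied
    ``((px, py), mm_position)`` pairs. ``ticks`` mode finds the bright
    yellow ruler band, segments its dark tick marks, projects tick
    centroids onto the band axis and converts the median inter-tick pixel
    spacing with ``tick_spacing_mm``. Tick spacings whose dispersion
    exceeds ``max_spacing_dispersion`` of the median are rejected as an
    unreliable calibration.
    """
    if mode == "manual":
        if not manual_points or len(manual_points) < 2:
            raise CalibrationError("manual mode needs >= 2 (pixel, mm) pairs")
        pts = [(np.asarray(p, dtype=float), float(mm)) for p, mm in manual_points]
        num = den = 0.0
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                dpx = float(np.linalg.norm(pts[i][0] - pts[j][0]))
                dmm = abs(pts[i][1] - pts[j][1])
                num += dmm * dpx
                den += dpx * dpx
        if den == 0:
            raise CalibrationError("manual reference points are coincident")
        return ScaleCalibration(
            mm_per_px=num / den, method="manual-two-point",
            reference_points=[(tuple(p), mm) for p, mm in pts],
        )

    if mode != "ticks":
        raise ValueError(f"unknown calibration mode {mode!r}")

    rgb = _as_rgb(image)
    band = _yellow_mask(rgb)
    if band.sum() < 100:
        raise CalibrationError("no ruler band found (yellow segmentation empty)")
    lbl = measure.label(band, connectivity=2)
    props = measure.regionprops(lbl)
    band_region = max(props, key=lambda r: r.area)
    band = lbl == band_region.label
    from scipy.ndimage import binary_fill_holes

    band = binary_fill_holes(band)

    # dark ticks inside the (filled) band
    gray = rgb2gray(rgb)
    ticks = band & (gray < 0.35)
    tick_lbl = measure.label(ticks, connectivity=2)
    tick_props = [r for r in measure.regionprops(tick_lbl) if r.area >= 4]
    if len(tick_props) < 2:
        raise CalibrationError(
            f"found {len(tick_props)} usable tick marks; need >= 2"
        )
    centroids = np.array([r.centroid for r in tick_props])  # (row, col)

    # band axis via PCA of the band pixel coordinates
    ys, xs = np.nonzero(band)
    coords = np.column_stack([xs, ys]).astype(float)
    coords -= coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    axis = vt[0]
    proj = np.sort(centroids[:, [1, 0]] @ axis)
    spacings = np.diff(proj)
    spacings = spacings[spacings > 1.0]
    if len(spacings) == 0:
        raise CalibrationError("tick centroids are coincident along the band axis")
    med = float(np.median(spacings))
    if len(spacings) > 1 and float(np.std(spacings)) > max_spacing_dispersion * med:
        raise CalibrationError(
            f"tick spacing dispersion {np.std(spacings):.2f} px exceeds "
            f"{max_spacing_dispersion:.0%} of the median {med:.2f} px"
        )
    refs = [
        ((float(c[1]), float(c[0])), float(k * tick_spacing_mm))
        for k, c in enumerate(centroids[np.argsort(centroids[:, [1, 0]] @ axis)])
    ]
    return ScaleCalibration(
        mm_per_px=tick_spacing_mm / med, method="tick-detection",
        reference_points=refs,
    )


# ---------------------------------------------------------------------------
# segmentation


@dataclass
class SilhouetteMask:
    """Binary silhouette (one connected component) plus its provenance."""

    mask: np.ndarray  # bool (H, W)
    calibration: ScaleCalibration
    provenance: dict = field(default_factory=dict)
    border_touch: bool = False
    # working grayscale (polarity applied, ruler excluded); lets the contour
    # step find the true subpixel threshold crossing instead of the binary edge
    intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mask.sum() == 0:
            raise SegmentationError("empty silhouette mask")

    @property
    def pixel_area_mm2(self) -> float:
        """Pixel-count area estimate (diagnostic; see contour shoelace)."""
        return float(self.mask.sum()) * self.calibration.mm_per_px**2


def segment_silhouette(
    image: np.ndarray,
    calibration: ScaleCalibration,
    opening_radius_px: int = 2,
    polarity: str = "dark",
    threshold: float | str = "otsu",
    exclude_box: tuple[int, int, int, int] | str | None = "auto",
) -> SilhouetteMask:
    """Extract the object silhouette from a photograph.

    Grayscale (luma) conversion, Otsu global threshold with dark-side
    selection (or a fixed threshold in [0, 1]), disk-structuring-element
    morphological opening, then the largest 8-connected component.
    The ruler region is excluded either automatically (yellow-band mask,
    dilated) or by an explicit ``(row0, row1, col0, col1)`` box.
    """
    rgb = _as_rgb(image)
    gray = rgb2gray(rgb)
    if polarity == "light":
        gray = 1.0 - gray
    elif polarity != "dark":
        raise ValueError("polarity must be 'dark' or 'light'")

    excluded = np.zeros(gray.shape, dtype=bool)
    if exclude_box == "auto":
        excluded = morphology.dilation(_yellow_mask(rgb), morphology.disk(5))
    elif exclude_box is not None:
        r0, r1, c0, c1 = exclude_box
        excluded[r0:r1, c0:c1] = True
    work = np.where(excluded, 1.0, gray)

    if threshold == "otsu":
        thr = float(filters.threshold_otsu(work))
    else:
        thr = float(threshold)
    fg = work < thr
    if opening_radius_px > 0:
        fg = morphology.opening(fg, morphology.disk(opening_radius_px))
    if fg.sum() == 0:
        raise SegmentationError(
            f"no foreground below threshold {thr:.3f} after opening"
        )
    lbl = measure.label(fg, connectivity=2)
    largest = max(measure.regionprops(lbl), key=lambda r: (r.area, -r.label))
    mask = lbl == largest.label
    border = bool(
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    )
    if border:
        warnings.warn("silhouette touches the image border", stacklevel=2)
    return SilhouetteMask(
        mask=mask,
        calibration=calibration,
        provenance={
            "threshold": thr, "opening_radius_px": opening_radius_px,
            "polarity": polarity,
        },
        border_touch=border,
        intensity=work,
    )


# ---------------------------------------------------------------------------
# contour and measures


@dataclass
class Contour:
    """Closed simple polyline of subpixel boundary points, mm coordinates."""

    points: np.ndarray  # (n, 2), x/y mm, not repeating the first point

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) < 3:
            raise ContourError(f"contour needs >= 3 points, got {len(self.points)}")
        if self.area <= 0:
            raise ContourError("contour encloses no area")

    @property
    def area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return abs(
            0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        )

    @property
    def perimeter(self) -> float:
        d = np.roll(self.points, -1, axis=0) - self.points
        return float(np.linalg.norm(d, axis=1).sum())


def contour_and_measures(mask: SilhouetteMask) -> tuple[Contour, float, float]:
    """Subpixel outer boundary plus shoelace area and polyline perimeter (mm).

    Marching squares is run on the (lightly smoothed) working grayscale at
    the segmentation threshold, so the boundary interpolates the true
    intensity crossing at subpixel accuracy; when only a binary mask is
    available, the mask itself is smoothed with a 1 px Gaussian and traced
    at 0.5 instead. Inner holes are ignored with a warning.
    """
    from scipy.ndimage import gaussian_filter

    mm = mask.calibration.mm_per_px
    if mask.intensity is not None:
        fld = gaussian_filter(mask.intensity, sigma=0.8, mode="nearest")
        level = mask.provenance.get("threshold", 0.5)
        contours = measure.find_contours(-fld, -level)  # object is the dark side
    else:
        fld = gaussian_filter(mask.mask.astype(float), sigma=1.0, mode="constant")
        contours = measure.find_contours(fld, 0.5)
    if not contours:
        raise ContourError("marching squares found no boundary")
    if len(contours) > 1:
        warnings.warn(
            f"{len(contours) - 1} inner contour(s) ignored; outer boundary only",
            stacklevel=2,
        )

    def _shoelace(c):
        x, y = c[:, 1], c[:, 0]
        return abs(0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))

    outer = max(contours, key=_shoelace)
    pts = np.column_stack([outer[:, 1], outer[:, 0]]) * mm  # (x, y) mm
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    contour = Contour(points=pts)
    return contour, contour.area, contour.perimeter


# ---------------------------------------------------------------------------
# Feret diameters (rotating calipers)


def _hull_points(points: np.ndarray) -> np.ndarray:
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise ContourError(f"degenerate contour, hull failed: {exc}") from exc
    return points[hull.vertices]  # CCW order


def feret_diameters(contour: Contour) -> tuple[float, float]:
    """Maximum and minimum Feret diameters via rotating calipers.

    dmax is the largest antipodal hull-vertex distance; dmin is the
    minimum directional width, attained for a convex polygon with a
    support line flush with one of its edges.
    """
    hp = _hull_points(contour.points)
    n = len(hp)
    if n < 3:
        raise ContourError("fewer than 3 hull points")

    def _area2(i, j, k):
        return abs(
            (hp[j, 0] - hp[i, 0]) * (hp[k, 1] - hp[i, 1])
            - (hp[j, 1] - hp[i, 1]) * (hp[k, 0] - hp[i, 0])
        )

    # antipodal pairs: advance the opposite vertex while triangle area grows
    dmax2 = 0.0
    k = 1
    for i in range(n):
        j = (i + 1) % n
        while _area2(i, j, (k + 1) % n) > _area2(i, j, k):
            k = (k + 1) % n
        for p in (i, j):
            d2 = float(((hp[p] - hp[k]) ** 2).sum())
            dmax2 = max(dmax2, d2)

    # minimum width: farthest vertex from each edge's support line
    dmin = np.inf
    k = 1
    for i in range(n):
        j = (i + 1) % n
        e = hp[j] - hp[i]
        elen = float(np.linalg.norm(e))
        if elen == 0:
            continue
        while _area2(i, j, (k + 1) % n) > _area2(i, j, k):
            k = (k + 1) % n
        width = _area2(i, j, k) / elen
        dmin = min(dmin, width)
    return float(np.sqrt(dmax2)), float(dmin)


def shape_ratios(
    area_mm2: float,
    perimeter_mm: float,
    feret_max_mm: float,
    feret_min_mm: float,
    contour: Contour,
) -> tuple[float, float, float]:
    """Aspect ratio dmin/dmax, circularity 4 pi A / P^2, and solidity
    (silhouette area over convex-hull area)."""
    if feret_max_mm <= 0 or perimeter_mm <= 0:
        raise UndefinedDescriptorError("zero Feret diameter or perimeter")
    hp = _hull_points(contour.points)
    x, y = hp[:, 0], hp[:, 1]
    hull_area = abs(0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    if hull_area <= 0:
        raise UndefinedDescriptorError("zero hull area")
    return (
        float(feret_min_mm / feret_max_mm),
        float(4.0 * np.pi * area_mm2 / perimeter_mm**2),
        float(area_mm2 / hull_area),
    )


# ---------------------------------------------------------------------------
# curvature


def _resample_closed(pts: np.ndarray, spacing: float) -> np.ndarray:
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(round(total / spacing)), 8)
    si = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(si, s, closed[:, 0])
    y = np.interp(si, s, closed[:, 1])
    return np.column_stack([x, y])


def min_curvature_radius(
    contour: Contour,
    window: int = 5,
    residual_rel_tol: float = 0.15,
    resample_spacing_mm: float | None = None,
) -> float:
    """Smallest osculating-circle radius along the contour (tip sharpness).

    At every contour point an algebraic least-squares circle is fitted to
    the symmetric ``window``-point neighbourhood; fits whose RMS residual
    exceeds ``residual_rel_tol`` of the fitted radius (with a small
    absolute floor of half the point spacing) are discarded, and the
    minimum accepted radius is returned. The contour is resampled to
    uniform arc-length spacing first (default: its median point spacing).
    """
    pts = contour.points
    seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    # default: 4x the native point spacing, so grid-level wiggle stays small
    # against the sagitta of the window arc
    spacing = (
        4.0 * float(np.median(seg[seg > 0]))
        if resample_spacing_mm is None
        else resample_spacing_mm
    )
    pts = _resample_closed(pts, spacing)
    n = len(pts)
    if n < 2 * window + 1:
        raise CurvatureError(
            f"contour has {n} points; needs >= {2 * window + 1} for window {window}"
        )
    abs_floor = 0.5 * spacing
    best = np.inf
    idx = np.arange(-window, window + 1)
    for i in range(n):
        w = pts[(i + idx) % n]
        x, y = w[:, 0], w[:, 1]
        A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
        bvec = x**2 + y**2
        try:
            sol, *_ = np.linalg.lstsq(A, bvec, rcond=None)
        except np.linalg.LinAlgError:
            continue
        cx, cy, c0 = sol
        r2 = c0 + cx**2 + cy**2
        if r2 <= 0:
            continue
        r = float(np.sqrt(r2))
        resid = float(np.sqrt(np.mean((np.hypot(x - cx, y - cy) - r) ** 2)))
        if resid <= max(residual_rel_tol * r, abs_floor):
            best = min(best, r)
    if not np.isfinite(best):
        raise CurvatureError("all osculating-circle fits rejected")
    return best


# ---------------------------------------------------------------------------
# aggregate descriptor record


@dataclass
class Shape2DDescriptors:
    """Full 2D silhouette descriptor block (stored at full precision)."""

    area_mm2: float
    perimeter_mm: float
    feret_max_mm: float
    feret_min_mm: float
    aspect_ratio: float
    circularity: float
    solidity: float
    min_curvature_radius_mm: float
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "area_mm2": self.area_mm2,
            "perimeter_mm": self.perimeter_mm,
            "feret_max_mm": self.feret_max_mm,
            "feret_min_mm": self.feret_min_mm,
            "aspect_ratio": self.aspect_ratio,
            "circularity": self.circularity,
            "solidity": self.solidity,
            "min_curvature_radius_mm": self.min_curvature_radius_mm,
        }
        d.update({f"diag_{k}": v for k, v in self.diagnostics.items()})
        return d

    def rounded(self, ndigits: int = 2) -> dict:
        return {
            k: round(v, ndigits) if isinstance(v, float) else v
            for k, v in self.to_dict().items()
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def describe_2d(
    image: np.ndarray,
    calibration: ScaleCalibration | None = None,
    calibration_mode: str = "ticks",
    manual_points: list | None = None,
    tick_spacing_mm: float = 1.0,
    opening_radius_px: int = 2,
    polarity: str = "dark",
    threshold: float | str = "otsu",
    exclude_box=None,
    curvature_window: int = 5,
) -> Shape2DDescriptors:
    """Full 2D pipeline: calibrate, segment, contour, Feret, ratios,
    curvature. Values are stored at full precision; round only at report
    time."""
    if calibration is None:
        calibration = calibrate(
            image, mode=calibration_mode, manual_points=manual_points,
            tick_spacing_mm=tick_spacing_mm,
        )
    if exclude_box is None:
        # harmless when no ruler is present; keeps tick marks out of the
        # threshold statistics and the contour field
        exclude_box = "auto"
    mask = segment_silhouette(
        image, calibration, opening_radius_px=opening_radius_px,
        polarity=polarity, threshold=threshold, exclude_box=exclude_box,
    )
    contour, area, perim = contour_and_measures(mask)
    dmax, dmin = feret_diameters(contour)
    ar, circ, sol = shape_ratios(area, perim, dmax, dmin, contour)
    min_r = min_curvature_radius(contour, window=curvature_window)
    return Shape2DDescriptors(
        area_mm2=area,
        perimeter_mm=perim,
        feret_max_mm=dmax,
        feret_min_mm=dmin,
        aspect_ratio=ar,
        circularity=circ,
        solidity=sol,
        min_curvature_radius_mm=min_r,
        diagnostics={
            "mm_per_px": calibration.mm_per_px,
            "pixel_count_area_mm2": mask.pixel_area_mm2,
            "threshold": mask.provenance["threshold"],
            "border_touch": mask.border_touch,
        },
    )
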