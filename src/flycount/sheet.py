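"""Paper-sheet localisation and millimetre-calibrated rectification.

The counting method photographs dark insects scattered on a bright
standard-size paper sheet (A3/A4/A5 or a custom W x H mm rectangle) lying
on a dark, non-glare background.  Because the physical sheet dimensions
are known, warping the detected sheet quadrilateral to a fronto-parallel
raster gives every pixel a physical size, and all downstream object
measurements can be expressed in millimetres.

Conventions used throughout the package:

* image arrays are row-major ``uint8``, coordinates in ``(x, y)`` pixel
  order when stored in quadrilaterals;
* the rectified sheet is always in canonical *landscape* orientation
  (width >= height); portrait photographs are rotated implicitly by the
  corner-ordering step;
* the millimetre origin is the rectified sheet's top-left corner, so the
  centre of pixel ``(row, col)`` sits at
  ``((col + 0.5) * mm_per_px_x, (row + 0.5) * mm_per_px_y)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.spatial import ConvexHull
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label, regionprops
from skimage.transform import ProjectiveTransform, warp

from .errors import AmbiguousSheet, DegenerateQuad, InputError, NoSheetFound

#: ISO 216 dimensions in millimetres, landscape (width >= height).
ISO_SIZES_MM = {"A3": (420.0, 297.0), "A4": (297.0, 210.0), "A5": (210.0, 148.0)}

#: Default long side of the rectified raster, px.  ~0.15 mm/px on A4,
#: which comfortably resolves 2-3 mm flies.
DEFAULT_TARGET_LONG_SIDE_PX = 2000

# Sheet-detection tuning: minimum fraction of the frame a sheet may
# occupy, ambiguity ratio between the two largest bright candidates, and
# the minimum Otsu class contrast (8-bit) below which the frame is
# considered unimodal.
MIN_SHEET_FRACTION = 0.05
AMBIGUITY_RATIO = 0.90
MIN_CLASS_CONTRAST = 40.0
MIN_CORNER_ANGLE_DEG = 20.0


@dataclass(frozen=True)
class SheetSpec:
    """Physical paper dimensions — the calibration anchor.

    ``width_mm >= height_mm`` always (canonical landscape).
    """

    name: str
    width_mm: float
    height_mm: float

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("sheet dimensions must be positive")
        if self.width_mm < self.height_mm:
            raise ValueError("canonical orientation is landscape: width_mm >= height_mm")

    @property
    def aspect(self) -> float:
        return self.height_mm / self.width_mm

    @classmethod
    def iso(cls, name: str) -> "SheetSpec":
        w, h = ISO_SIZES_MM[name.upper()]
        return cls(name.upper(), w, h)

    @classmethod
    def custom(cls, width_mm: float, height_mm: float) -> "SheetSpec":
        if height_mm > width_mm:  # accept either order, canonicalise
            width_mm, height_mm = height_mm, width_mm
        return cls("custom", float(width_mm), float(height_mm))

    @classmethod
    def parse(cls, text: str) -> "SheetSpec":
        """Parse ``A3``/``A4``/``A5`` or a custom ``WxH`` millimetre pair."""
        t = text.strip().upper()
        if t in ISO_SIZES_MM:
            return cls.iso(t)
        if "X" in t:
            try:
                w, h = (float(p) for p in t.split("X"))
            except ValueError as exc:
                raise InputError(f"cannot parse paper size {text!r}") from exc
            return cls.custom(w, h)
        raise InputError(f"cannot parse paper size {text!r}")


@dataclass(frozen=True)
class Quadrilateral:
    """Sheet outline in image pixel coordinates.

    ``corners`` is a (4, 2) float array in ``(x, y)`` order: top-left,
    top-right, bottom-right, bottom-left of the canonical landscape sheet.
    """

    corners: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.corners, dtype=float)
        if c.shape != (4, 2):
            raise ValueError("quadrilateral needs exactly 4 (x, y) corners")
        object.__setattr__(self, "corners", c)
        if not _is_convex(c):
            raise ValueError("quadrilateral corners must form a convex polygon")

    @property
    def area(self) -> float:
        return _polygon_area(self.corners)

    def interior_angles_deg(self) -> np.ndarray:
        c = self.corners
        angles = []
        for i in range(4):
            a, b, d = c[i - 1], c[i], c[(i + 1) % 4]
            u, v = a - b, d - b
            cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        return np.array(angles)


@dataclass
class RectifiedImage:
    """Fronto-parallel grayscale raster of the sheet with physical scale."""

    pixels: np.ndarray  # uint8, shape (H, W)
    mm_per_px_x: float
    mm_per_px_y: float
    sheet: SheetSpec

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def px_to_mm(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinates to mm, origin at the sheet's top-left corner."""
        return (np.asarray(cols) + 0.5) * self.mm_per_px_x, (np.asarray(rows) + 0.5) * self.mm_per_px_y


# ---------------------------------------------------------------------------
# image loading / grayscale


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG/JPEG as a numpy array (grayscale or RGB)."""
    p = Path(path)
    if not p.exists():
        raise InputError(f"input image not found: {p}")
    try:
        img = iio.imread(p)
    except Exception as exc:  # pragma: no cover - backend specific
        raise InputError(f"cannot read image {p}: {exc}") from exc
    return np.asarray(img)


def to_gray(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) image to 8-bit luminance (ITU-R 601 weights)."""
    img = np.asarray(image)
    if img.ndim == 2:
        return img.astype(np.uint8, copy=False)
    if img.ndim == 3:
        rgb = img[..., :3].astype(np.float64)
        lum = rgb @ np.array([0.299, 0.587, 0.114])
        return np.clip(np.round(lum), 0, 255).astype(np.uint8)
    raise InputError(f"unsupported image shape {img.shape}")


# ---------------------------------------------------------------------------
# geometry helpers


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _is_convex(pts: np.ndarray) -> bool:
    n = len(pts)
    signs = []
    for i in range(n):
        a, b, c = pts[i], pts[(i + 1) % n], pts[(i + 2) % n]
        cross = (b[0] - a[0]) * (c[1] - b[1]) - (b[1] - a[1]) * (c[0] - b[0])
        signs.append(np.sign(cross))
    signs = [s for s in signs if s != 0]
    return len(set(signs)) <= 1


def order_corners(corners: np.ndarray) -> np.ndarray:
    """Order 4 corners canonically: landscape top-left first, clockwise.

    The polygon is first made clockwise in image coordinates (y down),
    then rotated so the first corner is the top-left of the *landscape*
    sheet: if the quad is portrait in the image (vertical edges longer
    than horizontal ones), the start is shifted by one so the long edges
    become top/bottom — this is what auto-rotates portrait photographs.
    """
    pts = np.asarray(corners, dtype=float)
    centre = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - centre[1], pts[:, 0] - centre[0])
    pts = pts[np.argsort(ang)]  # counter-clockwise in math coords == clockwise on screen? normalise:
    # signed area > 0 means counter-clockwise in (x, y up); with y down it is clockwise on screen.
    x, y = pts[:, 0], pts[:, 1]
    signed = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if signed < 0:  # make clockwise on screen
        pts = pts[::-1]
    start = int(np.argmin(pts.sum(axis=1)))  # most top-left
    pts = np.roll(pts, -start, axis=0)
    horiz = 0.5 * (np.linalg.norm(pts[0] - pts[1]) + np.linalg.norm(pts[3] - pts[2]))
    vert = 0.5 * (np.linalg.norm(pts[0] - pts[3]) + np.linalg.norm(pts[1] - pts[2]))
    if vert > horiz:  # portrait in the image: rotate 90° to landscape
        pts = np.roll(pts, -1, axis=0)
    return pts


def _refine_corners(contour_xy: np.ndarray, quad: np.ndarray) -> np.ndarray:
    """Refine corner estimates by fitting a line to each edge's contour points.

    Contour points are assigned to the nearest quad edge; points close to a
    corner are discarded; each edge is fit by total least squares and
    adjacent edge lines are intersected.  Falls back to the input corners
    when an edge has too few supporting points.
    """
    edges = [(quad[i], quad[(i + 1) % 4]) for i in range(4)]
    diag = np.linalg.norm(quad.max(axis=0) - quad.min(axis=0))
    corner_excl = max(5.0, 0.03 * diag)
    band = max(3.0, 0.01 * diag)

    dists = np.empty((len(contour_xy), 4))
    for i, (a, b) in enumerate(edges):
        ab = b - a
        t = np.clip(((contour_xy - a) @ ab) / (ab @ ab), 0.0, 1.0)
        proj = a + t[:, None] * ab
        dists[:, i] = np.linalg.norm(contour_xy - proj, axis=1)
    assign = np.argmin(dists, axis=1)
    near_corner = np.min(np.linalg.norm(contour_xy[:, None, :] - quad[None, :, :], axis=2), axis=1) < corner_excl

    lines = []
    for i, (a, b) in enumerate(edges):
        pts = contour_xy[(assign == i) & (dists[:, i] < band) & ~near_corner]
        if len(pts) < 10:
            # parametrise the unrefined edge instead
            d = (b - a) / np.linalg.norm(b - a)
            lines.append((a, d))
            continue
        mean = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - mean, full_matrices=False)
        lines.append((mean, vt[0]))

    refined = np.empty((4, 2))
    for i in range(4):
        p1, d1 = lines[i - 1]
        p2, d2 = lines[i]
        a_mat = np.column_stack([d1, -d2])
        if abs(np.linalg.det(a_mat)) < 1e-9:
            refined[i] = quad[i]
            continue
        t = np.linalg.solve(a_mat, p2 - p1)
        refined[i] = p1 + t[0] * d1
    return refined


# ---------------------------------------------------------------------------
# detection and rectification


def detect_sheet(image: np.ndarray) -> Quadrilateral:
    """Locate the bright paper sheet and return its corner quadrilateral.

    Strategy: Otsu threshold on luminance -> largest bright connected
    region -> convex hull of its contour -> four extreme corners, refined
    by least-squares line fits along each edge.

    Raises ``NoSheetFound`` when no bright region covers at least 5% of
    the frame, and ``AmbiguousSheet`` when the two largest candidates
    differ in area by less than 10%.
    """
    gray = to_gray(image)
    h, w = gray.shape
    if h < 100 or w < 100:
        raise InputError("image must be at least 100x100 pixels")

    thr = threshold_otsu(gray)
    bright = gray > thr
    # unimodal guard: if the two Otsu classes barely differ the frame is
    # either all sheet or all background
    lo = gray[~bright]
    hi = gray[bright]
    if lo.size == 0 or hi.size == 0 or (hi.mean() - lo.mean()) < MIN_CLASS_CONTRAST:
        if gray.mean() >= 128:  # sheet fills the frame
            full = np.array([[-0.5, -0.5], [w - 0.5, -0.5], [w - 0.5, h - 0.5], [-0.5, h - 0.5]])
            return Quadrilateral(order_corners(full))
        raise NoSheetFound("no bright sheet-like region in the image")

    lab = label(bright, connectivity=2)
    regions = sorted(regionprops(lab), key=lambda r: r.area, reverse=True)
    min_area = MIN_SHEET_FRACTION * h * w
    candidates = [r for r in regions if r.area >= min_area]
    if not candidates:
        raise NoSheetFound("no bright region covers at least 5% of the frame")
    if len(candidates) >= 2 and candidates[1].area / candidates[0].area > AMBIGUITY_RATIO:
        raise AmbiguousSheet("two bright regions of nearly equal area; cannot pick the sheet")

    mask = lab == candidates[0].label
    contours = find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)
    contour_xy = contour[:, ::-1]  # (row, col) -> (x, y)

    hull = ConvexHull(contour_xy)
    hull_pts = contour_xy[hull.vertices]

    # four extreme corners of the hull (sheet photographed without extreme roll)
    s = hull_pts.sum(axis=1)
    d = hull_pts[:, 0] - hull_pts[:, 1]
    corners = np.array(
        [hull_pts[np.argmin(s)], hull_pts[np.argmax(d)], hull_pts[np.argmax(s)], hull_pts[np.argmin(d)]]
    )
    if len(np.unique(corners.round(3), axis=0)) < 4:
        raise NoSheetFound("bright region is not quadrilateral")
    corners = _refine_corners(contour_xy, corners)

    quad_area = _polygon_area(corners)
    if quad_area < min_area:
        raise NoSheetFound("detected quadrilateral covers less than 5% of the frame")
    ordered = order_corners(corners)
    if not _is_convex(ordered):
        raise NoSheetFound("detected corners are not convex")
    return Quadrilateral(ordered)


def rectify(
    image: np.ndarray,
    quad: Quadrilateral,
    sheet: SheetSpec,
    target_long_side_px: int = DEFAULT_TARGET_LONG_SIDE_PX,
) -> RectifiedImage:
    """Warp the sheet quadrilateral to a fronto-parallel mm-calibrated raster.

    The output raster is ``target_long_side_px`` wide and
    ``round(target_long_side_px * height_mm / width_mm)`` tall;
    ``mm_per_px`` follows from the physical sheet dimensions.
    """
    if target_long_side_px < 200:
        raise ValueError("target_long_side_px must be >= 200")
    angles = quad.interior_angles_deg()
    if np.any(angles < MIN_CORNER_ANGLE_DEG):
        raise DegenerateQuad(f"corner angle {angles.min():.1f} deg < {MIN_CORNER_ANGLE_DEG} deg")

    w_px = int(target_long_side_px)
    h_px = int(round(target_long_side_px * sheet.aspect))
    # output pixel-corner frame: sheet corners sit on the outer pixel corners
    dst_rect = np.array(
        [[-0.5, -0.5], [w_px - 0.5, -0.5], [w_px - 0.5, h_px - 0.5], [-0.5, h_px - 0.5]]
    )
    tform = ProjectiveTransform.from_estimate(dst_rect, quad.corners)
    if not tform:
        raise DegenerateQuad("homography estimation failed")

    gray = to_gray(image).astype(np.float64) / 255.0
    warped = warp(gray, tform, output_shape=(h_px, w_px), order=1, mode="edge")
    pixels = np.clip(np.round(warped * 255.0), 0, 255).astype(np.uint8)
    return RectifiedImage(
        pixels=pixels,
        mm_per_px_x=sheet.width_mm / w_px,
        mm_per_px_y=sheet.height_mm / h_px,
        sheet=sheet,
    )


def full_frame_quad(image: np.ndarray) -> Quadrilateral:
    """Quadrilateral spanning the whole image (for pre-rectified inputs)."""
    h, w = to_gray(image).shape
    return Quadrilateral(
        np.array([[-0.5, -0.5], [w - 0.5, -0.5], [w - 0.5, h - 0.5], [-0.5, h - 0.5]])
    )
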