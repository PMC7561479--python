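"""Binarisation of the rectified sheet and connected-object extraction.

Dark flies on bright paper give a strongly bimodal histogram, so a global
Otsu threshold (after a 3x3 median filter against sensor noise) separates
objects from sheet.  Component interiors are filled before measurement —
specular highlights on the thorax would otherwise punch holes and bias
area downward — and a 2 mm band along the sheet edge is forced to
background so sheet-edge shadows never masquerade as elongated objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import MultiPoint
from skimage.filters import threshold_isodata
from skimage.measure import label, regionprops
from skimage.transform import resize

from .sheet import RectifiedImage

#: width of the forced-background band along the sheet edge, mm
MARGIN_MM = 2.0

#: minimum relative class contrast (object vs paper, after flat-field
#: normalisation) for the raster to count as bimodal; below it the sheet
#: is considered empty and the mask is all background
MIN_OBJECT_CONTRAST_REL = 0.25


class Label(str, Enum):
    """Classification state of a detected object."""

    UNCLASSIFIED = "unclassified"
    EXCLUDED_SMALL = "excluded_small"
    EXCLUDED_LARGE = "excluded_large"
    GARBAGE = "garbage"
    TARGET = "target"
    TOUCHING = "touching"


@dataclass
class DetectedObject:
    """One 8-connected dark component with pixel and mm measurements."""

    id: int
    area_px: int
    area_mm2: float
    length_mm: float
    centroid_mm: tuple[float, float]
    bbox_px: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    label: Label = Label.UNCLASSIFIED
    cluster_estimate: int = 0
    # pixel coordinates of the component, kept for annotation/debug output
    coords_px: np.ndarray | None = field(default=None, repr=False)


def margin_px(rect: RectifiedImage) -> tuple[int, int]:
    """Forced-background band width in pixels, (rows, cols)."""
    return (
        int(np.ceil(MARGIN_MM / rect.mm_per_px_y)),
        int(np.ceil(MARGIN_MM / rect.mm_per_px_x)),
    )


def _illumination_field(img: np.ndarray) -> np.ndarray:
    """Smooth multiplicative illumination estimate (flat-field reference).

    Estimated on a 16x-downsampled copy with a wide Gaussian, so sparse
    mm-scale objects barely dent it while sheet-scale lighting gradients
    are captured.
    """
    h, w = img.shape
    small = resize(img, (max(h // 16, 8), max(w // 16, 8)), order=1, anti_aliasing=True)
    small = ndi.gaussian_filter(small, sigma=max(small.shape) / 8.0)
    return np.maximum(resize(small, (h, w), order=1), 1e-3)


def binarize(rect: RectifiedImage, invert: bool = False) -> np.ndarray:
    """Foreground mask of the rectified sheet (True = object pixel).

    Flat-field normalisation (dividing out a coarse illumination estimate)
    makes the threshold immune to lighting gradients; the isodata
    criterion — the threshold midway between the two class means — keeps
    the object boundary pinned to the half-intensity edge crossing, so
    mm-unit measurements are stable across raster resolutions.
    ``invert=True`` segments light objects on a dark sheet instead.
    Returns an all-False mask when the raster has no real object/sheet
    contrast (an empty sheet must not yield noise speckle).
    """
    # median kernel sized in mm (~0.3 mm, min 3 px) so denoising and the
    # resulting object morphology do not depend on the raster resolution
    k = max(3, 2 * int(round(0.15 / min(rect.mm_per_px_x, rect.mm_per_px_y))) + 1)
    img = ndi.median_filter(rect.pixels, size=k).astype(np.float32)
    norm = img / _illumination_field(img)
    if float(norm.max() - norm.min()) < 0.5 * MIN_OBJECT_CONTRAST_REL:
        return np.zeros(rect.shape, dtype=bool)  # no object/paper contrast at all
    try:
        thr = threshold_isodata(norm, nbins=512)
    except (ValueError, IndexError):  # (near-)uniform raster
        return np.zeros(rect.shape, dtype=bool)
    fg = norm > thr if invert else norm < thr
    if not fg.any() or fg.all():
        return np.zeros(rect.shape, dtype=bool)
    # bimodality guard: a threshold always splits, even pure noise
    contrast = abs(float(norm[~fg].mean()) - float(norm[fg].mean()))
    if contrast < MIN_OBJECT_CONTRAST_REL:
        return np.zeros(rect.shape, dtype=bool)
    # refine to the midpoint of the two *plateau* levels: class means drag
    # the threshold with the edge-ramp pixel count, which varies with blur
    # and resolution and would bias object sizes systematically; the
    # plateau midpoint pins the boundary at the half-intensity crossing
    core = ndi.binary_erosion(fg, iterations=2)
    if not core.any():
        core = ndi.binary_erosion(fg)
    obj_level = float(np.median(norm[core])) if core.any() else float(np.median(norm[fg]))
    bg_level = float(np.median(norm[~fg]))
    thr = 0.5 * (obj_level + bg_level)
    fg = norm > thr if invert else norm < thr
    mask = ndi.binary_fill_holes(fg)
    mr, mc = margin_px(rect)
    mask[:mr, :] = False
    mask[-mr:, :] = False
    mask[:, :mc] = False
    mask[:, -mc:] = False
    return mask


def _caliper_mm(points_xy_mm: np.ndarray) -> float:
    """Longer side of the minimum-area rotated rectangle over mm points."""
    pts = points_xy_mm
    if len(pts) > 16:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear: shapely handles the degenerate hull
    rect = MultiPoint(pts).minimum_rotated_rectangle
    if rect.geom_type == "Polygon":
        ring = np.asarray(rect.exterior.coords)
        return float(np.linalg.norm(np.diff(ring, axis=0), axis=1).max())
    if rect.geom_type == "LineString":
        return float(rect.length)
    return 0.0


#: minimum object/background contrast (8-bit) for the intensity-based
#: sub-pixel outline; below it the binary mask outline is used instead
#: (e.g. for synthetic masks without a raster behind them)
MIN_CALIPER_CONTRAST = 30.0


def _component_length(region, rect: RectifiedImage) -> float:
    """Caliper length of one component, in mm.

    The outline is the iso-contour of the local intensity patch at the
    midpoint between the object and paper plateau levels — marching
    squares interpolates it to sub-pixel positions, so the measurement
    does not depend on the raster resolution (any two rectifications of
    the same photograph interpolate the same underlying field).  When the
    patch has no real contrast (a bare mask), the 0.5 iso-contour of the
    binary coverage patch is used, which makes a 10-px row of pixels
    measure exactly 10 px.
    """
    from skimage.measure import find_contours

    mm_x, mm_y = rect.mm_per_px_x, rect.mm_per_px_y
    r0, c0, r1, c1 = region.bbox
    h, w = rect.shape
    pad = 3
    pr0, pc0 = max(r0 - pad, 0), max(c0 - pad, 0)
    pr1, pc1 = min(r1 + pad, h), min(c1 + pad, w)
    local = np.zeros((pr1 - pr0, pc1 - pc0), dtype=bool)
    local[region.coords[:, 0] - pr0, region.coords[:, 1] - pc0] = True

    patch = rect.pixels[pr0:pr1, pc0:pc1].astype(np.float32)
    core = ndi.binary_erosion(local, iterations=2)
    ring = ~ndi.binary_dilation(local, iterations=2)
    if core.any() and ring.any():
        obj_level = float(np.median(patch[core]))
        bg_level = float(np.median(patch[ring]))
        if abs(bg_level - obj_level) >= MIN_CALIPER_CONTRAST:
            level = 0.5 * (obj_level + bg_level)
            contours = find_contours(patch, level)
            if contours:
                pts = np.vstack(contours)
                return _caliper_mm(np.column_stack([pts[:, 1] * mm_x, pts[:, 0] * mm_y]))

    padded = np.pad(local, 1).astype(np.float32)
    contours = find_contours(padded, 0.5)
    if not contours:  # single-pixel speck
        return float(max(mm_x, mm_y))
    pts = np.vstack(contours)
    return _caliper_mm(np.column_stack([pts[:, 1] * mm_x, pts[:, 0] * mm_y]))


def extract_objects(mask: np.ndarray, rect: RectifiedImage) -> list[DetectedObject]:
    """One ``DetectedObject`` per 8-connected foreground component.

    Components whose bounding box touches the forced margin band are
    dropped (they are truncated by it and cannot be measured).
    """
    if mask.shape != rect.shape:
        raise ValueError("mask shape must match the rectified raster")
    h, w = mask.shape
    mr, mc = margin_px(rect)
    lab = label(mask, connectivity=2)
    objects: list[DetectedObject] = []
    next_id = 1
    for region in regionprops(lab):
        r0, c0, r1, c1 = region.bbox
        if r0 <= mr or c0 <= mc or r1 >= h - mr or c1 >= w - mc:
            continue
        length = _component_length(region, rect)
        cy, cx = region.centroid
        x_mm, y_mm = rect.px_to_mm(cy, cx)
        objects.append(
            DetectedObject(
                id=next_id,
                area_px=int(region.area),
                area_mm2=float(region.area) * rect.mm_per_px_x * rect.mm_per_px_y,
                length_mm=length,
                centroid_mm=(float(x_mm), float(y_mm)),
                bbox_px=(r0, c0, r1, c1),
                coords_px=region.coords,
            )
        )
        next_id += 1
    return objects


def segment(rect: RectifiedImage, invert: bool = False) -> list[DetectedObject]:
    """Convenience: binarize then extract, as the pipeline runs it."""
    return extract_objects(binarize(rect, invert=invert), rect)
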