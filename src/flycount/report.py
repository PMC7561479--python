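"""Outputs: annotated image, per-object TSV table, and the pipeline driver.

Colour convention for the annotated image: garbage outlined blue, single
targets green, touching clusters red; length-excluded objects gray.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.segmentation import find_boundaries

from .classify import ClassificationParams, CountReport, count
from .errors import InputError
from .scene import SceneSpec  # noqa: F401  (re-exported for CLI convenience)
from .segmentation import DetectedObject, Label, segment
from .sheet import (
    DEFAULT_TARGET_LONG_SIDE_PX,
    RectifiedImage,
    SheetSpec,
    detect_sheet,
    full_frame_quad,
    load_image,
    rectify,
)

LABEL_COLORS: dict[Label, tuple[int, int, int]] = {
    Label.GARBAGE: (0, 0, 255),
    Label.TARGET: (0, 200, 0),
    Label.TOUCHING: (255, 0, 0),
    Label.EXCLUDED_SMALL: (128, 128, 128),
    Label.EXCLUDED_LARGE: (128, 128, 128),
    Label.UNCLASSIFIED: (128, 128, 128),
}


@dataclass
class AnnotatedImage:
    """RGB raster of the rectified sheet with colour-coded object outlines."""

    pixels: np.ndarray  # uint8, shape (H, W, 3)


def annotate(rect: RectifiedImage, objects: list[DetectedObject]) -> AnnotatedImage:
    """Outline each object in its label colour; other pixels unchanged."""
    rgb = np.stack([rect.pixels] * 3, axis=-1).astype(np.uint8)
    for obj in objects:
        if obj.coords_px is None:
            continue
        r0, c0, r1, c1 = obj.bbox_px
        local = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=bool)
        local[obj.coords_px[:, 0] - r0 + 1, obj.coords_px[:, 1] - c0 + 1] = True
        edge = find_boundaries(local, mode="outer")
        rr, cc = np.nonzero(edge)
        rr = np.clip(rr + r0 - 1, 0, rect.shape[0] - 1)
        cc = np.clip(cc + c0 - 1, 0, rect.shape[1] - 1)
        rgb[rr, cc] = LABEL_COLORS[obj.label]
    return AnnotatedImage(pixels=rgb)


# ---------------------------------------------------------------------------
# TSV export

_OBJECT_COLUMNS = ["id", "label", "area_mm2", "length_mm", "centroid_x_mm", "centroid_y_mm", "cluster_estimate"]

_SUMMARY_FIELDS = [
    "n_excluded_small",
    "n_excluded_large",
    "n_garbage",
    "n_targets",
    "n_touching_objects",
    "touching_total_estimate",
    "total_estimate",
    "mean_area_mm2",
]


def export_table(objects: list[DetectedObject], report: CountReport, path: str | Path) -> None:
    """Write the per-object table plus a summary block as TSV.

    UTF-8, Unix newlines, tab delimiter, reals to 4 decimals.  Summary
    rows are prefixed ``#summary`` so the object table stays machine
    readable with a plain TSV reader.
    """
    path = Path(path)
    lines = ["\t".join(_OBJECT_COLUMNS)]
    for o in objects:
        lines.append(
            "\t".join(
                [
                    str(o.id),
                    o.label.value,
                    f"{o.area_mm2:.4f}",
                    f"{o.length_mm:.4f}",
                    f"{o.centroid_mm[0]:.4f}",
                    f"{o.centroid_mm[1]:.4f}",
                    str(o.cluster_estimate),
                ]
            )
        )
    for name in _SUMMARY_FIELDS:
        value = getattr(report, name)
        text = f"{value:.4f}" if isinstance(value, float) else str(value)
        lines.append(f"#summary\t{name}\t{text}")
    try:
        path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    except OSError as exc:
        raise InputError(f"cannot write table to {path}: {exc}") from exc


def parse_table(path: str | Path) -> tuple[list[dict], dict]:
    """Read back an exported TSV: (object rows, summary dict)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"table not found: {path}")
    rows: list[dict] = []
    summary: dict = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        if not line:
            continue
        parts = line.split("\t")
        if parts[0] == "#summary":
            name, value = parts[1], parts[2]
            summary[name] = float(value) if name == "mean_area_mm2" else int(value)
            continue
        row = dict(zip(header, parts))
        for key in ("id", "cluster_estimate"):
            row[key] = int(row[key])
        for key in ("area_mm2", "length_mm", "centroid_x_mm", "centroid_y_mm"):
            row[key] = float(row[key])
        rows.append(row)
    return rows, summary


# ---------------------------------------------------------------------------
# pipeline driver


@dataclass
class CountResult:
    """Everything the pipeline produced for one image."""

    rect: RectifiedImage
    objects: list[DetectedObject]
    report: CountReport


def count_image(
    image: np.ndarray,
    sheet: SheetSpec,
    params: ClassificationParams | None = None,
    target_long_side_px: int = DEFAULT_TARGET_LONG_SIDE_PX,
    skip_detect: bool = False,
    mm_per_px: float | None = None,
    invert: bool = False,
) -> CountResult:
    """Detect -> rectify -> segment -> classify on one image array.

    With ``skip_detect`` the input is taken as already fronto-parallel;
    ``mm_per_px`` then overrides the scale implied by the sheet size.
    """
    from .sheet import to_gray

    if skip_detect:
        gray = to_gray(image)
        if mm_per_px is not None:
            h, w = gray.shape
            rect = RectifiedImage(gray, mm_per_px, mm_per_px, SheetSpec.custom(w * mm_per_px, h * mm_per_px))
        else:
            quad = full_frame_quad(image)
            rect = rectify(image, quad, sheet, target_long_side_px)
    else:
        quad = detect_sheet(image)
        rect = rectify(image, quad, sheet, target_long_side_px)
    objects = segment(rect, invert=invert)
    report = count(objects, params)
    return CountResult(rect=rect, objects=objects, report=report)


def count_file(
    path: str | Path,
    sheet: SheetSpec,
    params: ClassificationParams | None = None,
    **kwargs,
) -> CountResult:
    """``count_image`` on a PNG/JPEG file."""
    return count_image(load_image(path), sheet, params, **kwargs)


def save_annotated(annotated: AnnotatedImage, path: str | Path) -> None:
    iio.imwrite(Path(path), annotated.pixels)
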