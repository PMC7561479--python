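"""Size-based object classification and count estimation.

The counting rule works on object sizes alone, with five parameters:

* objects shorter than ``min_length_mm`` (default 3 mm: fly fragments,
  debris) or longer than ``max_length_mm`` (default 14 mm: hairs, pen
  marks) are excluded outright;
* the areas of the remaining objects are sorted and a ``rejection
  percentile`` (default 10%) is discarded from each tail before taking
  the mean single-fly area;
* an object with area below ``mean x trash_area_factor`` (default 0.71)
  is garbage, above ``mean x touching_area_factor`` (default 4) it is a
  clump of touching flies, otherwise it is a single target fly;
* each touching clump contributes ``floor(area / mean)`` flies.

The total estimate is the number of targets plus the summed clump
estimates.  Boundary-equal areas are targets (the garbage/touching rules
use strict inequalities), and boundary-equal lengths are kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import NoObjects
from .segmentation import DetectedObject, Label


@dataclass(frozen=True)
class ClassificationParams:
    """The five counting parameters (defaults as used for adult flies)."""

    min_length_mm: float = 3.0
    max_length_mm: float = 14.0
    rejection_percentile: float = 10.0  # percent, per tail, in [0, 50)
    trash_area_factor: float = 0.71
    touching_area_factor: float = 4.0

    def __post_init__(self) -> None:
        if not self.min_length_mm < self.max_length_mm:
            raise ValueError("min_length_mm must be < max_length_mm")
        if not 0.0 <= self.rejection_percentile < 50.0:
            raise ValueError("rejection_percentile must be in [0, 50)")
        if not 0.0 < self.trash_area_factor < self.touching_area_factor:
            raise ValueError("need 0 < trash_area_factor < touching_area_factor")


@dataclass(frozen=True)
class CountReport:
    """Category counts and the total fly estimate for one sheet."""

    n_excluded_small: int
    n_excluded_large: int
    n_garbage: int
    n_targets: int
    n_touching_objects: int
    touching_total_estimate: int
    total_estimate: int
    mean_area_mm2: float

    @classmethod
    def empty(cls) -> "CountReport":
        return cls(0, 0, 0, 0, 0, 0, 0, float("nan"))


def filter_by_length(
    objects: Iterable[DetectedObject], params: ClassificationParams
) -> list[DetectedObject]:
    """Assign excluded_small / excluded_large; boundary-equal lengths kept.

    Returns the kept (still unclassified) objects; labels are written in
    place on every input object.
    """
    kept = []
    for obj in objects:
        if obj.length_mm < params.min_length_mm:
            obj.label = Label.EXCLUDED_SMALL
        elif obj.length_mm > params.max_length_mm:
            obj.label = Label.EXCLUDED_LARGE
        else:
            obj.label = Label.UNCLASSIFIED
            kept.append(obj)
    return kept


def trimmed_mean_area(areas_mm2: Sequence[float], rejection_percentile: float) -> float:
    """Mean area after discarding ``floor(p/100 * n)`` objects per tail.

    Falls back to the untrimmed mean if trimming would discard everything.
    """
    areas = np.sort(np.asarray(list(areas_mm2), dtype=float))
    n = areas.size
    if n == 0:
        raise NoObjects("no objects left to average")
    k = int(np.floor(rejection_percentile / 100.0 * n))
    if 2 * k >= n:
        return float(areas.mean())
    return float(areas[k : n - k].mean())


def classify_by_area(
    objects: Iterable[DetectedObject], mean_area_mm2: float, params: ClassificationParams
) -> None:
    """Label kept objects garbage / target / touching against the mean area."""
    if not mean_area_mm2 > 0:
        raise ValueError("mean_area_mm2 must be positive")
    trash_cut = mean_area_mm2 * params.trash_area_factor
    touch_cut = mean_area_mm2 * params.touching_area_factor
    for obj in objects:
        if obj.area_mm2 < trash_cut:
            obj.label = Label.GARBAGE
        elif obj.area_mm2 > touch_cut:
            obj.label = Label.TOUCHING
        else:
            obj.label = Label.TARGET


def estimate_cluster_count(obj: DetectedObject, mean_area_mm2: float) -> int:
    """Integer part of area / mean area: flies in one touching clump."""
    if obj.label is not Label.TOUCHING:
        raise ValueError("cluster estimation applies to touching objects only")
    est = int(np.floor(obj.area_mm2 / mean_area_mm2))
    obj.cluster_estimate = est
    return est


def count(
    objects: Sequence[DetectedObject],
    params: ClassificationParams | None = None,
) -> CountReport:
    """Run the full classification chain and assemble the count report.

    Raises ``NoObjects`` when nothing survives the length filter (this
    includes an empty input list).
    """
    params = params or ClassificationParams()
    objects = list(objects)
    kept = filter_by_length(objects, params)
    if not kept:
        raise NoObjects("no objects survive the length filter")
    mean_area = trimmed_mean_area([o.area_mm2 for o in kept], params.rejection_percentile)
    classify_by_area(kept, mean_area, params)
    touching = [o for o in kept if o.label is Label.TOUCHING]
    for obj in touching:
        estimate_cluster_count(obj, mean_area)
    n_targets = sum(o.label is Label.TARGET for o in kept)
    touching_total = sum(o.cluster_estimate for o in touching)
    return CountReport(
        n_excluded_small=sum(o.label is Label.EXCLUDED_SMALL for o in objects),
        n_excluded_large=sum(o.label is Label.EXCLUDED_LARGE for o in objects),
        n_garbage=sum(o.label is Label.GARBAGE for o in kept),
        n_targets=n_targets,
        n_touching_objects=len(touching),
        touching_total_estimate=touching_total,
        total_estimate=n_targets + touching_total,
        mean_area_mm2=mean_area,
    )
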