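import numpy as np
import pytest

import flycount as fc


def make_object(
    id: int = 1,
    area_mm2: float = 5.0,
    length_mm: float = 4.0,
    label: fc.Label = fc.Label.UNCLASSIFIED,
    centroid_mm: tuple[float, float] = (10.0, 10.0),
) -> fc.DetectedObject:
    """Hand-built object for classification-rule tests (no raster behind it)."""
    return fc.DetectedObject(
        id=id,
        area_px=max(1, int(round(area_mm2 / 0.01))),
        area_mm2=area_mm2,
        length_mm=length_mm,
        centroid_mm=centroid_mm,
        bbox_px=(0, 0, 1, 1),
        label=label,
    )


@pytest.fixture(scope="session")
def small_scene():
    """One 12-fly A4 scene shared by sheet/reporting tests."""
    spec = fc.SceneSpec(n_singles=12, n_debris=3, seed=42, output_long_side_px=1600)
    image, truth = fc.generate_scene(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def small_scene_result(small_scene):
    spec, image, truth = small_scene
    result = fc.count_image(image, spec.sheet, target_long_side_px=1600)
    return spec, truth, result


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
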