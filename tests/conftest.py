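import numpy as np
import pytest

from anglemech.geometry import (
    BACKGROUND,
    CILIARY,
    IRIS,
    SCLERA,
    AcquisitionMode,
    PhysicalSpacing,
    SegmentationMask,
)
from anglemech.features import extract_feature_row
from anglemech.synthetic import AnatomyParams, render_mask


@pytest.fixture(scope="session")
def default_render():
    """Default synthetic scene: (mask, ground truth)."""
    return render_mask(AnatomyParams(), seed=0)


@pytest.fixture(scope="session")
def default_row(default_render):
    mask, _ = default_render
    return extract_feature_row(mask, image_id="default")


def make_band_mask(
    iris_rows=(100, 140),
    shape=(400, 512),
    um_per_px=10.0,
    sclera_rows=(10, 40),
    ciliary_box=((140, 200), (0, 60)),
):
    """Hand-built axis-aligned mask: horizontal iris band of known vertical
    thickness, a sclera band above, and a ciliary block touching the iris."""
    labels = np.zeros(shape, dtype=np.uint8)
    labels[sclera_rows[0]: sclera_rows[1], :] = SCLERA
    labels[iris_rows[0]: iris_rows[1], :] = IRIS
    (r0, r1), (c0, c1) = ciliary_box
    labels[r0:r1, c0:c1] = CILIARY
    return SegmentationMask(
        labels=labels,
        mode=AcquisitionMode.HALF_FRAME,
        spacing=PhysicalSpacing(um_per_px, um_per_px),
    )
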