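import numpy as np
import pytest

from nucmorph.morphometry import LabeledPatch
from nucmorph.synthetic import make_patch


@pytest.fixture(scope="session")
def patch50():
    """One noise-free 512x512 patch of 50 ellipses with its ground truth."""
    return make_patch(n_nuclei=50, canvas=(512, 512), seed=7)


@pytest.fixture(scope="session")
def labeled_patch50(patch50):
    class_map = {s.id: s.cell_class for s in patch50.specs}
    return LabeledPatch(
        rgb=patch50.rgb,
        labels=patch50.labels,
        mpp=patch50.mpp,
        class_map=class_map,
    )


def raster_ellipse(a, b, angle=0.0, shape=(128, 128), center=None):
    """Direct pixel-center-inside rasterization used as an independent
    oracle (no shared code with the package's rasterizer)."""
    H, W = shape
    if center is None:
        center = (H / 2, W / 2)
    rr, cc = np.mgrid[0:H, 0:W]
    dr = rr - center[0]
    dc = cc - center[1]
    x = dr * np.cos(angle) + dc * np.sin(angle)
    y = -dr * np.sin(angle) + dc * np.cos(angle)
    return (x / a) ** 2 + (y / b) ** 2 < 1.0
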