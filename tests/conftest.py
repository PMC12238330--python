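import numpy as np
import pytest

from planardose.dpk import DoseKernel
from planardose.imaging_io import OrganMask, PlanarImage
from planardose.phantom import KernelModel, default_phantom, make_kernel


@pytest.fixture
def small_image():
    return PlanarImage(
        np.array([[1.0, 2.0], [3.0, 4.0]]),
        pixel_size_mm=(2.3976, 2.3976),
        view="anterior",
        duration_s=1.0,
    )


@pytest.fixture
def delta_kernel():
    g = np.zeros((5, 5))
    g[2, 2] = 1.0
    return DoseKernel(g)


@pytest.fixture
def radial_kernel():
    return make_kernel(KernelModel(amplitude=1e-4, range_mm=3.0, kernel_size=9))


@pytest.fixture
def phantom_cfg():
    return default_phantom()


@pytest.fixture
def square_mask():
    pix = np.zeros((11, 11), dtype=bool)
    pix[4:7, 4:7] = True
    return OrganMask(pix, "tumor")
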