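import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from portaledge import PhantomSpec, ViewLabel, build_phantom, project

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale phantom: 48^3 voxels of 4 mm, 96^2 projections."""
    return PhantomSpec(shape_vox=(48, 48, 48), voxel_mm=4.0)


@pytest.fixture(scope="session")
def small_volume(small_spec):
    return build_phantom(small_spec)


@pytest.fixture(scope="session")
def small_projections(small_spec, small_volume):
    return {
        (beam, view): project(small_volume, beam, ViewLabel(view), small_spec)
        for beam in ("kv", "mv")
        for view in ("AP", "LAT")
    }


@pytest.fixture()
def edge_image():
    """64x64 step image whose boundary follows a gentle cubic in the column.

    Returns (grid, boundary) where boundary(c) gives the real-valued row of
    the intensity step at column c.
    """
    from portaledge import IntensityGrid

    n = 64
    coeffs = np.array([2e-4, -0.02, 0.7, 22.0])

    def boundary(c):
        return np.polyval(coeffs, c)

    rows = np.arange(n)[:, None]
    cols = np.arange(n)[None, :]
    img = np.where(rows > boundary(cols), 1200.0, 150.0)
    return IntensityGrid(img, spacing_px_mm=1.0), boundary
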