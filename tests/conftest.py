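import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from smallfov_mar import (AttenuationTable, ScanGeometry, Spectrum,
                          effective_mu_water)

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_geom() -> ScanGeometry:
    """64x64 grid, detector wide enough to cover the whole image."""
    return ScanGeometry(source_to_iso=150.0, detector_to_iso=100.0,
                        n_views=90, detector_cell_size=1.0, n_detectors=120,
                        image_extent=64.0, image_matrix=64)


@pytest.fixture(scope="session")
def small_geom() -> ScanGeometry:
    """Untruncated geometry for reduced-scale pipeline tests; the image
    grid (0.5 mm) is finer than the detector sampling at iso (0.6 mm) so
    reprojection of a reconstruction preserves the detector band."""
    return ScanGeometry(source_to_iso=300.0, detector_to_iso=200.0,
                        n_views=360, detector_cell_size=1.0, n_detectors=320,
                        image_extent=128.0, image_matrix=256)


@pytest.fixture(scope="session")
def spectrum() -> Spectrum:
    return Spectrum.kramers_120kvp()


@pytest.fixture(scope="session")
def atten() -> AttenuationTable:
    return AttenuationTable.default()


@pytest.fixture(scope="session")
def mu_water_eff(spectrum, atten) -> float:
    return effective_mu_water(spectrum, atten)


def disk_image(geom: ScanGeometry, radius: float, mu: float,
               center=(0.0, 0.0), soft_edge: float = 0.0) -> np.ndarray:
    """Analytic disk rasterized with a half-pixel antialiased (or wider
    cosine-tapered) edge."""
    c = geom.pixel_centers()
    xx, yy = np.meshgrid(c, c)
    r = np.hypot(xx - center[0], yy - center[1])
    if soft_edge > 0:
        t = np.clip((r - radius + soft_edge) / soft_edge, 0.0, 1.0)
        return mu * 0.5 * (1.0 + np.cos(np.pi * t))
    return mu * np.clip((radius - r) / geom.pixel_size + 0.5, 0.0, 1.0)
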