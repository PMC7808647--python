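"""Array containers for projection and image data.

A :class:`Sinogram` is a views x detector-bins array tagged with the
physical domain of its values (material path length / line integral,
photon-count intensity, or log projection) and linked to its acquisition
geometry. A :class:`ReconImage` is a square attenuation or HU image tagged
with its unit and FOV radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ScanGeometry

__all__ = ["Sinogram", "ReconImage", "DEFAULT_MU_WATER", "mu_to_hu", "hu_to_mu"]

SINOGRAM_DOMAINS = ("path_length", "intensity", "log_projection")
IMAGE_UNITS = ("mu", "HU")

#: Linear attenuation of water (mm^-1) at the default 60 keV effective
#: energy, used for HU conversion.
DEFAULT_MU_WATER = 0.02059


@dataclass
class Sinogram:
    """Projection data: ``values[view, detector_bin]``.

    ``detector_oversample`` counts fine bins per native detector cell;
    ``pad_bins`` counts extra virtual cells appended on *each* side of the
    detector by truncation correction (native cell pitch).
    """

    values: np.ndarray
    geometry: ScanGeometry
    domain: str = "path_length"
    detector_oversample: int = 1
    pad_bins: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("sinogram values must be 2-D (views x bins)")
        if self.domain not in SINOGRAM_DOMAINS:
            raise ValueError(f"domain must be one of {SINOGRAM_DOMAINS}")
        if self.detector_oversample < 1:
            raise ValueError("detector_oversample must be >= 1")
        expected = (self.geometry.n_detectors + 2 * self.pad_bins) \
            * self.detector_oversample
        if self.values.shape != (self.geometry.n_views, expected):
            raise ValueError(
                f"sinogram shape {self.values.shape} inconsistent with geometry "
                f"({self.geometry.n_views} views x {expected} bins)")
        if self.domain == "intensity" and np.any(self.values < 0):
            raise ValueError("intensity-domain sinogram must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def detector_coords(self) -> np.ndarray:
        """Signed bin-center coordinates (mm) including padding."""
        du = self.geometry.detector_cell_size / self.detector_oversample
        n = self.n_bins
        return (np.arange(n) - (n - 1) / 2.0) * du

    def with_values(self, values: np.ndarray, domain: str | None = None) -> "Sinogram":
        return replace(self, values=values,
                       domain=self.domain if domain is None else domain)

    def copy(self) -> "Sinogram":
        return replace(self, values=self.values.copy())


@dataclass
class ReconImage:
    """Square reconstructed image with unit tag and FOV radius."""

    values: np.ndarray
    pixel_size: float
    fov_radius: float
    unit: str = "mu"
    mu_water: float = DEFAULT_MU_WATER

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("image must be 2-D square")
        if self.unit not in IMAGE_UNITS:
            raise ValueError(f"unit must be one of {IMAGE_UNITS}")
        if self.pixel_size <= 0 or self.fov_radius <= 0:
            raise ValueError("pixel_size and fov_radius must be positive")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def pixel_centers(self) -> np.ndarray:
        n = self.n
        return (np.arange(n) + 0.5 - n / 2.0) * self.pixel_size

    def fov_mask(self, radius: float | None = None) -> np.ndarray:
        r = self.fov_radius if radius is None else radius
        c = self.pixel_centers()
        xx, yy = np.meshgrid(c, c)
        return xx * xx + yy * yy <= r * r

    def masked(self, radius: float | None = None, fill: float = 0.0) -> "ReconImage":
        """Copy with pixels outside the FOV set to ``fill``."""
        out = self.values.copy()
        out[~self.fov_mask(radius)] = fill
        return replace(self, values=out)

    def to_hu(self) -> "ReconImage":
        if self.unit == "HU":
            return self
        return replace(self, values=mu_to_hu(self.values, self.mu_water), unit="HU")

    def to_mu(self) -> "ReconImage":
        if self.unit == "mu":
            return self
        return replace(self, values=hu_to_mu(self.values, self.mu_water), unit="mu")

    def copy(self) -> "ReconImage":
        return replace(self, values=self.values.copy())


def mu_to_hu(mu: np.ndarray, mu_water: float = DEFAULT_MU_WATER) -> np.ndarray:
    """HU = 1000 (mu - mu_water) / mu_water."""
    return 1000.0 * (np.asarray(mu) - mu_water) / mu_water


def hu_to_mu(hu: np.ndarray, mu_water: float = DEFAULT_MU_WATER) -> np.ndarray:
    return mu_water * (1.0 + np.asarray(hu) / 1000.0)
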