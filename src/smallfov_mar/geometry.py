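"""Fan-beam acquisition geometry.

A :class:`ScanGeometry` describes a 2-D fan-beam system with a flat
(equispaced) detector: source and detector rotate around the iso-center,
the detector line is perpendicular to the central ray, and the image is
reconstructed on a square grid centered at iso.

Two named presets are shipped, ``conventional`` and ``dental``, matching a
whole-body CT and a dental CBCT slice geometry respectively, plus scaled
``*_fast`` variants (half views / half detector / quarter image area) for
quick experiments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = ["ScanGeometry", "GEOMETRY_PRESETS", "get_geometry"]


@dataclass(frozen=True)
class ScanGeometry:
    """Fan-beam scan geometry for a flat detector.

    Parameters
    ----------
    source_to_iso : float
        Source to iso-center distance (mm).
    detector_to_iso : float
        Detector to iso-center distance (mm).
    n_views : int
        Number of projection views, uniformly spaced over ``angular_range``.
    detector_cell_size : float
        Width of one detector cell (mm).
    n_detectors : int
        Number of detector cells.
    image_extent : float
        Side length of the square reconstruction grid (mm).
    image_matrix : int
        Number of pixels per image side.
    angular_range : float
        Total angular coverage in radians (default full rotation).
    fov_diameter : float or None
        Diameter of the circular field of view used for masking/cropping.
        Defaults to ``image_extent``.
    """

    source_to_iso: float
    detector_to_iso: float
    n_views: int
    detector_cell_size: float
    n_detectors: int
    image_extent: float
    image_matrix: int
    angular_range: float = 2.0 * math.pi
    fov_diameter: float | None = None

    def __post_init__(self) -> None:
        for name in ("source_to_iso", "detector_to_iso", "detector_cell_size",
                     "image_extent", "angular_range"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("n_views", "n_detectors", "image_matrix"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer")
        if self.fov_diameter is None:
            object.__setattr__(self, "fov_diameter", self.image_extent)
        elif self.fov_diameter <= 0:
            raise ValueError("fov_diameter must be strictly positive")

    # ------------------------------------------------------------------ #
    @property
    def pixel_size(self) -> float:
        """Image pixel size in mm (``image_extent / image_matrix``)."""
        return self.image_extent / self.image_matrix

    @property
    def source_to_detector(self) -> float:
        return self.source_to_iso + self.detector_to_iso

    @property
    def fov_radius(self) -> float:
        return self.fov_diameter / 2.0

    def detector_width(self) -> float:
        """Physical detector width in mm."""
        return self.n_detectors * self.detector_cell_size

    def detector_fov_diameter(self) -> float:
        """Diameter of the region fully sampled by every view (mm).

        This is the detector-limited field of view
        ``2 * SID * sin(atan(W/2 / SDD))`` — the "small FOV" of a truncated
        acquisition. It may be smaller than ``fov_diameter`` when the
        reconstruction grid extends beyond the sampled region.
        """
        gamma = math.atan(0.5 * self.detector_width() / self.source_to_detector)
        return 2.0 * self.source_to_iso * math.sin(gamma)

    def small_fov_radius(self) -> float:
        """Radius of the effective small FOV: detector-limited, capped by
        ``fov_diameter``."""
        return min(self.fov_radius, self.detector_fov_diameter() / 2.0)

    def view_angles(self) -> np.ndarray:
        """View angles in radians, endpoint excluded."""
        return np.arange(self.n_views) * (self.angular_range / self.n_views)

    def detector_coords(self, oversample: int = 1) -> np.ndarray:
        """Signed detector cell-center coordinates (mm) on the physical
        detector line; zero at the central ray."""
        n = self.n_detectors * oversample
        du = self.detector_cell_size / oversample
        return (np.arange(n) - (n - 1) / 2.0) * du

    def pixel_centers(self) -> np.ndarray:
        """1-D pixel-center coordinates (mm), x right / y up, origin at iso."""
        n = self.image_matrix
        return (np.arange(n) + 0.5 - n / 2.0) * self.pixel_size

    def fov_mask(self, radius: float | None = None) -> np.ndarray:
        """Boolean mask of pixels inside a circular FOV (default
        ``fov_radius``)."""
        r = self.fov_radius if radius is None else radius
        c = self.pixel_centers()
        xx, yy = np.meshgrid(c, c)
        return xx * xx + yy * yy <= r * r

    # ------------------------------------------------------------------ #
    def replace(self, **kwargs) -> "ScanGeometry":
        d = asdict(self)
        d.update(kwargs)
        return ScanGeometry(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(**d)

    @classmethod
    def from_config(cls, path: str | Path) -> "ScanGeometry":
        """Load a geometry from a JSON or YAML config file."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


def _preset(**kw) -> ScanGeometry:
    return ScanGeometry(**kw)


GEOMETRY_PRESETS: dict[str, ScanGeometry] = {
    # Whole-body CT slice geometry.
    "conventional": _preset(
        source_to_iso=700.0, detector_to_iso=500.0, n_views=720,
        detector_cell_size=0.388, n_detectors=1024,
        image_extent=358.4, image_matrix=512,
    ),
    # Dental CBCT slice geometry.
    "dental": _preset(
        source_to_iso=500.0, detector_to_iso=200.0, n_views=720,
        detector_cell_size=0.388, n_detectors=512,
        image_extent=143.36, image_matrix=512,
    ),
    # Scaled variants: same FOV and physics, half the angular/detector
    # sampling and half the image resolution, for quick experiments.
    "conventional_fast": _preset(
        source_to_iso=700.0, detector_to_iso=500.0, n_views=360,
        detector_cell_size=0.776, n_detectors=512,
        image_extent=358.4, image_matrix=256,
    ),
    "dental_fast": _preset(
        source_to_iso=500.0, detector_to_iso=200.0, n_views=360,
        detector_cell_size=0.776, n_detectors=256,
        image_extent=143.36, image_matrix=256,
    ),
}


def get_geometry(name_or_path: str) -> ScanGeometry:
    """Resolve a geometry preset name or a JSON/YAML config path."""
    if name_or_path in GEOMETRY_PRESETS:
        return GEOMETRY_PRESETS[name_or_path]
    p = Path(name_or_path)
    if p.exists():
        return ScanGeometry.from_config(p)
    raise KeyError(
        f"unknown geometry {name_or_path!r}; presets: {sorted(GEOMETRY_PRESETS)}"
    )
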