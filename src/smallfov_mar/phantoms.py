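"""Synthetic test objects with known ground truth.

Phantoms are triples of per-material density-fraction maps (water, bone,
metal) on the reconstruction grid; 1.0 means nominal material density.
Shapes are rasterized with sub-pixel supersampling so boundary pixels carry
fractional coverage (line integrals through analytic shapes then match
closed forms to well under 1%). Overlapping shapes follow later-wins
semantics: a newly painted shape takes ownership of its support.

The bench-style disk phantom is a 25 cm water disk with 32 cylinders of
5 mm diameter along its perimeter; a requested number of cylinders inside
and outside the small FOV are metal, the rest bone. The phantom is placed
slightly off iso-center by default so that, with the conventional scan
geometry, part of the cylinder ring lies inside the detector-limited small
FOV and part outside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .containers import ReconImage
from .geometry import ScanGeometry
from .physics import (AttenuationTable, NoiseModel, Spectrum, MATERIALS,
                      simulate_measurement)
from .projector import fbp_reconstruct

__all__ = ["MaterialPhantom", "make_disk_phantom", "make_ellipse_phantom",
           "make_reference_image", "DEFAULT_DISK_OFFSET"]

#: default disk-phantom center offset (mm); off-center so the cylinder ring
#: straddles the detector-limited small FOV of the conventional geometry
DEFAULT_DISK_OFFSET = (-15.0, 0.0)

_SUPERSAMPLE = 4


@dataclass
class MaterialPhantom:
    """Per-material 2-D density-fraction maps on a shared grid."""

    water_map: np.ndarray
    bone_map: np.ndarray
    metal_map: np.ndarray
    pixel_size: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("water_map", "bone_map", "metal_map"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, arr)
        if not (self.water_map.shape == self.bone_map.shape
                == self.metal_map.shape):
            raise ValueError("material maps must be congruent")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n(self) -> int:
        return self.water_map.shape[0]

    def material_maps(self) -> dict[str, np.ndarray]:
        return {"water": self.water_map, "bone": self.bone_map,
                "metal": self.metal_map}

    def pixel_centers(self) -> np.ndarray:
        n = self.n
        return (np.arange(n) + 0.5 - n / 2.0) * self.pixel_size

    def cropped_to_fov(self, radius: float) -> "MaterialPhantom":
        """Zero all material outside a centered circle of ``radius`` mm."""
        c = self.pixel_centers()
        xx, yy = np.meshgrid(c, c)
        inside = (xx * xx + yy * yy) <= radius * radius
        return MaterialPhantom(
            self.water_map * inside, self.bone_map * inside,
            self.metal_map * inside, self.pixel_size,
            {**self.metadata, "cropped_to_radius_mm": radius})

    def without_metal(self) -> "MaterialPhantom":
        return MaterialPhantom(self.water_map, self.bone_map,
                               np.zeros_like(self.metal_map), self.pixel_size,
                               {**self.metadata, "metal_removed": True})


# --------------------------------------------------------------------- #
def _ellipse_coverage(n: int, pix: float, cx: float, cy: float,
                      a: float, b: float, angle: float = 0.0,
                      soft_edge: float = 0.0,
                      ss: int = _SUPERSAMPLE) -> np.ndarray:
    """Fractional pixel coverage of an ellipse (center mm, semi-axes mm,
    rotation radians), computed on a bounding box with ss x ss subsampling.

    ``soft_edge`` > 0 replaces the hard boundary by a cosine taper of that
    width (mm), producing a band-limited shape."""
    half = 0.5 * n * pix
    rmax = max(a, b) + soft_edge
    # bounding box in pixel indices
    i0 = max(0, int((cx - rmax + half) / pix) - 1)
    i1 = min(n, int((cx + rmax + half) / pix) + 2)
    j0 = max(0, int((cy - rmax + half) / pix) - 1)
    j1 = min(n, int((cy + rmax + half) / pix) + 2)
    out = np.zeros((n, n))
    if i1 <= i0 or j1 <= j0:
        return out
    sub = (np.arange(ss) + 0.5) / ss  # subpixel offsets in [0,1)
    xs = (np.arange(i0, i1)[:, None] + sub[None, :]) * pix - half
    ys = (np.arange(j0, j1)[:, None] + sub[None, :]) * pix - half
    X = xs.reshape(-1)[None, :] - cx   # (1, nx*ss)
    Y = ys.reshape(-1)[:, None] - cy   # (ny*ss, 1)
    ca, sa = math.cos(angle), math.sin(angle)
    U = (X * ca + Y * sa) / a
    V = (-X * sa + Y * ca) / b
    rho = np.sqrt(U * U + V * V)
    if soft_edge > 0:
        # approximate signed boundary distance via the radial scaling
        dist = (rho - 1.0) * min(a, b)
        t = np.clip((dist + soft_edge) / soft_edge, 0.0, 1.0)
        vals = 0.5 * (1.0 + np.cos(np.pi * t))
        vals[dist <= -soft_edge] = 1.0
    else:
        vals = (rho <= 1.0).astype(np.float64)
    cov = vals.reshape(j1 - j0, ss, i1 - i0, ss).mean(axis=(1, 3))
    out[j0:j1, i0:i1] = cov
    return out


def _paint(maps: dict[str, np.ndarray], material: str, coverage: np.ndarray,
           density: float) -> None:
    """Later-wins painting: the new shape takes over its covered fraction."""
    for m in maps:
        maps[m] *= (1.0 - coverage)
    maps[material] += density * coverage


def make_ellipse_phantom(spec: list[dict], geometry: ScanGeometry) -> MaterialPhantom:
    """Rasterize a list of ellipses into a phantom.

    Each entry: ``{"material": "water"|"bone"|"metal", "center": (x, y) mm,
    "axes": (a, b) mm, "angle": radians (optional), "density": fraction
    (optional, default 1.0), "soft_edge": cosine-taper width in mm
    (optional, default 0 = hard antialiased edge)}``. Later entries win at
    overlaps.
    """
    n, pix = geometry.image_matrix, geometry.pixel_size
    maps = {m: np.zeros((n, n)) for m in MATERIALS}
    for e in spec:
        mat = e["material"]
        if mat not in MATERIALS:
            raise ValueError(f"unknown material {mat!r}")
        cx, cy = e["center"]
        a, b = e["axes"]
        cov = _ellipse_coverage(n, pix, cx, cy, a, b, e.get("angle", 0.0),
                                e.get("soft_edge", 0.0))
        _paint(maps, mat, cov, e.get("density", 1.0))
    return MaterialPhantom(maps["water"], maps["bone"], maps["metal"], pix,
                           {"ellipses": list(spec)})


def make_disk_phantom(n_inside_metals: int, n_outside_metals: int,
                      geometry: ScanGeometry, seed: int = 0,
                      center_offset: tuple[float, float] = DEFAULT_DISK_OFFSET,
                      disk_diameter: float = 250.0,
                      n_cylinders: int = 32,
                      cylinder_diameter: float = 5.0,
                      fov_margin: float = 3.0,
                      metal_density: float = 0.12,
                      metal_slot_indices=None) -> MaterialPhantom:
    """Bench-style disk phantom: water disk with a ring of perimeter
    cylinders, a chosen number of which are metal inside / outside the
    small FOV (the remainder are bone).

    Cylinder slots sit on a ring 5 mm inside the disk edge, uniformly
    spaced in angle. "Inside"/"outside" is judged against the
    detector-limited small FOV of ``geometry``: a slot is eligible as an
    inside (outside) metal only when the whole cylinder clears the FOV
    boundary by ``fov_margin`` mm, so metals straddling the boundary never
    occur; metal slots are chosen deterministically under ``seed``.

    ``metal_density`` is the density fraction of the metal inserts relative
    to the nominal (gold) metal of the attenuation table; the default 0.12
    emulates stainless-steel-like rods (steel attenuates roughly 12% as
    strongly as solid gold at diagnostic energies), the kind of insert a
    bench phantom actually carries. Metal rays are then heavily attenuated
    and noisy but not fully photon-starved.

    ``metal_slot_indices`` overrides the seeded choice with explicit slot
    numbers (0..n_cylinders-1); the inside/outside counts are then derived
    from the geometry instead of enforced.
    """
    if n_inside_metals < 0 or n_outside_metals < 0:
        raise ValueError("metal counts must be non-negative")
    if n_inside_metals + n_outside_metals > n_cylinders:
        raise ValueError("requested metals exceed available cylinder slots")
    n, pix = geometry.image_matrix, geometry.pixel_size
    cx0, cy0 = center_offset
    disk_r = disk_diameter / 2.0
    cyl_r = cylinder_diameter / 2.0
    ring_r = disk_r - cyl_r - 2.5
    fov_r = geometry.small_fov_radius()

    angles = 2.0 * math.pi * np.arange(n_cylinders) / n_cylinders
    pos = np.stack([cx0 + ring_r * np.cos(angles),
                    cy0 + ring_r * np.sin(angles)], axis=1)
    dist = np.hypot(pos[:, 0], pos[:, 1])
    if metal_slot_indices is not None:
        metal_slots = set(int(k) for k in metal_slot_indices)
        if metal_slots and not all(0 <= k < n_cylinders for k in metal_slots):
            raise ValueError("metal slot index out of range")
        n_inside_metals = int(np.sum(dist[sorted(metal_slots)] <= fov_r)) \
            if metal_slots else 0
        n_outside_metals = len(metal_slots) - n_inside_metals
    else:
        inside_slots = np.flatnonzero(dist <= fov_r - cyl_r - fov_margin)
        outside_slots = np.flatnonzero(dist >= fov_r + cyl_r + fov_margin)
        if n_inside_metals > inside_slots.size:
            raise ValueError(
                f"only {inside_slots.size} cylinder slots lie inside the "
                f"small FOV (requested {n_inside_metals} inside metals)")
        if n_outside_metals > outside_slots.size:
            raise ValueError(
                f"only {outside_slots.size} cylinder slots lie outside the "
                f"small FOV (requested {n_outside_metals} outside metals)")
        rng = np.random.default_rng(seed)
        metal_slots = set(rng.choice(inside_slots, n_inside_metals,
                                     replace=False).tolist())
        metal_slots |= set(rng.choice(outside_slots, n_outside_metals,
                                      replace=False).tolist())

    maps = {m: np.zeros((n, n)) for m in MATERIALS}
    _paint(maps, "water", _ellipse_coverage(n, pix, cx0, cy0, disk_r, disk_r),
           1.0)
    for k in range(n_cylinders):
        mat = "metal" if k in metal_slots else "bone"
        cov = _ellipse_coverage(n, pix, pos[k, 0], pos[k, 1], cyl_r, cyl_r)
        _paint(maps, mat, cov, metal_density if mat == "metal" else 1.0)

    meta = {
        "phantom": "disk",
        "center_offset_mm": list(center_offset),
        "disk_diameter_mm": disk_diameter,
        "cylinder_diameter_mm": cylinder_diameter,
        "ring_radius_mm": ring_r,
        "small_fov_radius_mm": fov_r,
        "cylinder_positions_mm": pos.tolist(),
        "metal_slots": sorted(metal_slots),
        "metal_density": metal_density,
        "n_inside_metals": n_inside_metals,
        "n_outside_metals": n_outside_metals,
        "seed": seed,
    }
    return MaterialPhantom(maps["water"], maps["bone"], maps["metal"], pix, meta)


def make_reference_image(phantom: MaterialPhantom, geometry: ScanGeometry,
                         spectrum: Spectrum | None = None,
                         atten: AttenuationTable | None = None,
                         noise: NoiseModel | None = None,
                         filter_window: str = "hann") -> ReconImage:
    """Truncation-free, metal-free reference reconstruction.

    All material outside the small FOV is removed (so no truncation occurs)
    along with all metal; the cropped object is then simulated and
    reconstructed. This is the ground-truth image against which NMSE/SSIM
    of the MAR pipelines are measured.
    """
    fov_r = geometry.small_fov_radius()
    cropped = phantom.cropped_to_fov(fov_r).without_metal()
    sino = simulate_measurement(cropped, geometry, spectrum, atten, noise)
    img = fbp_reconstruct(sino, filter_window=filter_window, fov_radius=fov_r)
    return img.masked()
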