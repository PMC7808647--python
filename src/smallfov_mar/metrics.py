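"""Image-quality metrics and the disk-phantom comparison harness.

NMSE is the mean squared difference normalized by the product of the two
image means over a rectangular ROI:

    NMSE = (1/N) sum_k (f(k) - f_ref(k))^2 / (mean(f) * mean(f_ref))

SSIM is evaluated as a single global window over the ROI (not the usual
sliding-window variant):

    SSIM = (2 mu_A mu_B + C1)(2 sigma_AB + C2)
           / ((mu_A^2 + mu_B^2 + C1)(sigma_A^2 + sigma_B^2 + C2))

with C1 = (0.01 L)^2, C2 = (0.03 L)^2 and L the dynamic range of the
reference ROI by default. A sliding-window mode is available as a
non-default extra.

Metrics default to linear-attenuation images (strictly positive in tissue,
so the NMSE mean product is safe); HU images can be passed but risk a
near-zero mean product, which raises.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import ReconImage
from .geometry import ScanGeometry, get_geometry

__all__ = ["ROI", "MetricConfig", "nmse", "ssim", "ExperimentConfig",
           "run_comparison", "summarize_comparison"]


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest, 0-based half-open pixel bounds."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("ROI must be non-empty")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI must be within image bounds")

    def extract(self, image: ReconImage | np.ndarray) -> np.ndarray:
        arr = image.values if isinstance(image, ReconImage) else np.asarray(image)
        if self.row0 + self.height > arr.shape[0] \
                or self.col0 + self.width > arr.shape[1]:
            raise ValueError("ROI exceeds image bounds")
        return arr[self.row0:self.row0 + self.height,
                   self.col0:self.col0 + self.width]

    @classmethod
    def centered(cls, n: int, side: int) -> "ROI":
        """Centered square ROI of ``side`` pixels in an n x n image."""
        side = min(side, n)
        r0 = (n - side) // 2
        return cls(r0, r0, side, side)

    @classmethod
    def centered_fov_fraction(cls, image: ReconImage,
                              fraction: float = 0.5) -> "ROI":
        """Centered square whose side is ``fraction`` of the FOV diameter."""
        side = int(round(fraction * 2.0 * image.fov_radius / image.pixel_size))
        return cls.centered(image.n, max(side, 1))

    @classmethod
    def square_at_mm(cls, image: ReconImage, center_mm: tuple[float, float],
                     side_mm: float) -> "ROI":
        """Square ROI of ``side_mm`` centered at physical coordinates
        ``center_mm`` (x right / y up, origin at iso), clipped to the image."""
        n, pix = image.n, image.pixel_size
        side = max(1, min(n, int(round(side_mm / pix))))
        cx, cy = center_mm
        icol = int(round(cx / pix + n / 2.0 - 0.5))
        irow = int(round(cy / pix + n / 2.0 - 0.5))
        col0 = min(max(icol - side // 2, 0), n - side)
        row0 = min(max(irow - side // 2, 0), n - side)
        return cls(row0, col0, side, side)


@dataclass
class MetricConfig:
    """SSIM stabilization constants; computed from the reference dynamic
    range when not given explicitly."""

    C1: float | None = None
    C2: float | None = None
    dynamic_range: float | None = None
    k1: float = 0.01
    k2: float = 0.03

    def constants(self, ref_roi: np.ndarray) -> tuple[float, float]:
        L = self.dynamic_range
        if L is None:
            L = float(np.ptp(ref_roi))
            if L <= 0:
                L = max(abs(float(ref_roi.flat[0])), 1.0)
        c1 = (self.k1 * L) ** 2 if self.C1 is None else self.C1
        c2 = (self.k2 * L) ** 2 if self.C2 is None else self.C2
        if c1 <= 0 or c2 <= 0:
            raise ValueError("C1 and C2 must be > 0")
        return c1, c2


def _roi_pair(f, f_ref, roi: ROI | None, exclude: np.ndarray | None = None):
    a = f.values if isinstance(f, ReconImage) else np.asarray(f, dtype=float)
    b = f_ref.values if isinstance(f_ref, ReconImage) else \
        np.asarray(f_ref, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a grid")
    if exclude is not None:
        exclude = np.asarray(exclude, dtype=bool)
        if exclude.shape != a.shape:
            raise ValueError("exclusion mask must match the image grid")
    if roi is not None:
        a, b = roi.extract(a), roi.extract(b)
        exclude = roi.extract(exclude) if exclude is not None else None
    if exclude is not None:
        keep = ~exclude
        if not keep.any():
            raise ValueError("exclusion mask removes the whole ROI")
        a, b = a[keep], b[keep]
    return a.astype(np.float64), b.astype(np.float64)


def nmse(f, f_ref, roi: ROI | None = None,
         exclude: np.ndarray | None = None) -> float:
    """Normalized mean squared error of ``f`` against ``f_ref`` over ``roi``.

    ``exclude`` (full-image boolean mask) drops pixels from the statistics,
    typically the metal support when scoring MAR images against a
    metal-free reference.
    """
    a, b = _roi_pair(f, f_ref, roi, exclude)
    denom = a.mean() * b.mean()
    if abs(denom) < 1e-30:
        raise ValueError("NMSE undefined: product of ROI means is ~0 "
                         "(use attenuation-domain images)")
    return float(np.mean((a - b) ** 2) / denom)


def ssim(A, B, roi: ROI | None = None,
         cfg: MetricConfig | None = None, mode: str = "global",
         exclude: np.ndarray | None = None) -> float:
    """Structural similarity between ``A`` and ``B`` over ``roi``.

    ``mode="global"`` (default) evaluates the formula once with ROI-wide
    statistics. ``mode="windowed"`` averages a sliding 7x7 uniform window
    (the common image-processing variant, provided for convenience;
    ``exclude`` is not supported there).
    """
    cfg = cfg or MetricConfig()
    if mode == "global":
        a, b = _roi_pair(A, B, roi, exclude)
        c1, c2 = cfg.constants(b)
        mu_a, mu_b = a.mean(), b.mean()
        va, vb = a.var(), b.var()
        cov = ((a - mu_a) * (b - mu_b)).mean()
        return float((2 * mu_a * mu_b + c1) * (2 * cov + c2)
                     / ((mu_a ** 2 + mu_b ** 2 + c1) * (va + vb + c2)))
    if mode == "windowed":
        if exclude is not None:
            raise ValueError("exclude is not supported in windowed mode")
        a, b = _roi_pair(A, B, roi)
        c1, c2 = cfg.constants(b)
        return _ssim_windowed(a, b, c1, c2)
    raise ValueError(f"unknown SSIM mode {mode!r}")


def _ssim_windowed(a, b, c1, c2, size: int = 7) -> float:
    f = lambda x: ndimage.uniform_filter(x, size=size, mode="reflect")
    mu_a, mu_b = f(a), f(b)
    va = f(a * a) - mu_a ** 2
    vb = f(b * b) - mu_b ** 2
    cov = f(a * b) - mu_a * mu_b
    s = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)
         / ((mu_a ** 2 + mu_b ** 2 + c1) * (va + vb + c2)))
    return float(s.mean())


# --------------------------------------------------------------------- #
# experiment harness
# --------------------------------------------------------------------- #
def _artifact_roi(phantom, reference: ReconImage, fraction: float) -> ROI:
    """Scoring region for the disk experiment: a square of ``fraction`` of
    the FOV diameter centered between the FOV center and the inside-metal
    cylinders, so the scored area spans the streak-affected region and the
    cylinder boundaries (the area the bench comparison marks)."""
    meta = phantom.metadata
    slots = meta.get("metal_slots", [])
    pos = np.asarray(meta.get("cylinder_positions_mm", []), dtype=float)
    fov_r = reference.fov_radius
    side = fraction * 2.0 * fov_r
    if len(slots) and pos.size:
        mpos = pos[slots]
        inside = mpos[np.hypot(mpos[:, 0], mpos[:, 1]) <= fov_r]
        if inside.size:
            cx, cy = inside.mean(axis=0) / 2.0  # midway to the FOV center
            return ROI.square_at_mm(reference, (cx, cy), side)
    return ROI.centered_fov_fraction(reference, fraction)
@dataclass
class ExperimentConfig:
    """Disk-phantom comparison: pipelines x methods x outside-metal counts
    x noise seeds, all scored against the cropped metal-free reference."""

    geometry: str = "conventional_fast"
    n_inside_metals: int = 3
    outside_counts: tuple[int, ...] = (1, 2, 3)
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    pipelines: tuple[str, ...] = ("previous", "proposed")
    methods: tuple[str, ...] = ("lmar", "nmar")
    I0: float = 1e5
    noise: bool = True
    # square inscribed in the small FOV (side = diameter / sqrt(2)), so the
    # scored region spans the streak-affected area
    roi_fraction: float = 0.7071
    phantom_seed_offset: int = 0


def run_comparison(cfg: ExperimentConfig = ExperimentConfig()) -> pd.DataFrame:
    """Run the full disk-phantom suite and return one row per
    (outside-metal count, pipeline, method, seed) with NMSE and SSIM."""
    from .physics import (AttenuationTable, NoiseModel, Spectrum,
                          effective_mu_water, simulate_measurement)
    from .phantoms import make_disk_phantom, make_reference_image
    from .truncation import default_truncation_config, \
        truncation_corrected_recon
    from .mar import (MARConfig, compute_trace, previous_pipeline,
                      proposed_pipeline, segment_metal)

    geometry = get_geometry(cfg.geometry)
    spectrum = Spectrum.kramers_120kvp()
    atten = AttenuationTable.default()
    mu_w = effective_mu_water(spectrum, atten)
    mar_cfg = MARConfig(mu_water=mu_w)
    trunc_cfg = default_truncation_config(geometry)

    rows = []
    for n_out in cfg.outside_counts:
        for seed in cfg.seeds:
            pseed = cfg.phantom_seed_offset + seed
            phantom = make_disk_phantom(cfg.n_inside_metals, n_out,
                                        geometry, seed=pseed)
            meas_noise = NoiseModel(I0=cfg.I0, seed=1000 * pseed + n_out,
                                    enabled=cfg.noise)
            ref_noise = NoiseModel(I0=cfg.I0, seed=1000 * pseed + n_out + 500,
                                   enabled=cfg.noise)
            measured = simulate_measurement(phantom, geometry, spectrum,
                                            atten, meas_noise)
            reference = make_reference_image(phantom, geometry, spectrum,
                                             atten, ref_noise)
            roi = _artifact_roi(phantom, reference, cfg.roi_fraction)
            # score artifact, not the metal itself: the (ground-truth)
            # metal support is excluded from the statistics
            exclude = ndimage.binary_dilation(phantom.metal_map > 0,
                                              iterations=2)

            # shared across pipelines and methods
            trunc_image = truncation_corrected_recon(
                measured, geometry, trunc_cfg,
                filter_window=mar_cfg.synthesis_filter_window)
            metal_mask = segment_metal(trunc_image, mar_cfg)
            trace = compute_trace(metal_mask, geometry, mar_cfg.oversample,
                                  mar_cfg.trace_dilation)
            synthesized = None
            for pipeline, method in itertools.product(cfg.pipelines,
                                                      cfg.methods):
                if pipeline == "previous":
                    res = previous_pipeline(
                        measured, geometry, trunc_cfg, mar_cfg, method,
                        trunc_image=trunc_image, metal_mask=metal_mask,
                        trace=trace)
                else:
                    res = proposed_pipeline(
                        measured, geometry, trunc_cfg, mar_cfg, method,
                        trunc_image=trunc_image, metal_mask=metal_mask,
                        trace=trace, synthesized=synthesized)
                    synthesized = res.work_sinogram
                rows.append({
                    "phantom_variant": "disk",
                    "n_outside_metals": n_out,
                    "pipeline": pipeline,
                    "method": method,
                    "seed": seed,
                    "nmse": nmse(res.image, reference, roi, exclude=exclude),
                    "ssim": ssim(res.image, reference, roi, exclude=exclude),
                })
    return pd.DataFrame(rows)


def summarize_comparison(df: pd.DataFrame) -> pd.DataFrame:
    """Seed-averaged table: one row per (outside-metal count, method),
    previous/proposed columns for NMSE and SSIM."""
    g = df.groupby(["n_outside_metals", "method", "pipeline"])[["nmse", "ssim"]] \
        .mean().reset_index()
    wide = g.pivot(index=["n_outside_metals", "method"], columns="pipeline",
                   values=["nmse", "ssim"])
    wide.columns = [f"{metric}_{pipe}" for metric, pipe in wide.columns]
    return wide.reset_index()
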