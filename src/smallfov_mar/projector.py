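"""Fan-beam system model: forward projection, adjoint, and weighted FBP.

The projector is ray-driven: each ray (source to detector-cell center) is
clipped to the image square and sampled at a fixed sub-pixel step with
bilinear interpolation. The backprojector used by the adjoint test is the
exact matrix transpose of the projector (same rays, same steps, bilinear
*scatter* instead of gather), so ``<Ax, y> == <x, A^T y>`` holds to float
rounding.

Reconstruction is the standard flat-detector fan-beam weighted FBP:
detector coordinates are rebinned to a virtual detector through iso,
cosine-weighted, ramp-filtered along detector rows (zero-padded FFT,
optional Hann apodization), and backprojected with the 1/U^2 distance
weight. A full rotation is assumed; each ray is covered twice over 2*pi,
which the filter's 1/2 factor accounts for.

Geometry convention: source at angle ``beta`` sits at
``(R cos(beta), R sin(beta))``; the flat detector line passes at
``detector_to_iso`` on the far side, perpendicular to the central ray;
image origin at iso, x right / y up, pixel centers at
``(i + 0.5 - n/2) * pixel_size``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit
from scipy import fft as sp_fft

from .containers import ReconImage, Sinogram
from .geometry import ScanGeometry

__all__ = [
    "forward_project", "backproject_adjoint", "fbp_reconstruct",
    "rebin_detector", "ramp_filter_rows",
]

#: ray sampling step as a fraction of the pixel size
DEFAULT_STEP_FRACTION = 0.5


# --------------------------------------------------------------------- #
# numba kernels
# --------------------------------------------------------------------- #
@njit(cache=True, fastmath=True)
def _clip_ray(sx, sy, dx, dy, half, length):
    """Clip ray s + t*d, t in [0, length], to the square [-half, half]^2.

    Returns (tmin, tmax); empty when tmin >= tmax.
    """
    tmin = 0.0
    tmax = length
    eps = 1e-12
    if abs(dx) < eps:
        if sx < -half or sx > half:
            return 1.0, 0.0
    else:
        t1 = (-half - sx) / dx
        t2 = (half - sx) / dx
        lo = min(t1, t2)
        hi = max(t1, t2)
        if lo > tmin:
            tmin = lo
        if hi < tmax:
            tmax = hi
    if abs(dy) < eps:
        if sy < -half or sy > half:
            return 1.0, 0.0
    else:
        t1 = (-half - sy) / dy
        t2 = (half - sy) / dy
        lo = min(t1, t2)
        hi = max(t1, t2)
        if lo > tmin:
            tmin = lo
        if hi < tmax:
            tmax = hi
    return tmin, tmax


@njit(cache=True, fastmath=True)
def _fp_kernel(img, pix, betas, R, Dd, ucoords, step):
    n = img.shape[0]
    half = 0.5 * n * pix
    n_views = betas.shape[0]
    n_bins = ucoords.shape[0]
    out = np.zeros((n_views, n_bins))
    for v in range(n_views):
        cb = math.cos(betas[v])
        sb = math.sin(betas[v])
        sx = R * cb
        sy = R * sb
        for d in range(n_bins):
            u = ucoords[d]
            px = -Dd * cb - u * sb
            py = -Dd * sb + u * cb
            dx = px - sx
            dy = py - sy
            length = math.sqrt(dx * dx + dy * dy)
            dx /= length
            dy /= length
            tmin, tmax = _clip_ray(sx, sy, dx, dy, half, length)
            if tmax <= tmin:
                continue
            nsteps = int((tmax - tmin) / step) + 1
            h = (tmax - tmin) / nsteps
            t = tmin + 0.5 * h
            acc = 0.0
            for _ in range(nsteps):
                fx = (sx + t * dx) / pix + 0.5 * n - 0.5
                fy = (sy + t * dy) / pix + 0.5 * n - 0.5
                ix = int(math.floor(fx))
                iy = int(math.floor(fy))
                ax = fx - ix
                ay = fy - iy
                if 0 <= iy < n and 0 <= ix < n:
                    acc += (1 - ax) * (1 - ay) * img[iy, ix]
                if 0 <= iy < n and 0 <= ix + 1 < n:
                    acc += ax * (1 - ay) * img[iy, ix + 1]
                if 0 <= iy + 1 < n and 0 <= ix < n:
                    acc += (1 - ax) * ay * img[iy + 1, ix]
                if 0 <= iy + 1 < n and 0 <= ix + 1 < n:
                    acc += ax * ay * img[iy + 1, ix + 1]
                t += h
            out[v, d] = acc * h
    return out


@njit(cache=True, fastmath=True)
def _bp_adjoint_kernel(sino, n, pix, betas, R, Dd, ucoords, step):
    """Exact transpose of ``_fp_kernel``."""
    half = 0.5 * n * pix
    n_views = betas.shape[0]
    n_bins = ucoords.shape[0]
    img = np.zeros((n, n))
    for v in range(n_views):
        cb = math.cos(betas[v])
        sb = math.sin(betas[v])
        sx = R * cb
        sy = R * sb
        for d in range(n_bins):
            val = sino[v, d]
            if val == 0.0:
                continue
            u = ucoords[d]
            px = -Dd * cb - u * sb
            py = -Dd * sb + u * cb
            dx = px - sx
            dy = py - sy
            length = math.sqrt(dx * dx + dy * dy)
            dx /= length
            dy /= length
            tmin, tmax = _clip_ray(sx, sy, dx, dy, half, length)
            if tmax <= tmin:
                continue
            nsteps = int((tmax - tmin) / step) + 1
            h = (tmax - tmin) / nsteps
            w = val * h
            t = tmin + 0.5 * h
            for _ in range(nsteps):
                fx = (sx + t * dx) / pix + 0.5 * n - 0.5
                fy = (sy + t * dy) / pix + 0.5 * n - 0.5
                ix = int(math.floor(fx))
                iy = int(math.floor(fy))
                ax = fx - ix
                ay = fy - iy
                if 0 <= iy < n and 0 <= ix < n:
                    img[iy, ix] += (1 - ax) * (1 - ay) * w
                if 0 <= iy < n and 0 <= ix + 1 < n:
                    img[iy, ix + 1] += ax * (1 - ay) * w
                if 0 <= iy + 1 < n and 0 <= ix < n:
                    img[iy + 1, ix] += (1 - ax) * ay * w
                if 0 <= iy + 1 < n and 0 <= ix + 1 < n:
                    img[iy + 1, ix + 1] += ax * ay * w
                t += h
    return img


@njit(cache=True, fastmath=True)
def _bp_fbp_kernel(q, betas, R, s0, ds, n, pix, dbeta):
    """Pixel-driven distance-weighted backprojection of filtered rows ``q``
    sampled on the virtual (iso-centered) detector grid ``s0 + k*ds``."""
    n_views, n_s = q.shape
    img = np.zeros((n, n))
    for v in range(n_views):
        cb = math.cos(betas[v])
        sb = math.sin(betas[v])
        for iy in range(n):
            y = (iy + 0.5 - 0.5 * n) * pix
            for ix in range(n):
                x = (ix + 0.5 - 0.5 * n) * pix
                dal = R - (x * cb + y * sb)
                if dal <= 1e-6:
                    continue
                s = (-x * sb + y * cb) * R / dal
                fs = (s - s0) / ds
                i0 = int(math.floor(fs))
                if i0 < 0 or i0 >= n_s - 1:
                    continue
                a = fs - i0
                U = dal / R
                img[iy, ix] += ((1 - a) * q[v, i0] + a * q[v, i0 + 1]) / (U * U)
    return img * dbeta


# --------------------------------------------------------------------- #
# public API
# --------------------------------------------------------------------- #
def _as_array_and_check(image, geometry: ScanGeometry) -> np.ndarray:
    if isinstance(image, ReconImage):
        if not math.isclose(image.pixel_size, geometry.pixel_size,
                            rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(
                f"image pixel size {image.pixel_size} does not match geometry "
                f"pixel size {geometry.pixel_size}")
        arr = image.values
    else:
        arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("image must be 2-D square")
    if arr.shape[0] != geometry.image_matrix:
        raise ValueError(
            f"image matrix {arr.shape[0]} does not match geometry "
            f"{geometry.image_matrix}")
    return np.ascontiguousarray(arr, dtype=np.float64)


def forward_project(image, geometry: ScanGeometry, oversample: int = 1,
                    step_fraction: float = DEFAULT_STEP_FRACTION) -> Sinogram:
    """Fan-beam line integrals of ``image`` (units mm^-1 -> dimensionless).

    ``oversample`` subdivides each detector cell into that many fine bins
    (the synthesized-sinogram step projects onto a finely sampled detector
    and rebins back with :func:`rebin_detector`).
    """
    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    arr = _as_array_and_check(image, geometry)
    vals = _fp_kernel(
        arr, geometry.pixel_size, geometry.view_angles(),
        geometry.source_to_iso, geometry.detector_to_iso,
        geometry.detector_coords(oversample),
        step_fraction * geometry.pixel_size,
    )
    return Sinogram(vals, geometry, domain="path_length",
                    detector_oversample=oversample)


def backproject_adjoint(sino: Sinogram,
                        step_fraction: float = DEFAULT_STEP_FRACTION) -> np.ndarray:
    """Unfiltered backprojection that is the exact transpose of
    :func:`forward_project` (for adjoint-based algorithms and testing; not
    the FBP backprojector)."""
    g = sino.geometry
    if sino.pad_bins:
        raise ValueError("adjoint backprojection expects an unpadded sinogram")
    return _bp_adjoint_kernel(
        np.ascontiguousarray(sino.values), g.image_matrix, g.pixel_size,
        g.view_angles(), g.source_to_iso, g.detector_to_iso,
        g.detector_coords(sino.detector_oversample),
        step_fraction * g.pixel_size,
    )


def ramp_filter_rows(p: np.ndarray, ds: float, window: str = "hann") -> np.ndarray:
    """Ramp-filter each row of ``p`` (sample spacing ``ds``) by zero-padded
    FFT convolution with the band-limited ramp kernel, halved for the
    double angular coverage of a full fan rotation.

    ``window``: ``"hann"`` (default) applies a Hann apodization up to
    Nyquist; ``"ramlak"`` is the bare band-limited ramp.
    """
    n_s = p.shape[-1]
    n_pad = sp_fft.next_fast_len(max(2 * n_s, 64), real=True)
    k = np.arange(n_pad)
    k = np.minimum(k, n_pad - k)  # circular symmetric kernel
    g = np.zeros(n_pad)
    g[0] = 1.0 / (8.0 * ds * ds)
    odd = (k % 2 == 1)
    g[odd] = -0.5 / (np.pi * k[odd] * ds) ** 2
    G = np.real(sp_fft.rfft(g))
    if window == "hann":
        f = sp_fft.rfftfreq(n_pad, d=ds)
        f_nyq = 0.5 / ds
        G = G * 0.5 * (1.0 + np.cos(np.pi * f / f_nyq))
    elif window != "ramlak":
        raise ValueError(f"unknown filter window {window!r}")
    P = sp_fft.rfft(p, n=n_pad, axis=-1)
    q = sp_fft.irfft(P * G, n=n_pad, axis=-1)[..., :n_s]
    return ds * q


def fbp_reconstruct(sino: Sinogram, geometry: ScanGeometry | None = None,
                    filter_window: str = "hann",
                    fov_radius: float | None = None) -> ReconImage:
    """Weighted filtered backprojection of a fan-beam sinogram.

    Accepts ``path_length`` or ``log_projection`` sinograms, including
    detector-oversampled or truncation-padded ones (the detector grid is
    taken from the sinogram itself). Output unit is mm^-1.
    """
    g = sino.geometry if geometry is None else geometry
    if geometry is not None and geometry.n_views != sino.values.shape[0]:
        raise ValueError("n_views inconsistent between sinogram and geometry")
    if sino.domain == "intensity":
        raise ValueError("FBP expects path_length or log_projection data, "
                         "not raw intensities")
    if not math.isclose(g.angular_range, 2.0 * math.pi, rel_tol=1e-6):
        raise NotImplementedError("FBP supports full-rotation scans only")
    R = g.source_to_iso
    mag = R / g.source_to_detector
    u = sino.detector_coords()
    s = u * mag                       # virtual detector through iso
    ds = (g.detector_cell_size / sino.detector_oversample) * mag
    pw = sino.values * (R / np.sqrt(R * R + s * s))   # cosine weight
    q = ramp_filter_rows(pw, ds, window=filter_window)
    img = _bp_fbp_kernel(
        np.ascontiguousarray(q), g.view_angles(), R, s[0], ds,
        g.image_matrix, g.pixel_size, g.angular_range / g.n_views,
    )
    r_fov = g.fov_radius if fov_radius is None else fov_radius
    return ReconImage(img, pixel_size=g.pixel_size, fov_radius=r_fov, unit="mu")


def rebin_detector(sino: Sinogram, factor: int) -> Sinogram:
    """Average each block of ``factor`` adjacent fine bins into one coarse
    bin (inverse of detector oversampling); domain tag preserved."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return sino.copy()
    n_bins = sino.values.shape[1]
    if n_bins % factor:
        raise ValueError(f"{n_bins} bins not divisible by factor {factor}")
    if sino.detector_oversample % factor:
        raise ValueError(
            f"oversample {sino.detector_oversample} not divisible by {factor}")
    vals = sino.values.reshape(sino.values.shape[0], n_bins // factor, factor)
    return Sinogram(vals.mean(axis=2), sino.geometry, domain=sino.domain,
                    detector_oversample=sino.detector_oversample // factor,
                    pad_bins=sino.pad_bins)
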