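"""Truncation-artifact correction by symmetric mirroring.

A truncated projection row ends abruptly at a non-zero value, which the
ramp filter turns into a bright rim at the FOV edge of the FBP image. The
correction estimates ``N_s`` virtual samples beyond each truncated detector
edge by reflecting the innermost ``N_ext`` measured samples about the edge
and tapering them with a cosine weighting so the extension decays smoothly
to zero. The weighting for pixel index ``N`` of the full
``2*N_ext + N_s``-sample window is

    w(N) = cos((N_ext - N)/N_ext * pi/2)        N = 0 .. N_ext-1
    w(N) = 1                                     N = N_ext .. N_ext+N_s-1
    w(N) = cos((N - N_s - N_ext + 1)/N_ext * pi/2)   N = N_ext+N_s .. 2*N_ext+N_s-1

i.e. a cosine rise over ``N_ext`` samples, a flat unity plateau of ``N_s``
samples, and a mirrored cosine fall. Measured samples are never modified;
the k-th synthesized sample outward mirrors the measured sample k-1 inward
from the edge (half-sample reflection) and is scaled by the k-th weight of
the falling branch, reaching zero at k = N_ext.

Defaults for the number of mirrored samples: 300 for the conventional
geometry, 150 for the dental one (scaled proportionally for reduced
detector sampling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .containers import ReconImage, Sinogram
from .geometry import ScanGeometry
from .projector import fbp_reconstruct

__all__ = ["TruncationConfig", "truncation_weight", "extend_sinogram",
           "truncation_corrected_recon", "default_truncation_config"]

#: a detector edge counts as truncated when the edge sample exceeds this
#: fraction of the row maximum
TRUNCATION_EDGE_FRACTION = 0.01


@dataclass
class TruncationConfig:
    """Mirroring extension parameters.

    N_ext: number of inner measured samples mirrored (and length of each
    cosine taper). N_s: number of samples synthesized per truncated side;
    None means N_s = N_ext (the taper then ends exactly at zero).
    """

    N_ext: int = 300
    N_s: int | None = None

    def __post_init__(self) -> None:
        if self.N_ext < 1:
            raise ValueError("N_ext must be >= 1")
        if self.N_s is None:
            self.N_s = self.N_ext
        if self.N_s < 0:
            raise ValueError("N_s must be >= 0")


def default_truncation_config(geometry: ScanGeometry,
                              reference_n_detectors: int = 1024,
                              reference_n_ext: int = 300) -> TruncationConfig:
    """N_ext scaled to the detector sampling: 300 at 1024 cells
    (conventional), 150 at 512 cells (dental), proportional otherwise."""
    n_ext = max(1, round(reference_n_ext * geometry.n_detectors
                         / reference_n_detectors))
    return TruncationConfig(N_ext=n_ext)


def truncation_weight(N, cfg: TruncationConfig):
    """Cosine-taper weighting for window index ``N`` in
    ``[0, 2*N_ext + N_s)``; scalar or array."""
    N = np.asarray(N)
    n_ext, n_s = cfg.N_ext, cfg.N_s
    total = 2 * n_ext + n_s
    if np.any(N < 0) or np.any(N >= total):
        raise ValueError(f"index out of range [0, {total})")
    w = np.ones(N.shape, dtype=np.float64)
    lo = N < n_ext
    hi = N >= n_ext + n_s
    w = np.where(lo, np.cos((n_ext - N) / n_ext * (math.pi / 2.0)), w)
    w = np.where(hi, np.cos((N - n_s - n_ext + 1) / n_ext * (math.pi / 2.0)), w)
    return float(w) if w.ndim == 0 else w


def _edge_weights(cfg: TruncationConfig) -> np.ndarray:
    """Weights for synthesized samples k = 1..N_s outward from an edge:
    the falling branch cos(k/N_ext * pi/2), zero beyond k = N_ext."""
    k = np.arange(1, cfg.N_s + 1, dtype=np.float64)
    w = np.cos(np.minimum(k, cfg.N_ext) / cfg.N_ext * (math.pi / 2.0))
    w[k >= cfg.N_ext] = np.maximum(w[k >= cfg.N_ext], 0.0)
    return w


def _is_truncated(row: np.ndarray, edge_value: float) -> bool:
    m = np.abs(row).max()
    return m > 0 and abs(edge_value) > TRUNCATION_EDGE_FRACTION * m


def extend_sinogram(sino: Sinogram, cfg: TruncationConfig) -> Sinogram:
    """Extend each projection row by ``N_s`` synthesized samples per side.

    A side is extended with the weighted mirror of its innermost ``N_ext``
    samples when its edge sample indicates truncation, and with zeros
    otherwise. Measured samples are returned bit-for-bit unchanged.
    """
    vals = sino.values
    n_views, n_bins = vals.shape
    if cfg.N_ext > n_bins:
        raise ValueError("N_ext larger than detector row")
    n_s = cfg.N_s
    if n_s == 0:
        return sino.copy()
    out = np.zeros((n_views, n_bins + 2 * n_s), dtype=vals.dtype)
    out[:, n_s:n_s + n_bins] = vals
    w = _edge_weights(cfg)
    n_mirror = min(n_s, cfg.N_ext)
    for v in range(n_views):
        row = vals[v]
        if _is_truncated(row, row[-1]):
            mirrored = row[-1:-1 - n_mirror:-1]  # row[-1], row[-2], ...
            out[v, n_s + n_bins:n_s + n_bins + n_mirror] = mirrored * w[:n_mirror]
        if _is_truncated(row, row[0]):
            mirrored = row[:n_mirror]
            out[v, n_s - n_mirror:n_s] = (mirrored * w[:n_mirror])[::-1]
    if sino.detector_oversample != 1:
        raise ValueError("extend_sinogram expects a native-grid sinogram")
    return Sinogram(out, sino.geometry, domain=sino.domain,
                    detector_oversample=1, pad_bins=sino.pad_bins + n_s)


def truncation_corrected_recon(sino: Sinogram, geometry: ScanGeometry | None = None,
                               cfg: TruncationConfig | None = None,
                               filter_window: str = "hann") -> ReconImage:
    """Extend the sinogram onto a virtual widened detector, reconstruct,
    and mask to the small FOV."""
    g = sino.geometry if geometry is None else geometry
    if cfg is None:
        cfg = default_truncation_config(g)
    extended = extend_sinogram(sino, cfg)
    img = fbp_reconstruct(extended, filter_window=filter_window,
                          fov_radius=g.small_fov_radius())
    return img.masked()
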