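"""Polychromatic X-ray measurement model.

Transmitted intensity through a three-material object (water, bone, metal)
under a polychromatic spectrum Omega(E):

    I = I0 * sum_E Omega(E) * exp(-mu_w(E) d_w - mu_b(E) d_b - mu_m(E) d_m)

with per-material path lengths ``d`` obtained by forward-projecting the
material maps. Detected counts are Poisson distributed, ``y ~ Poisson(I + r)``
with ``r`` the mean background/readout event count, and the log projection
is ``p = -ln(y / I0)``.

The default spectrum is a generic 120 kVp tungsten-anode bremsstrahlung
shape (Kramers' law attenuated by 2.5 mm of aluminium inherent filtration),
binned to 12 energies at 10-120 keV; the shipped attenuation table carries
NIST-derived mass attenuation coefficients for water, cortical bone and
gold. Both are plain-text and user-replaceable.

Also provided is the soft-threshold decomposition of a (metal-excluded) HU
image into bone and water component images: with weight ``w(x)`` ramping
linearly from 0 at T1 (80 HU) to 1 at T2 (660 HU), the bone fraction is
``w(x)*x`` and the water fraction ``(1-w(x))*x``, so they sum to ``x``
exactly.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import ReconImage, Sinogram
from .geometry import ScanGeometry
from .projector import forward_project

__all__ = [
    "Spectrum", "AttenuationTable", "NoiseModel", "DecompositionConfig",
    "MaterialPathLengths", "polychromatic_intensity", "apply_poisson",
    "log_projection", "soft_threshold_decompose", "simulate_measurement",
    "effective_mu_water", "MATERIALS",
]

MATERIALS = ("water", "bone", "metal")

#: default material mass densities, g/cm^3 (water, cortical bone, gold)
DEFAULT_DENSITIES = {"water": 1.0, "bone": 1.92, "metal": 19.3}

#: zero-count floor applied before the log transform
ZERO_COUNT_FLOOR = 0.5

# aluminium mu/rho (cm^2/g) at 10..120 keV step 10, for inherent filtration
_AL_MU_RHO = np.array([26.23, 3.441, 1.128, 0.5685, 0.3681, 0.2778,
                       0.2341, 0.2018, 0.1846, 0.1704, 0.1621, 0.1549])
_AL_ENERGIES = np.arange(10.0, 121.0, 10.0)
_AL_DENSITY = 2.699  # g/cm^3


@dataclass
class Spectrum:
    """Discrete X-ray spectrum: fluence weights per energy bin.

    Raw weights are normalized to unit sum on construction, so intensities
    are invariant under rescaling of the input table.
    """

    energies: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.energies.ndim != 1 or self.energies.shape != self.weights.shape:
            raise ValueError("energies and weights must be matching 1-D arrays")
        if np.any(np.diff(self.energies) <= 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(self.weights < 0):
            raise ValueError("spectrum weights must be non-negative")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("spectrum weights must not be all zero")
        self.weights = self.weights / total

    @property
    def n_bins(self) -> int:
        return self.energies.size

    @classmethod
    def delta(cls, energy_kev: float) -> "Spectrum":
        """Monochromatic spectrum (single energy bin)."""
        return cls(np.array([energy_kev]), np.array([1.0]))

    @classmethod
    def kramers_120kvp(cls, n_bins: int = 12, e_min: float = 10.0,
                       e_max: float = 120.0,
                       filtration_mm_al: float = 2.5) -> "Spectrum":
        """Generic 120 kVp tungsten-anode bremsstrahlung spectrum.

        Kramers' law, ``N(E) ~ (E_max - E) / E``, attenuated by
        ``filtration_mm_al`` of aluminium inherent filtration and binned to
        ``n_bins`` energies spaced uniformly on [e_min, e_max].
        """
        e = np.linspace(e_min, e_max, n_bins)
        w = np.clip(e_max - e, 0.0, None) / e
        mu_al = np.interp(e, _AL_ENERGIES, _AL_MU_RHO) * _AL_DENSITY  # cm^-1
        w = w * np.exp(-mu_al * filtration_mm_al / 10.0)
        return cls(e, w)

    @classmethod
    def from_file(cls, path: str | Path) -> "Spectrum":
        """Load a two-column (energy keV, relative weight) text table;
        whitespace- or comma-delimited, '#' comments."""
        arr = _read_table(path)
        if arr.shape[1] < 2:
            raise ValueError("spectrum table needs two columns")
        return cls(arr[:, 0], arr[:, 1])


def _read_table(path: str | Path) -> np.ndarray:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip().replace(",", " ")
        if not line:
            continue
        try:
            rows.append([float(tok) for tok in line.split()])
        except ValueError:
            continue  # header line naming materials
    if not rows:
        raise ValueError(f"no numeric rows found in {path}")
    return np.asarray(rows, dtype=np.float64)


@dataclass
class AttenuationTable:
    """Linear attenuation coefficients (mm^-1) per material vs energy."""

    energies: np.ndarray
    mu: dict[str, np.ndarray]  # material -> mm^-1 at self.energies

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=np.float64)
        for m in MATERIALS:
            if m not in self.mu:
                raise ValueError(f"attenuation table missing material {m!r}")
            self.mu[m] = np.asarray(self.mu[m], dtype=np.float64)
            if self.mu[m].shape != self.energies.shape:
                raise ValueError(f"mu[{m!r}] shape mismatch")
            if np.any(self.mu[m] < 0):
                raise ValueError("attenuation coefficients must be >= 0")
        if not (np.all(self.mu["metal"] > self.mu["bone"])
                and np.all(self.mu["bone"] > self.mu["water"])):
            raise ValueError("expected mu_metal > mu_bone > mu_water "
                             "at every energy")

    def at(self, energies: np.ndarray) -> "AttenuationTable":
        """Log-log interpolate onto a new energy grid."""
        energies = np.atleast_1d(np.asarray(energies, dtype=np.float64))
        mu = {m: np.exp(np.interp(np.log(energies), np.log(self.energies),
                                  np.log(np.maximum(v, 1e-12))))
              for m, v in self.mu.items()}
        return AttenuationTable(energies, mu)

    def mu_water_at(self, energy_kev: float) -> float:
        return float(self.at(np.array([energy_kev])).mu["water"][0])

    @classmethod
    def from_file(cls, path: str | Path,
                  densities: dict[str, float] | None = None) -> "AttenuationTable":
        """Load a 4-column (energy keV, water, bone, metal) mass attenuation
        table in cm^2/g and convert to linear attenuation in mm^-1 using
        ``densities`` (g/cm^3)."""
        dens = dict(DEFAULT_DENSITIES)
        if densities:
            dens.update(densities)
        arr = _read_table(path)
        if arr.shape[1] < 4:
            raise ValueError("attenuation table needs 4 columns "
                             "(energy, water, bone, metal)")
        e = arr[:, 0]
        mu = {m: arr[:, i + 1] * dens[m] / 10.0  # cm^2/g * g/cm^3 -> mm^-1
              for i, m in enumerate(MATERIALS)}
        return cls(e, mu)

    @classmethod
    def default(cls, densities: dict[str, float] | None = None) -> "AttenuationTable":
        """The shipped NIST-derived water / cortical-bone / gold table."""
        ref = importlib.resources.files("smallfov_mar.data") / "attenuation_nist.txt"
        with importlib.resources.as_file(ref) as p:
            return cls.from_file(p, densities)


@dataclass
class NoiseModel:
    """Poisson counting noise: ``y ~ Poisson(I + r)``.

    I0 is the blank-scan count per detector cell per view; ``r`` the mean
    background/readout event count; ``enabled=False`` passes intensities
    through unchanged (noiseless simulation).
    """

    I0: float = 1e5
    r: float = 0.0
    seed: int = 0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.I0 <= 0:
            raise ValueError("I0 must be > 0")
        if self.r < 0:
            raise ValueError("r must be >= 0")


@dataclass
class DecompositionConfig:
    """Soft-threshold HU limits for water/bone decomposition."""

    T1: float = 80.0
    T2: float = 660.0

    def __post_init__(self) -> None:
        if not self.T1 < self.T2:
            raise ValueError("T1 must be < T2")


@dataclass
class MaterialPathLengths:
    """Per-material intersection lengths (mm), sinogram-shaped."""

    d_w: np.ndarray
    d_b: np.ndarray
    d_m: np.ndarray

    def __post_init__(self) -> None:
        self.d_w = np.asarray(self.d_w, dtype=np.float64)
        self.d_b = np.asarray(self.d_b, dtype=np.float64)
        self.d_m = np.asarray(self.d_m, dtype=np.float64)
        if not (self.d_w.shape == self.d_b.shape == self.d_m.shape):
            raise ValueError("path-length arrays must be congruent")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"water": self.d_w, "bone": self.d_b, "metal": self.d_m}


# --------------------------------------------------------------------- #
def polychromatic_intensity(paths: MaterialPathLengths, spectrum: Spectrum,
                            atten: AttenuationTable, I0: float,
                            geometry: ScanGeometry | None = None,
                            detector_oversample: int = 1) -> Sinogram | np.ndarray:
    """Spectrum-weighted transmitted intensity for given path lengths.

    Returns a bare array when ``geometry`` is None, else an
    intensity-domain :class:`Sinogram`.
    """
    for d in (paths.d_w, paths.d_b, paths.d_m):
        if np.any(d < 0):
            raise ValueError("path lengths must be non-negative")
    mu = atten.at(spectrum.energies).mu
    out = np.zeros_like(paths.d_w)
    for k in range(spectrum.n_bins):
        expo = (mu["water"][k] * paths.d_w + mu["bone"][k] * paths.d_b
                + mu["metal"][k] * paths.d_m)
        out += spectrum.weights[k] * np.exp(-expo)
    out *= I0
    if geometry is None:
        return out
    return Sinogram(out, geometry, domain="intensity",
                    detector_oversample=detector_oversample)


def apply_poisson(intensity: Sinogram, noise: NoiseModel) -> Sinogram:
    """Draw ``y ~ Poisson(I + r)`` per sample (reproducible under seed)."""
    if intensity.domain != "intensity":
        raise ValueError("apply_poisson expects an intensity-domain sinogram")
    if not noise.enabled:
        return intensity.with_values(intensity.values + noise.r)
    lam = np.clip(intensity.values + noise.r, 0.0, None)
    rng = np.random.default_rng(noise.seed)
    return intensity.with_values(rng.poisson(lam).astype(np.float64))


def log_projection(counts: Sinogram, I0: float,
                   floor: float = ZERO_COUNT_FLOOR) -> Sinogram:
    """Log transform ``p = -ln(y / I0)``; counts below ``floor`` are clamped
    so photon-starved samples stay finite."""
    if I0 <= 0:
        raise ValueError("I0 must be > 0")
    y = np.maximum(counts.values, floor)
    return counts.with_values(-np.log(y / I0), domain="log_projection")


def soft_threshold_decompose(image: ReconImage | np.ndarray,
                             cfg: DecompositionConfig = DecompositionConfig(),
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Split a metal-excluded HU image into (water, bone) HU components.

    Weight ``w`` is 0 below T1, 1 above T2, linear in between; bone
    component is ``w*x``, water component ``(1-w)*x``; they sum to ``x``
    exactly at every pixel.
    """
    if isinstance(image, ReconImage):
        if image.unit != "HU":
            raise ValueError("decomposition expects an HU image")
        x = image.values
    else:
        x = np.asarray(image, dtype=np.float64)
    w = np.clip((x - cfg.T1) / (cfg.T2 - cfg.T1), 0.0, 1.0)
    bone = w * x
    water = (1.0 - w) * x
    return water, bone


def effective_mu_water(spectrum: Spectrum, atten: AttenuationTable,
                       thickness_mm: float = 100.0) -> float:
    """Water-calibrated effective attenuation (mm^-1) of the beam.

    ``-ln(I(d)/I0) / d`` for a water slab of the given thickness: the value
    an FBP reconstruction of this spectrum assigns to water, used so that
    water maps to ~0 HU (the usual scanner water calibration).
    """
    mu = atten.at(spectrum.energies).mu["water"]
    I = float(np.sum(spectrum.weights * np.exp(-mu * thickness_mm)))
    return -np.log(I) / thickness_mm


def simulate_measurement(phantom, geometry: ScanGeometry,
                         spectrum: Spectrum | None = None,
                         atten: AttenuationTable | None = None,
                         noise: NoiseModel | None = None,
                         oversample: int = 1) -> Sinogram:
    """End-to-end measurement: per-material forward projection ->
    polychromatic intensity -> Poisson noise -> log projection.

    ``phantom`` provides ``material_maps()`` (see
    :class:`~smallfov_mar.phantoms.MaterialPhantom`). Truncation arises
    naturally when the phantom extends beyond the detector coverage.
    """
    spectrum = spectrum or Spectrum.kramers_120kvp()
    atten = atten or AttenuationTable.default()
    noise = noise or NoiseModel()
    maps = phantom.material_maps()
    paths = {}
    for m in MATERIALS:
        paths[m] = forward_project(maps[m], geometry, oversample=oversample).values
    mpl = MaterialPathLengths(paths["water"], paths["bone"], paths["metal"])
    I = polychromatic_intensity(mpl, spectrum, atten, noise.I0,
                                geometry=geometry, detector_oversample=oversample)
    y = apply_poisson(I, noise)
    return log_projection(y, noise.I0)
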