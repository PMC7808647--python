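"""Raster I/O: 32-bit float TIFF with a JSON sidecar.

Sinograms and images are written as single-page float32 TIFFs; phantoms as
multi-page TIFFs (one page per material). The sidecar (``<stem>.json``)
carries the geometry, units, domain tags and any provenance metadata so a
file round-trips to the same in-memory object.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .containers import ReconImage, Sinogram
from .geometry import ScanGeometry
from .phantoms import MaterialPhantom
from .physics import MATERIALS

__all__ = ["save_sinogram", "load_sinogram", "save_image", "load_image",
           "save_phantom", "load_phantom"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _write(path: Path, array: np.ndarray, meta: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def save_sinogram(path, sino: Sinogram, extra: dict | None = None) -> None:
    meta = {
        "kind": "sinogram",
        "domain": sino.domain,
        "detector_oversample": sino.detector_oversample,
        "pad_bins": sino.pad_bins,
        "geometry": sino.geometry.to_dict(),
    }
    if extra:
        meta["extra"] = extra
    _write(Path(path), sino.values, meta)


def load_sinogram(path) -> Sinogram:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    if meta.get("kind") != "sinogram":
        raise ValueError(f"{path} sidecar is not a sinogram")
    return Sinogram(tifffile.imread(path).astype(np.float64),
                    ScanGeometry.from_dict(meta["geometry"]),
                    domain=meta["domain"],
                    detector_oversample=meta["detector_oversample"],
                    pad_bins=meta.get("pad_bins", 0))


def save_image(path, image: ReconImage, extra: dict | None = None) -> None:
    meta = {
        "kind": "image",
        "unit": image.unit,
        "pixel_size_mm": image.pixel_size,
        "fov_radius_mm": image.fov_radius,
        "mu_water": image.mu_water,
    }
    if extra:
        meta["extra"] = extra
    _write(Path(path), image.values, meta)


def load_image(path) -> ReconImage:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    if meta.get("kind") != "image":
        raise ValueError(f"{path} sidecar is not an image")
    return ReconImage(tifffile.imread(path).astype(np.float64),
                      pixel_size=meta["pixel_size_mm"],
                      fov_radius=meta["fov_radius_mm"],
                      unit=meta["unit"], mu_water=meta.get("mu_water", 0.02059))


def save_phantom(path, phantom: MaterialPhantom) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stack = np.stack([phantom.material_maps()[m] for m in MATERIALS])
    tifffile.imwrite(path, stack.astype(np.float32),
                     photometric="minisblack")
    _sidecar(path).write_text(json.dumps({
        "kind": "phantom",
        "materials": list(MATERIALS),
        "pixel_size_mm": phantom.pixel_size,
        "metadata": phantom.metadata,
    }, indent=2))


def load_phantom(path) -> MaterialPhantom:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    if meta.get("kind") != "phantom":
        raise ValueError(f"{path} sidecar is not a phantom")
    stack = tifffile.imread(path).astype(np.float64)
    maps = {m: stack[i] for i, m in enumerate(meta["materials"])}
    return MaterialPhantom(maps["water"], maps["bone"], maps["metal"],
                           meta["pixel_size_mm"], meta.get("metadata", {}))
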