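"""File formats, geometry configs, comparison reports and run manifests.

Images and sinograms travel as single-channel 32-bit float TIFF; geometry
and spectrum configuration as YAML with keys mirroring the dataclass fields
(lengths in mm, the 180-degree angular range implicit).  Every CLI run
writes a JSON manifest recording inputs, parameters, software version,
seeds, warnings and SHA-256 checksums of the outputs, so deterministic
stages can be audited and reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

from .errors import GeometryError, NonFiniteError
from .geometry import ScanGeometry
from .synthetic import SpectrumModel

__all__ = [
    "read_image",
    "write_image",
    "read_sinogram",
    "write_sinogram",
    "write_mask",
    "load_geometry",
    "save_geometry",
    "save_spectrum",
    "compare_images",
    "write_manifest",
]

_GEOMETRY_KEYS = ("n_views", "n_bins", "bin_spacing", "n_pixels", "pixel_spacing")


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write a 2D array as single-channel float32 TIFF."""
    tifffile.imwrite(str(path), np.asarray(img, dtype=np.float32))


def read_image(path: str | Path) -> np.ndarray:
    """Read a float TIFF; rejects non-2D or non-finite data."""
    arr = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    if arr.ndim != 2:
        raise GeometryError(f"{path}: expected a single-channel 2D image")
    if not np.all(np.isfinite(arr)):
        raise NonFiniteError(f"{path}: contains NaN or infinite values")
    return arr


write_sinogram = write_image


def read_sinogram(path: str | Path, geom: ScanGeometry) -> np.ndarray:
    """Read a sinogram TIFF and validate it against the geometry."""
    arr = read_image(path)
    return geom.check_sinogram(arr, name=str(path))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as 0/255 uint8 TIFF for inspection."""
    tifffile.imwrite(str(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def save_geometry(path: str | Path, geom: ScanGeometry) -> None:
    data = {k: getattr(geom, k) for k in _GEOMETRY_KEYS}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_geometry(path: str | Path) -> ScanGeometry:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise GeometryError(f"{path}: geometry config must be a mapping")
    missing = [k for k in _GEOMETRY_KEYS if k not in data]
    if missing:
        raise GeometryError(f"{path}: missing geometry keys {missing}")
    return ScanGeometry(**{k: data[k] for k in _GEOMETRY_KEYS})


def save_spectrum(path: str | Path, spectrum: SpectrumModel) -> None:
    data = {
        "energies": list(spectrum.energies),
        "weights": list(spectrum.weights),
        "mu_curves": {k: list(v) for k, v in spectrum.mu_curves.items()},
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_spectrum(path: str | Path) -> SpectrumModel:
    data = yaml.safe_load(Path(path).read_text())
    return SpectrumModel(
        energies=tuple(data["energies"]),
        weights=tuple(data["weights"]),
        mu_curves={k: tuple(v) for k, v in data["mu_curves"].items()},
    )


def compare_images(
    a: np.ndarray,
    b: np.ndarray,
    region_mask: np.ndarray | None = None,
    ground_truth: np.ndarray | None = None,
) -> dict[str, Any]:
    """Quantitative comparison of two images, optionally against a truth.

    Reports max-abs and RMS difference, per-image minimum and negative-pixel
    count, and — when ``ground_truth`` is given — RMS error of each image
    against it, split inside/outside ``region_mask`` when that is given
    (e.g. the metal support).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise GeometryError(f"shape mismatch: {a.shape} vs {b.shape}")
    diff = a - b
    report: dict[str, Any] = {
        "max_abs_diff": float(np.abs(diff).max()),
        "rms_diff": float(np.sqrt(np.mean(diff**2))),
        "min_a": float(a.min()),
        "min_b": float(b.min()),
        "n_negative_a": int((a < 0).sum()),
        "n_negative_b": int((b < 0).sum()),
    }
    if ground_truth is not None:
        truth = np.asarray(ground_truth, dtype=np.float64)
        if truth.shape != a.shape:
            raise GeometryError("ground truth shape mismatch")
        for tag, img in (("a", a), ("b", b)):
            err = img - truth
            report[f"rms_{tag}_vs_truth"] = float(np.sqrt(np.mean(err**2)))
            if region_mask is not None:
                m = np.asarray(region_mask, bool)
                report[f"rms_{tag}_vs_truth_inside"] = float(
                    np.sqrt(np.mean(err[m] ** 2))
                )
                report[f"rms_{tag}_vs_truth_outside"] = float(
                    np.sqrt(np.mean(err[~m] ** 2))
                )
    return report


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    path: str | Path,
    *,
    command: str,
    inputs: dict[str, str] | None = None,
    parameters: dict[str, Any] | None = None,
    seed: int | None = None,
    warnings: list[str] | None = None,
    outputs: list[str | Path] | None = None,
) -> dict[str, Any]:
    """Write the run manifest JSON next to the outputs; returns its content."""
    from . import __version__

    def _clean(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return _clean(dataclasses.asdict(obj))
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    manifest = {
        "command": command,
        "version": __version__,
        "seed": seed,
        "inputs": inputs or {},
        "parameters": _clean(parameters or {}),
        "warnings": warnings or [],
        "outputs": {str(p): _sha256(Path(p)) for p in (outputs or [])},
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
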