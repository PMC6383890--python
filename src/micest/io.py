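"""File formats: NIfTI stacks with offset sidecars, TIFF slides, YAML configs.

A CEST or WASSR experiment is stored as a 4-D NIfTI (x, y, 1, offset) next to
an ``*_offsets.csv`` sidecar (columns index, offset_ppm) and a ``*_ref.nii.gz``
reference volume. B0 maps are a pair of NIfTI volumes (shift in ppm, validity
mask). Pool/pulse/scanner configuration round-trips through YAML.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import (
    B0Map,
    CestStack,
    ConfigurationError,
    ImageGeometry,
    PoolParameters,
    SaturationPulse,
    ScannerContext,
)

__all__ = [
    "save_stack",
    "load_stack",
    "save_b0_map",
    "load_b0_map",
    "save_slide",
    "load_slide",
    "load_pool_config",
    "default_pool_config",
]


def _affine(geom: ImageGeometry) -> np.ndarray:
    px, py = geom.pixel_size_mm
    return np.diag([px, py, geom.slice_thickness_mm, 1.0])


def save_stack(stack: CestStack, prefix: str | Path) -> None:
    """Write ``<prefix>.nii.gz``, ``<prefix>_ref.nii.gz``, ``<prefix>_offsets.csv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(stack.geometry)
    # (n_off, ny, nx) -> (nx, ny, 1, n_off) in scanner axis order
    data = np.transpose(stack.volumes, (2, 1, 0))[:, :, None, :]
    nib.save(nib.Nifti1Image(data.astype(np.float32), aff), str(prefix) + ".nii.gz")
    ref = stack.reference.T[:, :, None].astype(np.float32)
    nib.save(nib.Nifti1Image(ref, aff), str(prefix) + "_ref.nii.gz")
    pd.DataFrame(
        {"index": np.arange(stack.offsets_ppm.size), "offset_ppm": stack.offsets_ppm}
    ).to_csv(str(prefix) + "_offsets.csv", index=False)


def load_stack(prefix: str | Path, geometry: ImageGeometry | None = None) -> CestStack:
    prefix = str(prefix)
    img = nib.load(prefix + ".nii.gz")
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[2] != 1:
        raise ConfigurationError("expected a 4-D (x, y, 1, offset) stack")
    offsets = pd.read_csv(prefix + "_offsets.csv")["offset_ppm"].to_numpy()
    ref = np.asarray(nib.load(prefix + "_ref.nii.gz").dataobj, dtype=float)[:, :, 0]
    if geometry is None:
        px = img.header.get_zooms()
        nx, ny = data.shape[0], data.shape[1]
        geometry = ImageGeometry(
            fov_mm=(px[0] * nx, px[1] * ny), matrix=(nx, ny),
            slice_thickness_mm=float(px[2]),
        )
    volumes = np.transpose(data[:, :, 0, :], (2, 1, 0))
    return CestStack(volumes=volumes, offsets_ppm=offsets, reference=ref.T,
                     geometry=geometry)


def save_b0_map(b0: B0Map, prefix: str | Path, geometry: ImageGeometry) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(geometry)
    shift = np.nan_to_num(b0.shift, nan=0.0).T[:, :, None].astype(np.float32)
    nib.save(nib.Nifti1Image(shift, aff), str(prefix) + "_b0.nii.gz")
    mask = b0.valid.T[:, :, None].astype(np.uint8)
    nib.save(nib.Nifti1Image(mask, aff), str(prefix) + "_b0_mask.nii.gz")


def load_b0_map(prefix: str | Path) -> B0Map:
    prefix = str(prefix)
    shift = np.asarray(nib.load(prefix + "_b0.nii.gz").dataobj, dtype=float)[:, :, 0].T
    valid = np.asarray(nib.load(prefix + "_b0_mask.nii.gz").dataobj)[:, :, 0].T > 0
    return B0Map(shift=shift, valid=valid)


def save_slide(image: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float image as 16-bit TIFF."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    tifffile.imwrite(str(path), (arr * 65535).astype(np.uint16))


def load_slide(path: str | Path) -> np.ndarray:
    arr = np.asarray(tifffile.imread(str(path)), dtype=float)
    if arr.dtype.kind != "f" or arr.max() > 1.5:
        arr = arr / 65535.0
    return arr


def _parse_pool_config(cfg: dict) -> dict:
    pools = [PoolParameters(**p) for p in cfg.get("pools", [])]
    scanner = ScannerContext(**cfg.get("scanner", {}))
    pulses = {
        name: SaturationPulse(**kw) for name, kw in cfg.get("pulse", {}).items()
    }
    return {"pools": pools, "scanner": scanner, "pulses": pulses}


def load_pool_config(path: str | Path) -> dict:
    """Read a YAML pool/pulse/scanner configuration.

    Returns {"pools": [PoolParameters...], "scanner": ScannerContext,
    "pulses": {name: SaturationPulse}}.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return _parse_pool_config(cfg)


def default_pool_config() -> dict:
    """The packaged three-pool 9.4 T default configuration."""
    text = resources.files("micest").joinpath("data/default_pools.yaml").read_text()
    return _parse_pool_config(yaml.safe_load(text))
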