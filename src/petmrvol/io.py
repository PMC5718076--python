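"""Readers and writers: NIfTI volumes, FSL-style bvals, CSV tables, YAML config.

Grid spacing is taken from (and written to) the NIfTI header zooms in mm.
On disk, NIfTI arrays follow the usual ``(i, j, k[, t])`` layout; in memory
the package uses ``(slice, row, column)`` with the volume index first for 4D
stacks, so the b-value axis is moved between last and first on the way
through.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .adc import DwiSeries
from .errors import ConfigError, InvalidGeometryError
from .volumetry import ImageVolume, Mask, SliceAreaSeries


def _affine(spacing) -> np.ndarray:
    return np.diag([*spacing, 1.0])


def read_image(path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise InvalidGeometryError(f"{path}: expected a 3D image, got {data.shape}")
    return ImageVolume(data, tuple(float(z) for z in img.header.get_zooms()[:3]))


def read_mask(path) -> Mask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise InvalidGeometryError(f"{path}: expected a 3D mask, got {data.shape}")
    return Mask(data > 0, tuple(float(z) for z in img.header.get_zooms()[:3]))


def write_image(path, volume: ImageVolume, dtype=np.float32) -> None:
    nib.save(
        nib.Nifti1Image(np.asarray(volume.values, dtype=dtype), _affine(volume.spacing)),
        str(path),
    )


def write_mask(path, mask: Mask) -> None:
    nib.save(
        nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.spacing)), str(path)
    )


def read_bvals(path) -> tuple[float, ...]:
    """FSL-style bvals: whitespace- or newline-separated numbers."""
    values = np.loadtxt(str(path), ndmin=1).ravel()
    return tuple(float(v) for v in values)


def write_bvals(path, b_values) -> None:
    Path(path).write_text(" ".join(f"{b:g}" for b in b_values) + "\n")


def read_dwi(nifti_path, bvals_path) -> DwiSeries:
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise InvalidGeometryError(
            f"{nifti_path}: expected a 4D series, got {data.shape}"
        )
    return DwiSeries(
        np.moveaxis(data, -1, 0),
        read_bvals(bvals_path),
        tuple(float(z) for z in img.header.get_zooms()[:3]),
    )


def write_dwi(nifti_path, bvals_path, series: DwiSeries, dtype=np.float32) -> None:
    arr = np.moveaxis(np.asarray(series.values, dtype=dtype), 0, -1)
    nib.save(nib.Nifti1Image(arr, _affine(series.spacing)), str(nifti_path))
    write_bvals(bvals_path, series.b_values)


def read_slice_areas(csv_path, thickness_mm: float) -> SliceAreaSeries:
    """Slice-area CSV with columns ``slice_index, area_mm2``."""
    df = pd.read_csv(csv_path, comment="#")
    if "area_mm2" not in df.columns:
        raise ConfigError(f"{csv_path}: missing 'area_mm2' column")
    order = df.sort_values("slice_index") if "slice_index" in df.columns else df
    return SliceAreaSeries(order["area_mm2"].to_numpy(), thickness_mm)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: expected a mapping at the top level")
    return cfg
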