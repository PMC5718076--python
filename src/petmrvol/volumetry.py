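"""Image/mask containers and the volume primitives shared by every stage.

Anatomical planimetry, metabolic thresholding and functional clustering all
reduce to either counting voxels on a known grid or summing delineated slice
areas times slice thickness.  Grids are voxel-centred with axis order
``(slice, row, column)`` and per-axis spacing in millimetres; no world
transform is tracked, so a mask must live on exactly the grid of the image it
annotates — mismatched grids are rejected rather than silently resampled.
Volumes are returned in cm³.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    EmptyInputError,
    GridMismatchError,
    InvalidGeometryError,
    InvalidVolumeError,
)

#: Axis order convention tag used by every grid in the package.
AXIS_ORDER = "SRC"  # (slice, row, column)


def _validated_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in np.atleast_1d(spacing))
    if len(spacing) != 3:
        raise InvalidGeometryError(f"spacing must have 3 components, got {spacing!r}")
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise InvalidGeometryError(f"spacing components must be positive, got {spacing!r}")
    return spacing


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar grid with physical voxel spacing.

    Parameters
    ----------
    values
        3D array; SUV for PET, arbitrary signal units for MRI.
    spacing
        Voxel edge lengths in mm along (slice, row, column).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    axis_order: str = AXIS_ORDER

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim != 3 or arr.size == 0:
            raise InvalidGeometryError(
                f"expected a non-empty 3D grid, got shape {arr.shape}"
            )
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "spacing", _validated_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass(frozen=True)
class Mask:
    """A 3D boolean grid on the same footing as :class:`ImageVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    axis_order: str = AXIS_ORDER

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim != 3 or arr.size == 0:
            raise InvalidGeometryError(
                f"expected a non-empty 3D grid, got shape {arr.shape}"
            )
        object.__setattr__(self, "values", arr.astype(bool))
        object.__setattr__(self, "spacing", _validated_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.values))

    def same_grid(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def check_same_grid(self, other, what: str = "volume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"mask grid {self.shape}@{self.spacing} does not match "
                f"{what} grid {other.shape}@{other.spacing}"
            )


@dataclass(frozen=True)
class SliceAreaSeries:
    """Per-slice delineated areas (mm²) with a common slice thickness (mm)."""

    areas_mm2: np.ndarray
    thickness_mm: float

    def __post_init__(self):
        areas = np.asarray(self.areas_mm2, dtype=float).ravel()
        if areas.size == 0:
            raise EmptyInputError("slice-area series is empty")
        if np.any(~np.isfinite(areas)) or np.any(areas < 0):
            raise InvalidGeometryError("slice areas must be finite and >= 0")
        if not (np.isfinite(self.thickness_mm) and self.thickness_mm > 0):
            raise InvalidGeometryError(
                f"slice thickness must be positive, got {self.thickness_mm!r}"
            )
        object.__setattr__(self, "areas_mm2", areas)
        object.__setattr__(self, "thickness_mm", float(self.thickness_mm))


def voxel_count_volume(mask: Mask) -> float:
    """Volume of the retained voxels, in cm³.

    ``(number of true voxels) × (voxel volume in mm³) / 1000``; an empty mask
    has volume 0.
    """
    return mask.n_voxels * mask.voxel_volume_mm3 / 1000.0


def slice_areas(mask: Mask) -> SliceAreaSeries:
    """Per-slice in-plane areas of a mask, in mm².

    In-plane area is (in-plane voxel count) × (row spacing × column spacing);
    slice thickness is the slice-axis spacing.  By construction
    ``planimetric_volume(slice_areas(m)) == voxel_count_volume(m)``.
    """
    counts = mask.values.reshape(mask.shape[0], -1).sum(axis=1)
    in_plane = mask.spacing[1] * mask.spacing[2]
    return SliceAreaSeries(counts * in_plane, mask.spacing[0])


def planimetric_volume(series: SliceAreaSeries) -> float:
    """Planimetric volume in cm³: sum of slice areas times slice thickness."""
    return float(series.areas_mm2.sum() * series.thickness_mm / 1000.0)


def reader_average(volume_a: float, volume_b: float) -> float:
    """Arithmetic mean of two readers' volume estimates (cm³)."""
    if volume_a < 0 or volume_b < 0:
        raise InvalidVolumeError(
            f"volumes must be non-negative, got ({volume_a!r}, {volume_b!r})"
        )
    return 0.5 * (float(volume_a) + float(volume_b))
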