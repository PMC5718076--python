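"""Metabolic tumour volume by percent-of-SUVmax thresholding.

Inside an operator-supplied VOI, SUVmax is the single hottest voxel.  The
metabolic tumour volume at threshold *t* percent, MTV_t, is the volume of the
VOI voxels whose SUV is at or above ``t/100 × SUVmax`` (inclusive comparison;
no connected-component filtering — the VOI is the spatial gate that keeps
nearby physiological uptake such as the bladder out).  Because thresholds are
relative to SUVmax, every MTV is invariant under positive rescaling of the
SUV field, and the superlevel sets nest, so MTV is non-increasing in the
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyInputError
from .volumetry import ImageVolume, Mask, voxel_count_volume

#: The 13 default thresholds: 20% to 80% of SUVmax in 5% steps.
DEFAULT_THRESHOLDS = tuple(range(20, 85, 5))


@dataclass(frozen=True)
class MtvSweep:
    """SUVmax plus the threshold → volume (cm³) map of one sweep."""

    suv_max: float
    thresholds: tuple[float, ...]
    volumes_cm3: dict[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold_percent": list(self.thresholds),
                "volume_cm3": [self.volumes_cm3[t] for t in self.thresholds],
            }
        )


def suv_max(volume: ImageVolume, voi: Mask) -> float:
    """Maximum SUV over the voxels inside the VOI."""
    voi.check_same_grid(volume, "SUV volume")
    if voi.n_voxels == 0:
        raise EmptyInputError("VOI is empty")
    return float(volume.values[voi.values].max())


def _check_percent(percent: float) -> float:
    percent = float(percent)
    if not (0 < percent <= 100):
        raise DomainError(f"threshold percent must be in (0, 100], got {percent}")
    return percent


def mtv_at_threshold(volume: ImageVolume, voi: Mask, percent: float) -> float:
    """MTV at one threshold: cm³ of VOI voxels with SUV ≥ percent% of SUVmax."""
    percent = _check_percent(percent)
    peak = suv_max(volume, voi)
    retained = voi.values & (volume.values >= percent / 100.0 * peak)
    return voxel_count_volume(Mask(retained, voi.spacing))


def mtv_sweep(
    volume: ImageVolume,
    voi: Mask,
    thresholds=DEFAULT_THRESHOLDS,
) -> MtvSweep:
    """MTV at each threshold of a sweep (default MTV_20 … MTV_80, step 5)."""
    thresholds = tuple(_check_percent(t) for t in thresholds)
    if not thresholds:
        raise EmptyInputError("threshold list is empty")
    peak = suv_max(volume, voi)
    suv_in_voi = volume.values[voi.values]
    voxel_cm3 = voi.voxel_volume_mm3 / 1000.0
    volumes = {
        t: float(np.count_nonzero(suv_in_voi >= t / 100.0 * peak)) * voxel_cm3
        for t in thresholds
    }
    return MtvSweep(suv_max=peak, thresholds=thresholds, volumes_cm3=volumes)
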