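"""Functional tumour volume from DW-MRI.

Two routes mirror clinical practice:

* **manual** — the volume of a reader-drawn tumour mask (voxel counting,
  equivalent to per-slice area × slice thickness on the acquisition grid);
* **semi-automated** — K-means clustering of the (S0, ADC) feature pairs of
  every VOI voxel into three tissue classes, keeping only the solid-tumour
  cluster.  The classes are identified by their ADC centroids: fat/fibrotic
  tissue has low ADC and low S0, cellular solid tumour intermediate ADC and
  intermediate S0, and normal or cystic tissue high ADC and high S0.

Both features are z-scored over the VOI before clustering (raw S0 and ADC
differ by orders of magnitude and Euclidean K-means is scale-sensitive), so
the result is invariant to positive affine rescaling of either feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .adc import AdcMap
from .errors import DegenerateInputError, EmptyInputError
from .volumetry import ImageVolume, Mask, voxel_count_volume

#: Tissue classes in increasing order of centroid ADC.
TISSUE_CLASSES = ("fat_fibrotic", "tumour", "normal_cystic")

#: Integer codes used when a label map is written to disk.
LABEL_CODES = {"fat_fibrotic": 1, "tumour": 2, "normal_cystic": 3}


def _as_array(map_like, voi: Mask, what: str) -> np.ndarray:
    if isinstance(map_like, ImageVolume):
        voi.check_same_grid(map_like, what)
        return map_like.values
    arr = np.asarray(map_like, dtype=float)
    if arr.shape != voi.shape:
        raise DegenerateInputError(
            f"{what} shape {arr.shape} does not match VOI {voi.shape}"
        )
    return arr


@dataclass(frozen=True)
class ClusterModel:
    """Fitted three-class tissue clustering of a VOI.

    ``centroids`` are per-cluster mean (s0, adc) in the *raw* feature units;
    ``labels`` gives one cluster index per VOI voxel (order of
    ``np.flatnonzero(voi.values)``); ``tissue_assignment`` maps cluster index
    to tissue class.
    """

    k: int
    centroids: np.ndarray  # (k, 2): columns (s0, adc)
    labels: np.ndarray  # (n_voi,)
    voi: Mask
    tissue_assignment: dict[int, str]

    def class_mask(self, tissue: str) -> Mask:
        clusters = [c for c, t in self.tissue_assignment.items() if t == tissue]
        grid = np.zeros(self.voi.shape, dtype=bool)
        flat = np.zeros(self.voi.n_voxels, dtype=bool)
        for c in clusters:
            flat |= self.labels == c
        grid.ravel()[np.flatnonzero(self.voi.values.ravel())] = flat
        return Mask(grid, self.voi.spacing)

    def class_volumes(self) -> dict[str, float]:
        """Volume (cm³) of each tissue class; they partition the VOI."""
        voxel_cm3 = self.voi.voxel_volume_mm3 / 1000.0
        out = {}
        for tissue in TISSUE_CLASSES:
            clusters = [c for c, t in self.tissue_assignment.items() if t == tissue]
            n = sum(int(np.count_nonzero(self.labels == c)) for c in clusters)
            out[tissue] = n * voxel_cm3
        return out

    def label_volume(self) -> ImageVolume:
        """Integer label map (0 outside the VOI, tissue codes inside)."""
        grid = np.zeros(self.voi.shape, dtype=np.int16)
        codes = np.array(
            [LABEL_CODES[self.tissue_assignment[c]] for c in range(self.k)],
            dtype=np.int16,
        )
        grid.ravel()[np.flatnonzero(self.voi.values.ravel())] = codes[self.labels]
        return ImageVolume(grid, self.voi.spacing)


def ftv_manual(tumour_mask: Mask) -> float:
    """Manual functional tumour volume: cm³ of a reader-drawn mask."""
    if tumour_mask.n_voxels == 0:
        warnings.warn("manual tumour mask is empty; FTV = 0", stacklevel=2)
        return 0.0
    return voxel_count_volume(tumour_mask)


def assign_clusters(centroids: np.ndarray) -> dict[int, str]:
    """Map three cluster centroids to tissue classes by ADC ordering.

    The lowest-ADC centroid is fat/fibrotic, the middle one solid tumour, the
    highest normal/cystic.  Exact ADC ties are broken by the S0 centroid
    (lower S0 takes the lower-ADC role).
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape != (3, 2):
        raise DegenerateInputError(
            f"expected 3 centroids with (s0, adc) columns, got {centroids.shape}"
        )
    order = np.lexsort((centroids[:, 0], centroids[:, 1]))  # adc, then s0
    return {int(c): TISSUE_CLASSES[rank] for rank, c in enumerate(order)}


def kmeans_segment(
    voi: Mask,
    s0_map,
    adc_map,
    *,
    k: int = 3,
    seed: int = 0,
    n_init: int = 10,
    standardize: bool = True,
) -> ClusterModel:
    """Cluster the VOI voxels on (S0, ADC) and assign tissue classes.

    Lloyd's algorithm with k-means++ seeding, best of ``n_init`` restarts by
    within-cluster sum of squares; deterministic given ``seed``.  ``s0_map``
    and ``adc_map`` may be arrays, :class:`~petmrvol.volumetry.ImageVolume`
    instances, or a single :class:`~petmrvol.adc.AdcMap` passed as ``s0_map``.
    """
    if isinstance(s0_map, AdcMap) and adc_map is None:
        adc_map, s0_map = s0_map.adc, s0_map.s0
    if voi.n_voxels == 0:
        raise EmptyInputError("VOI is empty")
    s0 = _as_array(s0_map, voi, "S0 map")
    adc = _as_array(adc_map, voi, "ADC map")

    X = np.column_stack([s0[voi.values], adc[voi.values]]).astype(float)
    if X.shape[0] < k or np.unique(X, axis=0).shape[0] < k:
        raise DegenerateInputError(
            f"VOI must contain at least {k} distinct (s0, adc) vectors"
        )
    if standardize:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mean) / sd
    else:
        Z = X

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(Z)

    centroids = np.vstack([X[labels == c].mean(axis=0) for c in range(k)])
    assignment = assign_clusters(centroids) if k == 3 else {
        c: f"cluster_{c}" for c in range(k)
    }
    return ClusterModel(
        k=k, centroids=centroids, labels=labels, voi=voi,
        tissue_assignment=assignment,
    )


def ftv_semi_automated(
    voi: Mask,
    s0_map,
    adc_map,
    *,
    seed: int = 0,
    n_init: int = 10,
    slice_by_slice: bool = False,
) -> float:
    """Semi-automated FTV: cm³ of the solid-tumour cluster.

    Clusters the VOI into the three tissue classes and discards the
    fat/fibrotic and normal/cystic clusters.  Volumetric (whole-VOI)
    clustering is the default; ``slice_by_slice=True`` clusters each slice
    independently and sums the per-slice tumour volumes (slices whose VOI
    cross-section is too small to support three clusters are skipped with a
    warning).
    """
    if not slice_by_slice:
        model = kmeans_segment(voi, s0_map, adc_map, seed=seed, n_init=n_init)
        return model.class_volumes()["tumour"]

    total = 0.0
    for z in range(voi.shape[0]):
        if not voi.values[z].any():
            continue
        sub = np.zeros(voi.shape, dtype=bool)
        sub[z] = voi.values[z]
        try:
            model = kmeans_segment(
                Mask(sub, voi.spacing), s0_map, adc_map, seed=seed, n_init=n_init
            )
        except DegenerateInputError:
            warnings.warn(f"slice {z}: too few distinct voxels, skipped", stacklevel=2)
            continue
        total += model.class_volumes()["tumour"]
    return total
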