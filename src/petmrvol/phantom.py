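"""Multimodal digital phantoms with known ground truth.

The generator emulates the two imaging scenarios the pipeline analyses:

* **PET** — a hot spot with a smooth Gaussian radial SUV falloff over a low
  uptake background, plus a nearby high-uptake confounder sphere (the
  "bladder") deliberately left outside the spherical VOI.  Because the
  profile is analytic, the volume of every percent-of-SUVmax superlevel set
  has a closed form, giving an exact oracle for the MTV sweep.
* **DWI** — an ellipsoidal tumour inside a larger ellipsoidal VOI, with
  three planted tissue classes: fat/fibrotic (low ADC, low S0), solid tumour
  (intermediate ADC, intermediate S0) and normal/cystic (high ADC, high S0).
  Per-voxel ADC and S0 are drawn once from class-conditional normals
  (truncated at 0), the mono-exponential signal is evaluated at every
  scheduled b-value, and magnitude (Rician) noise is applied:
  ``S̃ = sqrt((S + g₁σ)² + (g₂σ)²)`` with independent unit normals.

Whole cohorts are sampled from study-scale parameter ranges (peak SUV
uniform over the reported 3.3–16.7 range; anatomical volumes averaging
~55 cm³), each patient seeded from a single master seed so every downstream
number is reproducible.  The PET falloff width is calibrated per patient so
the analytic MTV curve crosses the anatomical volume between the 30% and 35%
thresholds, reproducing the mechanism by which an intermediate threshold
best matches anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .adc import DEFAULT_B_VALUES, DwiSeries
from .concordance import MTV_THRESHOLDS, CohortVolumeTable
from .errors import InsufficientDataError, InvalidGeometryError
from .volumetry import ImageVolume, Mask, voxel_count_volume


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueClass:
    """Class-conditional (ADC, S0) distribution of one tissue type."""

    adc_mean: float  # mm²/s
    adc_sd: float
    s0_mean: float  # arbitrary signal units
    s0_sd: float


#: Default tissue classes.  The tumour ADC centre is the reported cervical
#: tumour mean (0.934×10⁻³ mm²/s); fat/fibrotic and normal/cystic flank it
#: with the low/high ADC and S0 pattern that defines the three clusters.
#: Spreads are narrow relative to the class gaps, emulating the distinctly
#: separated clusters of well-differentiated tissue.
DEFAULT_TISSUE_CLASSES = {
    "fat_fibrotic": TissueClass(0.30e-3, 0.03e-3, 150.0, 10.0),
    "tumour": TissueClass(0.934e-3, 0.05e-3, 450.0, 25.0),
    "normal_cystic": TissueClass(2.00e-3, 0.10e-3, 900.0, 45.0),
}


@dataclass(frozen=True)
class PetPhantomSpec:
    """Geometry and intensity model of the PET hot-spot phantom.

    SUV(r) = background + (peak − background)·exp(−r²/(2σ²)) about the grid
    centre, a confounder sphere of ``confounder_suv`` displaced by
    ``confounder_offset_mm`` (it must clear the VOI sphere), and optional
    additive Gaussian noise.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    peak_suv: float = 9.2
    background_suv: float = 0.6
    sigma_mm: float = 15.0
    voi_radius_mm: float = 40.0
    confounder_offset_mm: tuple[float, float, float] = (0.0, 52.0, 0.0)
    confounder_radius_mm: float = 8.0
    confounder_suv: float = 27.6
    noise_sd: float = 0.0

    def __post_init__(self):
        if not (self.peak_suv > self.background_suv > 0):
            raise InvalidGeometryError("need peak SUV > background SUV > 0")
        if self.sigma_mm <= 0 or self.voi_radius_mm <= 0:
            raise InvalidGeometryError("sigma and VOI radius must be positive")
        offset = np.linalg.norm(self.confounder_offset_mm)
        if offset <= self.voi_radius_mm + self.confounder_radius_mm:
            raise InvalidGeometryError(
                "confounder sphere intersects the VOI: offset "
                f"{offset:.1f} mm <= {self.voi_radius_mm + self.confounder_radius_mm:.1f} mm"
            )


@dataclass(frozen=True)
class DwiPhantomSpec:
    """Geometry, tissue classes and noise of the three-class DWI phantom.

    The tumour is the central ellipsoid ``semi_axes_mm`` (slice, row, column
    order).  The VOI is the same ellipsoid scaled by ``voi_scale``.  Planted
    classes: solid tumour = ellipsoid minus a small central cystic core
    (radius ``cyst_radius_fraction`` × smallest semi-axis, assigned to
    normal/cystic together with the superior half of the surrounding shell);
    fat/fibrotic = inferior half of the shell.
    """

    shape: tuple[int, int, int] = (20, 96, 96)
    spacing: tuple[float, float, float] = (4.0, 1.5, 1.5)
    semi_axes_mm: tuple[float, float, float] = (20.0, 24.0, 24.0)
    voi_scale: float = 1.3
    cyst_radius_fraction: float = 0.35
    classes: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_CLASSES))
    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    rician_sigma: float = 0.0

    def __post_init__(self):
        adc = [self.classes[t].adc_mean for t in
               ("fat_fibrotic", "tumour", "normal_cystic")]
        if not (adc[0] < adc[1] < adc[2]):
            raise InvalidGeometryError(
                f"class ADC means must be strictly ordered, got {adc}"
            )
        if self.voi_scale <= 1.0:
            raise InvalidGeometryError("voi_scale must exceed 1")
        half_extent = [(n // 2) * s for n, s in zip(self.shape, self.spacing)]
        for ax, (a, h) in enumerate(zip(self.semi_axes_mm, half_extent)):
            if a <= 0 or a * self.voi_scale >= h:
                raise InvalidGeometryError(
                    f"VOI semi-axis {a * self.voi_scale:.1f} mm does not fit the "
                    f"field along axis {ax} (half extent {h:.1f} mm)"
                )
        if self.rician_sigma < 0:
            raise InvalidGeometryError("rician_sigma must be >= 0")


@dataclass(frozen=True)
class PatientPhantomSpec:
    patient_id: str
    pet: PetPhantomSpec
    dwi: DwiPhantomSpec
    atv_cm3: float  # analytic anatomical (full-ellipsoid) volume
    seed: int


@dataclass(frozen=True)
class PhantomBundle:
    """One patient's realised phantoms plus their ground truth."""

    patient_id: str
    pet: ImageVolume
    pet_voi: Mask
    dwi: DwiSeries
    dwi_voi: Mask
    anatomical_mask: Mask  # full tumour ellipsoid on the DWI grid
    class_masks: dict[str, Mask]
    adc_true: np.ndarray
    s0_true: np.ndarray
    truth_mtv_cm3: dict[float, float]  # analytic, per threshold percent
    truth_volumes_cm3: dict[str, float]


# --------------------------------------------------------------------------
# PET
# --------------------------------------------------------------------------

def _radius_sq_mm(shape, spacing, centre_offset_mm=(0.0, 0.0, 0.0)):
    centre = [(n // 2) * s + o for n, s, o in zip(shape, spacing, centre_offset_mm)]
    axes = [
        (np.arange(n) * s - c) ** 2
        for n, s, c in zip(shape, spacing, centre)
    ]
    return (
        axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
    )


def analytic_mtv_curve(
    spec: PetPhantomSpec, thresholds=MTV_THRESHOLDS
) -> dict[float, float]:
    """Closed-form noiseless MTV (cm³) of the Gaussian profile per threshold.

    With peak P, background B and threshold level t·P/100, the superlevel set
    is the ball of radius σ·sqrt(−2·ln u) with u = (t·P/100 − B)/(P − B),
    capped at the VOI sphere; u ≤ 0 floods the whole VOI.
    """
    out = {}
    for t in thresholds:
        u = (t / 100.0 * spec.peak_suv - spec.background_suv) / (
            spec.peak_suv - spec.background_suv
        )
        if u <= 0:
            r = spec.voi_radius_mm
        elif u >= 1:
            r = 0.0
        else:
            r = min(spec.sigma_mm * np.sqrt(-2.0 * np.log(u)), spec.voi_radius_mm)
        out[float(t)] = 4.0 / 3.0 * np.pi * r**3 / 1000.0
    return out


def generate_pet_phantom(
    spec: PetPhantomSpec, seed: int | np.random.Generator = 0
) -> tuple[ImageVolume, Mask, dict[float, float]]:
    """Realise the PET phantom: SUV volume, VOI mask, analytic MTV curve."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r2 = _radius_sq_mm(spec.shape, spec.spacing)
    suv = spec.background_suv + (spec.peak_suv - spec.background_suv) * np.exp(
        -r2 / (2.0 * spec.sigma_mm**2)
    )
    r2_conf = _radius_sq_mm(spec.shape, spec.spacing, spec.confounder_offset_mm)
    suv[r2_conf <= spec.confounder_radius_mm**2] = spec.confounder_suv
    if spec.noise_sd > 0:
        suv = np.maximum(suv + rng.normal(0.0, spec.noise_sd, suv.shape), 0.0)
    voi = Mask(r2 <= spec.voi_radius_mm**2, spec.spacing)
    return ImageVolume(suv, spec.spacing), voi, analytic_mtv_curve(spec)


# --------------------------------------------------------------------------
# DWI
# --------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, size):
    draw = rng.normal(mean, sd, size)
    return np.maximum(draw, 0.0)


@dataclass(frozen=True)
class DwiPhantom:
    series: DwiSeries
    voi: Mask
    anatomical_mask: Mask
    class_masks: dict[str, Mask]
    adc_true: np.ndarray
    s0_true: np.ndarray


def generate_dwi_phantom(
    spec: DwiPhantomSpec, seed: int | np.random.Generator = 0
) -> DwiPhantom:
    """Realise the three-class DWI phantom with planted truth masks."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centre = [(n // 2) * s for n, s in zip(spec.shape, spec.spacing)]
    coords = [
        np.arange(n) * s - c for n, s, c in zip(spec.shape, spec.spacing, centre)
    ]

    def ellipsoid(scale):
        terms = [
            (coords[0] / (spec.semi_axes_mm[0] * scale)) ** 2,
            (coords[1] / (spec.semi_axes_mm[1] * scale)) ** 2,
            (coords[2] / (spec.semi_axes_mm[2] * scale)) ** 2,
        ]
        return (
            terms[0][:, None, None]
            + terms[1][None, :, None]
            + terms[2][None, None, :]
        ) <= 1.0

    tumour_ellipsoid = ellipsoid(1.0)
    voi_grid = ellipsoid(spec.voi_scale)
    r2 = _radius_sq_mm(spec.shape, spec.spacing)
    core = r2 <= (spec.cyst_radius_fraction * min(spec.semi_axes_mm)) ** 2
    shell = voi_grid & ~tumour_ellipsoid
    superior = coords[0][:, None, None] >= 0
    superior = np.broadcast_to(superior, spec.shape)

    masks = {
        "tumour": tumour_ellipsoid & ~core,
        "normal_cystic": core | (shell & superior),
        "fat_fibrotic": shell & ~superior,
    }

    adc_true = np.zeros(spec.shape)
    s0_true = np.zeros(spec.shape)
    for tissue, m in masks.items():
        cls = spec.classes[tissue]
        n = int(m.sum())
        adc_true[m] = _truncated_normal(rng, cls.adc_mean, cls.adc_sd, n)
        s0_true[m] = _truncated_normal(rng, cls.s0_mean, cls.s0_sd, n)

    b = np.asarray(spec.b_values)
    signal = s0_true[None] * np.exp(-b[:, None, None, None] * adc_true[None])
    if spec.rician_sigma > 0:
        g1 = rng.standard_normal(signal.shape)
        g2 = rng.standard_normal(signal.shape)
        signal = np.sqrt(
            (signal + spec.rician_sigma * g1) ** 2 + (spec.rician_sigma * g2) ** 2
        )

    return DwiPhantom(
        series=DwiSeries(signal.astype(np.float32), spec.b_values, spec.spacing),
        voi=Mask(voi_grid, spec.spacing),
        anatomical_mask=Mask(tumour_ellipsoid, spec.spacing),
        class_masks={t: Mask(m, spec.spacing) for t, m in masks.items()},
        adc_true=adc_true,
        s0_true=s0_true,
    )


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Study-scale sampling distribution for a synthetic patient cohort.

    Defaults: 29 patients; peak SUV uniform over the reported 3.3–16.7
    range; tumour-to-background chosen so background is 5–10% of peak;
    anatomical equivalent radius uniform over 15–30 mm (cohort mean volume
    ≈ 53 cm³); mild in-plane axis anisotropy at fixed volume.  The PET σ is
    set per patient so the analytic MTV equals the anatomical volume at
    ``crossing_threshold_pct``, putting the best-matching threshold between
    30 and 35 percent.
    """

    n_patients: int = 29
    peak_suv_range: tuple[float, float] = (3.3, 16.7)
    background_fraction_range: tuple[float, float] = (0.05, 0.10)
    tumour_radius_range_mm: tuple[float, float] = (15.0, 30.0)
    axis_ratio_range: tuple[float, float] = (0.85, 1.18)
    crossing_threshold_pct: float = 32.5
    rician_snr: float | None = None  # SNR at b=0 of the tumour class; None = noiseless
    pet_noise_sd: float = 0.0

    def __post_init__(self):
        if self.n_patients < 2:
            raise InsufficientDataError("a cohort needs at least 2 patients")


def _gaussian_radius_multiplier(threshold_pct: float, background_fraction: float):
    """sqrt(−2 ln u): superlevel-set radius at a threshold, in units of σ."""
    u = (threshold_pct / 100.0 - background_fraction) / (1.0 - background_fraction)
    return np.sqrt(-2.0 * np.log(u))


def sample_patient_specs(
    spec: CohortSpec, master_seed: int
) -> list[PatientPhantomSpec]:
    """Draw per-patient phantom specs; deterministic given the master seed."""
    seeds = np.random.SeedSequence(master_seed).spawn(spec.n_patients)
    out = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        peak = rng.uniform(*spec.peak_suv_range)
        bg_frac = rng.uniform(*spec.background_fraction_range)
        r_eq = rng.uniform(*spec.tumour_radius_range_mm)
        q1, q2 = rng.uniform(*spec.axis_ratio_range, size=2)
        # volume-preserving anisotropy; smallest axis along the slice direction
        axes = sorted([r_eq * q1, r_eq * q2, r_eq / (q1 * q2)])
        sigma = r_eq / _gaussian_radius_multiplier(
            spec.crossing_threshold_pct, bg_frac
        )
        patient_seed = int(rng.integers(0, 2**31 - 1))
        dwi_classes = dict(DEFAULT_TISSUE_CLASSES)
        rician = (
            dwi_classes["tumour"].s0_mean / spec.rician_snr
            if spec.rician_snr
            else 0.0
        )
        out.append(
            PatientPhantomSpec(
                patient_id=f"P{i + 1:03d}",
                pet=PetPhantomSpec(
                    peak_suv=peak,
                    background_suv=bg_frac * peak,
                    sigma_mm=sigma,
                    noise_sd=spec.pet_noise_sd,
                ),
                dwi=DwiPhantomSpec(
                    semi_axes_mm=(axes[0], axes[1], axes[2]),
                    classes=dwi_classes,
                    rician_sigma=rician,
                ),
                atv_cm3=4.0 / 3.0 * np.pi * r_eq**3 / 1000.0,
                seed=patient_seed,
            )
        )
    return out


def generate_patient(pspec: PatientPhantomSpec) -> PhantomBundle:
    """Realise one patient's PET and DWI phantoms with their truth."""
    rng = np.random.default_rng(pspec.seed)
    pet, pet_voi, truth_mtv = generate_pet_phantom(pspec.pet, rng)
    dwi = generate_dwi_phantom(pspec.dwi, rng)
    truth_volumes = {
        "atv": pspec.atv_cm3,
        "ftv_manual": voxel_count_volume(dwi.class_masks["tumour"]),
        "ftv_semi": voxel_count_volume(dwi.class_masks["tumour"]),
    }
    for t, v in truth_mtv.items():
        truth_volumes[f"mtv_{int(t)}"] = v
    return PhantomBundle(
        patient_id=pspec.patient_id,
        pet=pet,
        pet_voi=pet_voi,
        dwi=dwi.series,
        dwi_voi=dwi.voi,
        anatomical_mask=dwi.anatomical_mask,
        class_masks=dwi.class_masks,
        adc_true=dwi.adc_true,
        s0_true=dwi.s0_true,
        truth_mtv_cm3=truth_mtv,
        truth_volumes_cm3=truth_volumes,
    )


def truth_table(bundles: list[PhantomBundle]) -> CohortVolumeTable:
    """Assemble the planted/analytic truth volumes into a cohort table."""
    rows = {b.patient_id: b.truth_volumes_cm3 for b in bundles}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "patient_id"
    return CohortVolumeTable(df)


def generate_cohort(
    spec: CohortSpec, master_seed: int
) -> tuple[list[PhantomBundle], CohortVolumeTable]:
    """Realise a whole cohort and its truth table.

    For memory-lean streaming use :func:`sample_patient_specs` +
    :func:`generate_patient` one patient at a time.
    """
    bundles = [generate_patient(p) for p in sample_patient_specs(spec, master_seed)]
    return bundles, truth_table(bundles)
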