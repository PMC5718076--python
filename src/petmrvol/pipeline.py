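"""End-to-end phantom-cohort pipeline.

Runs the whole study flow on a synthetic cohort: phantom generation → ADC
fitting → manual and semi-automated FTV → MTV threshold sweep → anatomical
planimetry → cohort table → concordance report.  Every stage is seeded from
the single master seed, so a given configuration reproduces its output files
byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import phantom as ph
from .adc import fit_monoexponential
from .concordance import (
    MTV_THRESHOLDS,
    CohortVolumeTable,
    ConcordanceReport,
    build_report,
)
from .errors import ConfigError
from .ftv import ftv_manual, ftv_semi_automated
from .mtv import mtv_sweep
from .volumetry import planimetric_volume, slice_areas

log = logging.getLogger("petmrvol")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a phantom-cohort run."""

    out_dir: Path
    master_seed: int = 0
    n_patients: int = 29
    thresholds: tuple[float, ...] = MTV_THRESHOLDS
    kmeans_n_init: int = 10
    rician_snr: float | None = None
    pet_noise_sd: float = 0.0
    paired_test: str = "t"
    cohort: ph.CohortSpec = field(init=False)

    def __post_init__(self):
        if not self.thresholds or any(not (0 < t <= 100) for t in self.thresholds):
            raise ConfigError(f"thresholds must lie in (0, 100]: {self.thresholds}")
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        object.__setattr__(
            self,
            "cohort",
            ph.CohortSpec(
                n_patients=self.n_patients,
                rician_snr=self.rician_snr,
                pet_noise_sd=self.pet_noise_sd,
            ),
        )

    @classmethod
    def from_yaml_dict(cls, cfg: dict, out_dir) -> "PipelineConfig":
        known = {
            "master_seed", "n_patients", "thresholds", "kmeans_n_init",
            "rician_snr", "pet_noise_sd", "paired_test",
        }
        unknown = set(cfg) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in cfg:
            cfg = {**cfg, "thresholds": parse_threshold_spec(cfg["thresholds"])}
        return cls(out_dir=out_dir, **cfg)


def parse_threshold_spec(spec) -> tuple[float, ...]:
    """Parse ``start:stop:step`` (inclusive) or a list of percents."""
    if isinstance(spec, str):
        parts = spec.split(":")
        if len(parts) != 3:
            raise ConfigError(f"threshold spec must be start:stop:step, got {spec!r}")
        start, stop, step = (float(p) for p in parts)
        if step <= 0 or stop < start:
            raise ConfigError(f"bad threshold range {spec!r}")
        out, t = [], start
        while t <= stop + 1e-9:
            out.append(round(t, 6))
            t += step
        return tuple(out)
    return tuple(float(t) for t in spec)


@dataclass(frozen=True)
class PipelineResult:
    estimates: CohortVolumeTable
    truth: CohortVolumeTable
    report: ConcordanceReport
    paths: dict[str, Path]


def measure_patient(
    bundle: ph.PhantomBundle,
    thresholds=MTV_THRESHOLDS,
    *,
    kmeans_seed: int = 0,
    kmeans_n_init: int = 10,
) -> dict[str, float]:
    """All modality volume estimates (cm³) for one realised patient."""
    row: dict[str, float] = {}
    row["atv"] = planimetric_volume(slice_areas(bundle.anatomical_mask))
    adc_map = fit_monoexponential(bundle.dwi, bundle.dwi_voi)
    row["ftv_manual"] = ftv_manual(bundle.class_masks["tumour"])
    row["ftv_semi"] = ftv_semi_automated(
        bundle.dwi_voi, adc_map.s0, adc_map.adc,
        seed=kmeans_seed, n_init=kmeans_n_init,
    )
    sweep = mtv_sweep(bundle.pet, bundle.pet_voi, thresholds)
    for t in sweep.thresholds:
        row[f"mtv_{int(t)}"] = sweep.volumes_cm3[t]
    return row


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the cohort study flow and write its artifacts.

    Writes ``cohort_estimates.csv``, ``cohort_truth.csv``, ``table3.csv`` and
    ``table4.csv`` under ``config.out_dir``.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    log.info(
        "cohort run: n=%d seed=%d snr=%s pet_noise=%.3g",
        config.n_patients, config.master_seed,
        config.rician_snr, config.pet_noise_sd,
    )

    specs = ph.sample_patient_specs(config.cohort, config.master_seed)
    est_rows, truth_rows = {}, {}
    for pspec in specs:
        try:
            bundle = ph.generate_patient(pspec)
            est_rows[pspec.patient_id] = measure_patient(
                bundle,
                config.thresholds,
                kmeans_seed=config.master_seed,
                kmeans_n_init=config.kmeans_n_init,
            )
            truth_rows[pspec.patient_id] = bundle.truth_volumes_cm3
        except Exception as exc:
            raise RuntimeError(
                f"patient {pspec.patient_id}: pipeline stage failed: {exc}"
            ) from exc
        log.info("patient %s done", pspec.patient_id)

    estimates = CohortVolumeTable(
        pd.DataFrame.from_dict(est_rows, orient="index").rename_axis("patient_id")
    )
    truth = CohortVolumeTable(
        pd.DataFrame.from_dict(truth_rows, orient="index").rename_axis("patient_id")
    )
    report = build_report(estimates, test=config.paired_test)

    stamp = f"petmrvol cohort run; master_seed={config.master_seed}"
    paths = {
        "estimates": out / "cohort_estimates.csv",
        "truth": out / "cohort_truth.csv",
        "table3": out / "table3.csv",
        "table4": out / "table4.csv",
    }
    estimates.to_csv(paths["estimates"], header_comment=stamp)
    truth.to_csv(paths["truth"], header_comment=stamp)
    for name, frame in (("table3", report.table3()), ("table4", report.table4())):
        with open(paths[name], "w") as fh:
            fh.write(f"# {stamp}\n")
            frame.to_csv(fh, index_label="modality", float_format="%.10g")
    return PipelineResult(estimates=estimates, truth=truth, report=report, paths=paths)
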