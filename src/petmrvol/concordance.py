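"""Cohort concordance statistics between tumour-volume modalities.

The anatomical volume (ATV) is treated as the reference.  For every other
modality (manual and semi-automated functional volumes, and the 13 metabolic
volumes MTV_20 … MTV_80) the module reports, over the patients with complete
pairs:

* the means and the paired difference of means, ``mean(ATV) − mean(modality)``
  (positive ⇔ the modality under-estimates the anatomical volume on average);
* the percent difference, ``100 × diff / mean(ATV)``;
* a two-tailed paired-samples t test on the per-patient differences (a
  Wilcoxon signed-rank alternative is available);
* Pearson's product-moment correlation with its two-tailed p-value.

Display rounding follows radiology-report convention: volumes and differences
to 1 decimal (cm³), percents to 1 decimal, correlations to 3 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidVolumeError,
    UndefinedStatisticError,
)

#: MTV thresholds carried as cohort columns.
MTV_THRESHOLDS = tuple(range(20, 85, 5))

#: Modalities compared against the anatomical reference, in report order.
MODALITY_COLUMNS = ("ftv_manual", "ftv_semi") + tuple(
    f"mtv_{t}" for t in MTV_THRESHOLDS
)

REQUIRED_COLUMNS = ("atv", "ftv_manual", "ftv_semi")


def _mtv_columns(columns) -> list[str]:
    found = []
    for c in columns:
        if isinstance(c, str) and c.startswith("mtv_"):
            try:
                found.append((float(c[4:]), c))
            except ValueError:
                raise InsufficientDataError(f"malformed MTV column name {c!r}")
    return [c for _, c in sorted(found)]


@dataclass(frozen=True)
class CohortVolumeTable:
    """Per-patient volumes (cm³) for every modality; NaN marks missing cells.

    Requires ``atv``, ``ftv_manual`` and ``ftv_semi`` columns plus any number
    of ``mtv_<threshold>`` columns (13 with the default sweep).
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise InsufficientDataError(f"cohort table lacks columns: {missing}")
        cols = list(REQUIRED_COLUMNS) + _mtv_columns(df.columns)
        df = df.loc[:, cols].astype(float)
        df.index.name = "patient_id"
        if not df.index.is_unique:
            raise InsufficientDataError("patient ids must be unique")
        if (df.to_numpy() < 0).any():
            raise InvalidVolumeError("volumes must be non-negative")
        object.__setattr__(self, "data", df)

    @classmethod
    def from_csv(cls, path) -> "CohortVolumeTable":
        df = pd.read_csv(path, comment="#").set_index("patient_id")
        return cls(df)

    def to_csv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.data.to_csv(fh, index_label="patient_id", float_format="%.10g")

    @property
    def modality_columns(self) -> tuple[str, ...]:
        return tuple(c for c in self.data.columns if c != "atv")

    def complete_pairs(self, modality: str) -> tuple[np.ndarray, np.ndarray]:
        if modality not in self.modality_columns:
            raise InsufficientDataError(f"unknown modality column {modality!r}")
        sub = self.data[["atv", modality]].dropna()
        return sub["atv"].to_numpy(), sub[modality].to_numpy()


@dataclass(frozen=True)
class PairedDifference:
    modality: str
    n: int
    mean_atv: float
    mean_modality: float
    diff_cm3: float
    pct_diff: float
    p_value: float


def difference_from_means(mean_atv: float, mean_modality: float) -> tuple[float, float]:
    """Paired difference of means and its percent-of-ATV form.

    Pure arithmetic on two cohort means: ``diff = mean_atv − mean_modality``
    and ``pct = 100·diff/mean_atv``.
    """
    if mean_atv == 0:
        raise UndefinedStatisticError("percent difference undefined: mean ATV is 0")
    diff = float(mean_atv) - float(mean_modality)
    return diff, 100.0 * diff / float(mean_atv)


def paired_difference(
    table: CohortVolumeTable, modality: str, *, test: str = "t"
) -> PairedDifference:
    """Paired difference of means between ATV and a modality, with a p-value.

    ``test`` is ``"t"`` (two-tailed paired-samples t test, default) or
    ``"wilcoxon"`` (signed-rank).  If every per-patient difference is zero the
    p-value is reported as 1.
    """
    atv, mod = table.complete_pairs(modality)
    if atv.size < 2:
        raise InsufficientDataError(
            f"need >= 2 complete (atv, {modality}) pairs, have {atv.size}"
        )
    diff, pct = difference_from_means(atv.mean(), mod.mean())
    d = atv - mod
    if np.all(d == d[0]):
        # constant differences: the t statistic is 0/0 or infinite
        p = 1.0 if d[0] == 0 else 0.0
    elif test == "t":
        p = float(stats.ttest_rel(atv, mod).pvalue)
    elif test == "wilcoxon":
        p = float(stats.wilcoxon(atv, mod).pvalue)
    else:
        raise UndefinedStatisticError(f"unknown paired test {test!r}")
    return PairedDifference(
        modality=modality,
        n=int(atv.size),
        mean_atv=float(atv.mean()),
        mean_modality=float(mod.mean()),
        diff_cm3=diff,
        pct_diff=pct,
        p_value=p,
    )


def pearson_correlation(table: CohortVolumeTable, modality: str) -> tuple[float, float]:
    """Pearson r between ATV and a modality, with the t-transform p-value."""
    atv, mod = table.complete_pairs(modality)
    if atv.size < 3:
        raise InsufficientDataError(
            f"need >= 3 complete (atv, {modality}) pairs, have {atv.size}"
        )
    if np.std(atv) == 0 or np.std(mod) == 0:
        raise UndefinedStatisticError(
            f"correlation with {modality} undefined: zero variance"
        )
    res = stats.pearsonr(atv, mod)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ConcordanceReport:
    """Per-modality concordance statistics against the anatomical reference.

    ``rows`` is indexed by modality with columns ``n, mean_cm3,
    paired_diff_cm3, pct_diff, p_paired, pearson_r, p_pearson`` (NaN where a
    statistic is undefined).  ``closest_modality`` minimises the absolute
    paired difference; ``best_correlated`` maximises Pearson r.
    """

    atv_mean: float
    rows: pd.DataFrame
    closest_modality: str
    best_correlated: str | None

    def table3(self) -> pd.DataFrame:
        """Means / paired differences table, rounded for display."""
        out = pd.DataFrame(index=["atv", *self.rows.index])
        means = [self.atv_mean, *self.rows["mean_cm3"]]
        out["mean_cm3"] = np.round(means, 1)
        out["paired_diff_cm3"] = [np.nan, *np.round(self.rows["paired_diff_cm3"], 1)]
        out["pct_diff"] = [np.nan, *np.round(self.rows["pct_diff"], 1)]
        out["p_value"] = [np.nan, *np.round(self.rows["p_paired"], 3)]
        return out

    def table4(self) -> pd.DataFrame:
        """Correlation table, rounded for display."""
        out = pd.DataFrame(index=["atv", *self.rows.index])
        out["pearson_r"] = [1.0, *np.round(self.rows["pearson_r"], 3)]
        out["p_value"] = [np.nan, *np.round(self.rows["p_pearson"], 3)]
        return out


def build_report(table: CohortVolumeTable, *, test: str = "t") -> ConcordanceReport:
    """Full concordance report: one row per modality against ATV."""
    records = []
    for modality in table.modality_columns:
        pd_res = paired_difference(table, modality, test=test)
        try:
            r, p_r = pearson_correlation(table, modality)
        except (UndefinedStatisticError, InsufficientDataError):
            r, p_r = np.nan, np.nan
        records.append(
            {
                "modality": modality,
                "n": pd_res.n,
                "mean_cm3": pd_res.mean_modality,
                "paired_diff_cm3": pd_res.diff_cm3,
                "pct_diff": pd_res.pct_diff,
                "p_paired": pd_res.p_value,
                "pearson_r": r,
                "p_pearson": p_r,
            }
        )
    rows = pd.DataFrame.from_records(records).set_index("modality")
    closest = rows["paired_diff_cm3"].abs().idxmin()
    best = None if rows["pearson_r"].isna().all() else rows["pearson_r"].idxmax()
    return ConcordanceReport(
        atv_mean=float(table.data["atv"].mean()),
        rows=rows,
        closest_modality=str(closest),
        best_correlated=None if best is None else str(best),
    )
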