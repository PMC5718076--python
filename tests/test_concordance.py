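import numpy as np
import pandas as pd
import pytest
from scipy import stats

from petmrvol.concordance import (
    MODALITY_COLUMNS,
    CohortVolumeTable,
    build_report,
    difference_from_means,
    paired_difference,
    pearson_correlation,
)
from petmrvol.errors import (
    InsufficientDataError,
    InvalidVolumeError,
    UndefinedStatisticError,
)


def make_table(atv, **overrides):
    """Cohort table with every modality defaulting to a copy of ATV."""
    atv = np.asarray(atv, dtype=float)
    data = {"atv": atv}
    for col in MODALITY_COLUMNS:
        data[col] = overrides.get(col, atv.copy())
    df = pd.DataFrame(data, index=[f"P{i}" for i in range(len(atv))])
    return CohortVolumeTable(df)


class TestPairedDifference:
    def test_three_patient_long_hand_t(self):
        """t = d̄ / (s_d/√n) with n−1 df, computed independently."""
        atv = np.array([40.0, 55.0, 70.0])
        mod = np.array([35.0, 60.0, 61.0])
        res = paired_difference(make_table(atv, ftv_manual=mod), "ftv_manual")
        d = atv - mod
        t = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        p = 2 * stats.t.sf(abs(t), 2)
        assert res.diff_cm3 == pytest.approx(atv.mean() - mod.mean(), abs=1e-12)
        assert res.pct_diff == pytest.approx(
            100 * (atv.mean() - mod.mean()) / atv.mean(), abs=1e-12
        )
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_identical_columns_give_zero_diff_p_one(self):
        res = paired_difference(make_table([30.0, 50.0, 70.0]), "mtv_30")
        assert res.diff_cm3 == 0.0
        assert res.pct_diff == 0.0
        assert res.p_value == 1.0

    def test_wilcoxon_option(self):
        atv = np.array([40.0, 55.0, 70.0, 20.0, 90.0, 35.0])
        mod = atv - np.array([3.0, -1.0, 4.0, 2.0, 5.0, -2.0])
        res = paired_difference(
            make_table(atv, ftv_semi=mod), "ftv_semi", test="wilcoxon"
        )
        assert res.p_value == pytest.approx(
            stats.wilcoxon(atv, mod).pvalue, abs=1e-12
        )

    def test_insufficient_pairs(self):
        table = make_table([10.0, 20.0, 30.0])
        table.data.loc[:, "mtv_80"] = [np.nan, np.nan, 30.0]
        with pytest.raises(InsufficientDataError):
            paired_difference(table, "mtv_80")

    def test_zero_mean_atv_percent_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            difference_from_means(0.0, 10.0)

    def test_negative_volume_rejected_at_table_construction(self):
        with pytest.raises(InvalidVolumeError):
            make_table([-5.0, 20.0])


class TestPearsonCorrelation:
    def test_self_correlation_is_one(self):
        r, _ = pearson_correlation(make_table([30.0, 50.0, 70.0, 20.0]), "mtv_30")
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_reflection_is_minus_one(self):
        atv = np.array([30.0, 50.0, 70.0, 20.0])
        r, _ = pearson_correlation(
            make_table(atv, ftv_manual=100.0 - atv), "ftv_manual"
        )
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_five_pair_closed_form(self):
        atv = np.array([20.0, 35.0, 50.0, 65.0, 90.0])
        mod = np.array([25.0, 30.0, 55.0, 60.0, 95.0])
        r, p = pearson_correlation(make_table(atv, mtv_40=mod), "mtv_40")
        cov = np.mean((atv - atv.mean()) * (mod - mod.mean()))
        r_hand = cov / (atv.std() * mod.std())
        t = r_hand * np.sqrt(3 / (1 - r_hand**2))
        p_hand = 2 * stats.t.sf(abs(t), 3)
        assert r == pytest.approx(r_hand, abs=1e-12)
        assert p == pytest.approx(p_hand, abs=1e-12)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_correlation(
                make_table([30.0, 50.0, 70.0], mtv_20=[5.0, 5.0, 5.0]), "mtv_20"
            )


class TestBuildReport:
    def test_fifteen_modality_rows(self):
        report = build_report(make_table([30.0, 50.0, 70.0]))
        assert len(report.rows) == 15
        assert list(report.rows.index) == list(MODALITY_COLUMNS)

    def test_planted_closest_modality_flagged(self):
        rng = np.random.default_rng(0)
        atv = rng.uniform(20, 90, 12)
        overrides = {
            col: atv + rng.normal(0, 0.5, 12) + offset
            for col, offset in zip(MODALITY_COLUMNS, np.linspace(-21, 21, 15))
        }
        overrides = {c: np.maximum(v, 0) for c, v in overrides.items()}
        report = build_report(make_table(atv, **overrides))
        planted = min(
            MODALITY_COLUMNS,
            key=lambda c: abs(atv.mean() - overrides[c].mean()),
        )
        assert report.closest_modality == planted

    def test_degenerate_constant_cohort(self):
        report = build_report(make_table([42.0, 42.0, 42.0]))
        assert np.allclose(report.rows["paired_diff_cm3"], 0.0)
        assert report.rows["pearson_r"].isna().all()
        assert report.best_correlated is None

    def test_display_tables_shapes_and_rounding(self):
        report = build_report(make_table([30.0, 50.0, 70.3]))
        t3, t4 = report.table3(), report.table4()
        assert list(t3.index) == ["atv", *MODALITY_COLUMNS]
        assert t3.loc["atv", "mean_cm3"] == pytest.approx(50.1)
        assert t4.loc["atv", "pearson_r"] == 1.0


class TestCustomThresholdColumns:
    def test_report_follows_available_mtv_columns(self):
        atv = [30.0, 50.0, 70.0]
        df = pd.DataFrame(
            {"atv": atv, "ftv_manual": atv, "ftv_semi": atv,
             "mtv_40": [28.0, 52.0, 71.0], "mtv_20": [35.0, 55.0, 75.0]},
            index=["P1", "P2", "P3"],
        )
        table = CohortVolumeTable(df)
        assert table.modality_columns == ("ftv_manual", "ftv_semi", "mtv_20", "mtv_40")
        assert len(build_report(table).rows) == 4


class TestCsvRoundTrip:
    def test_cohort_csv_round_trip(self, tmp_path):
        table = make_table([30.0, 50.0, 70.0], mtv_30=[28.0, 52.0, 71.0])
        path = tmp_path / "cohort.csv"
        table.to_csv(path, header_comment="seed=7")
        back = CohortVolumeTable.from_csv(path)
        pd.testing.assert_frame_equal(table.data, back.data)
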