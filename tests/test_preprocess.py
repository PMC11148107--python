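import numpy as np
import pandas as pd
import pytest

from lipscreen import synthetic
from lipscreen.preprocess import (
    filter_precursors,
    matrix_from_records,
    normalize_intensities,
    remove_outliers_iqr,
    scale_unit_interval,
)
from lipscreen.report_io import OPTIONAL_COLUMNS, REPORT_COLUMNS


def make_report(values_by_run, protein="P1", precursor="PEPK/2"):
    """values_by_run: {(dose, replicate): intensity or dict precursor -> value}"""
    rows = []
    for (dose, rep), v in values_by_run.items():
        if not isinstance(v, dict):
            v = {precursor: v}
        for prec, val in v.items():
            rows.append((protein, prec.split("/")[0], prec, dose, rep, val, "FT", True))
    return pd.DataFrame(rows, columns=REPORT_COLUMNS + OPTIONAL_COLUMNS)


class TestNormalize:
    def test_median_log2_removes_constant_factor(self):
        rng = np.random.default_rng(3)
        base = {f"PEP{i}/2": float(v) for i, v in enumerate(rng.uniform(100, 5000, 10))}
        doubled = {k: 2.0 * v for k, v in base.items()}
        report = make_report({(0.0, 1): base, (1.0, 1): doubled})
        nm = normalize_intensities(report, method="median_log2")
        a, b = nm.values.columns
        assert np.allclose(nm.values[a], nm.values[b])

    def test_single_run_rejected(self):
        report = make_report({(0.0, 1): 100.0})
        with pytest.raises(ValueError, match="2 runs"):
            normalize_intensities(report)

    def test_non_positive_intensity_rejected(self):
        report = make_report({(0.0, 1): 100.0, (1.0, 1): -5.0})
        with pytest.raises(ValueError, match="positive"):
            normalize_intensities(report)

    def test_vst_flattens_mean_variance_trend(self):
        """On raw-scale heteroskedastic data (variance proportional to the
        mean) the glog transform reduces the |residual| vs mean slope
        relative to plain log2."""
        rng = np.random.default_rng(8)
        n_prec, n_run = 200, 8
        means = rng.uniform(50, 5000, n_prec)
        noise = rng.normal(0, 1, (n_prec, n_run)) * np.sqrt(40.0 * means)[:, None]
        raw = np.clip(means[:, None] + noise, 1.0, None)
        rows = []
        for i in range(n_prec):
            for j in range(n_run):
                rows.append((f"P{i//5}", f"PEP{i}", f"PEP{i}/2",
                             float(j // 2), j % 2 + 1, raw[i, j], "FT", True))
        report = pd.DataFrame(rows, columns=REPORT_COLUMNS + OPTIONAL_COLUMNS)

        def trend_slope(mat):
            m = mat.mean(axis=1)
            resid = np.abs(mat - mat.mean(axis=1, keepdims=True)).mean(axis=1)
            return abs(np.polyfit(m, resid, 1)[0])

        log2_mat = np.log2(raw)
        vst_mat = normalize_intensities(report, method="vst").values.to_numpy()
        # align rows (pivot sorts the index)
        assert trend_slope(vst_mat) < trend_slope(log2_mat)

    def test_vst_preserves_within_run_rank_order(self):
        report, _ = synthetic.generate_screen(n_proteins=5, seed=2)
        complete = report.dropna(subset=["intensity"])
        nm = normalize_intensities(complete, method="vst")
        raw, _, _ = matrix_from_records(complete)
        for col in nm.values.columns:
            a = raw[col].to_numpy(dtype=float)
            b = nm.values[col].to_numpy(dtype=float)
            mask = np.isfinite(a) & np.isfinite(b)
            order = np.argsort(a[mask])
            assert np.all(np.diff(b[mask][order]) >= 0)


class TestOutliers:
    def _matrix(self, values, dose=1.0):
        report = make_report({(dose, i + 1): v for i, v in enumerate(values)})
        report = pd.concat(
            [report, make_report({(0.0, 1): 10.0, (0.0, 2): 10.0})], ignore_index=True
        )
        return normalize_intensities(report, method="median_log2")

    def test_flags_value_beyond_upper_fence(self):
        # on the log2-free scale: work directly on a constructed matrix
        from lipscreen.preprocess import NormalizedMatrix

        values = pd.DataFrame(
            {"1_r1": [1.0], "1_r2": [2.0], "1_r3": [3.0], "1_r4": [100.0]},
            index=["PEPK/2"],
        )
        runs = pd.DataFrame(
            {"dose": [1.0] * 4, "replicate": [1, 2, 3, 4]},
            index=values.columns,
        )
        prec = pd.DataFrame(
            {"protein_id": ["P1"], "peptide_seq": ["PEPK"], "tryptic_type": ["FT"]},
            index=values.index,
        )
        nm = NormalizedMatrix(values=values, runs=runs, precursors=prec)
        out = remove_outliers_iqr(nm)
        got = out.values.iloc[0].tolist()
        # type-7: Q1=1.75, Q3=27.25, IQR=25.5, upper fence 65.5 -> 100 masked
        assert got[:3] == [1.0, 2.0, 3.0]
        assert np.isnan(got[3])

    def test_constant_replicates_untouched(self):
        from lipscreen.preprocess import NormalizedMatrix

        values = pd.DataFrame({f"1_r{i}": [5.0] for i in range(1, 5)}, index=["X/2"])
        runs = pd.DataFrame({"dose": [1.0] * 4, "replicate": range(1, 5)}, index=values.columns)
        prec = pd.DataFrame({"protein_id": ["P1"], "peptide_seq": ["X"],
                             "tryptic_type": ["FT"]}, index=values.index)
        out = remove_outliers_iqr(NormalizedMatrix(values, runs, prec))
        assert out.values.iloc[0].tolist() == [5.0] * 4

    def test_two_replicates_below_minimum_group_size(self):
        from lipscreen.preprocess import NormalizedMatrix

        values = pd.DataFrame({"1_r1": [1.0], "1_r2": [1000.0]}, index=["X/2"])
        runs = pd.DataFrame({"dose": [1.0, 1.0], "replicate": [1, 2]}, index=values.columns)
        prec = pd.DataFrame({"protein_id": ["P1"], "peptide_seq": ["X"],
                             "tryptic_type": ["FT"]}, index=values.index)
        out = remove_outliers_iqr(NormalizedMatrix(values, runs, prec))
        assert out.values.iloc[0].tolist() == [1.0, 1000.0]

    def test_second_pass_removes_under_one_percent(self, seeded_screen):
        report, _ = seeded_screen
        nm = normalize_intensities(report, method="median_log2")
        once = remove_outliers_iqr(nm)
        twice = remove_outliers_iqr(once)
        extra = np.isfinite(once.values.to_numpy()).sum() - np.isfinite(
            twice.values.to_numpy()
        ).sum()
        assert extra < 0.01 * np.isfinite(nm.values.to_numpy()).sum()


class TestCoverageFilter:
    def _screen_matrix(self):
        report, _ = synthetic.generate_screen(n_proteins=8, missing_rate=0.0, seed=4)
        return normalize_intensities(report, method="median_log2")

    def test_full_coverage_retained(self):
        nm = self._screen_matrix()
        out = filter_precursors(nm)
        assert len(out.values) == len(nm.values)

    def test_precursor_in_too_few_conditions_removed(self):
        nm = self._screen_matrix()
        victim = nm.values.index[0]
        # keep data in only 4 of 7 dose conditions
        drop_cols = [c for d in nm.doses[4:] for c in nm.runs_at_dose(d)]
        nm.values.loc[victim, drop_cols] = np.nan
        out = filter_precursors(nm)
        assert victim not in out.values.index

    def test_protein_with_single_survivor_removed(self):
        nm = self._screen_matrix()
        prot = nm.precursors["protein_id"].iloc[0]
        members = nm.precursors.index[nm.precursors["protein_id"] == prot]
        for victim in members[1:]:  # leave exactly one survivor
            nm.values.loc[victim] = np.nan
        out = filter_precursors(nm)
        assert prot not in set(out.precursors["protein_id"])

    def test_monotone_in_thresholds(self):
        report, _ = synthetic.generate_screen(n_proteins=10, missing_rate=0.15, seed=9)
        nm = normalize_intensities(report, method="median_log2")
        strict = filter_precursors(nm, min_replicates=4, min_conditions=6)
        relaxed = filter_precursors(nm, min_replicates=3, min_conditions=5)
        assert set(strict.values.index) <= set(relaxed.values.index)


class TestUnitScaling:
    def test_min_max_scaling(self):
        from lipscreen.preprocess import NormalizedMatrix

        values = pd.DataFrame({"0_r1": [5.0], "1_r1": [7.0], "2_r1": [9.0]}, index=["X/2"])
        runs = pd.DataFrame({"dose": [0.0, 1.0, 2.0], "replicate": [1, 1, 1]},
                            index=values.columns)
        prec = pd.DataFrame({"protein_id": ["P1"], "peptide_seq": ["X"],
                             "tryptic_type": ["FT"]}, index=values.index)
        out = scale_unit_interval(NormalizedMatrix(values, runs, prec))
        assert out.values.iloc[0].tolist() == [0.0, 0.5, 1.0]
        assert out.scaled

    def test_constant_precursor_flagged(self):
        from lipscreen.preprocess import NormalizedMatrix

        values = pd.DataFrame({"0_r1": [3.0], "1_r1": [3.0], "2_r1": [3.0]}, index=["X/2"])
        runs = pd.DataFrame({"dose": [0.0, 1.0, 2.0], "replicate": [1, 1, 1]},
                            index=values.columns)
        prec = pd.DataFrame({"protein_id": ["P1"], "peptide_seq": ["X"],
                             "tryptic_type": ["FT"]}, index=values.index)
        out = scale_unit_interval(NormalizedMatrix(values, runs, prec))
        assert "X/2" in out.constant
        assert out.values.iloc[0].isna().all()

    def test_every_scaled_row_spans_unit_interval(self, seeded_screen):
        report, _ = seeded_screen
        nm = normalize_intensities(report, method="median_log2")
        out = scale_unit_interval(nm)
        vals = out.values.to_numpy()
        for i, prec in enumerate(out.values.index):
            if prec in out.constant:
                continue
            row = vals[i][np.isfinite(vals[i])]
            assert row.min() == pytest.approx(0.0)
            assert row.max() == pytest.approx(1.0)
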