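import numpy as np
import pandas as pd
import pytest

import irdm
from irdm.panels_io import ExpressionMatrix
from irdm.preprocess import (
    CountsTable,
    center_standardize,
    knn_impute,
    normalize_counts,
    qc_filter,
    run_pipeline,
)


def make_table(counts: dict, lengths=None, totals=None, genes=None):
    df = pd.DataFrame(counts, index=genes or [f"G{i}" for i in range(len(next(iter(counts.values()))))])
    lengths = pd.Series(lengths if lengths is not None else 1000.0, index=df.index, dtype=float)
    totals = pd.Series(totals, dtype=float) if totals is not None else None
    return CountsTable(df, lengths, totals)


class TestQCFilter:
    def test_reads_rule_boundary(self):
        # 9999 and exactly 10000 both fail ("larger than 10000"); 10001 passes
        t = make_table(
            {"a": [9999], "b": [10000], "c": [10001]},
            genes=["G0"],
        )
        _, report = qc_filter(t, panel_size=1)
        assert not report.loc["a", "pass"]
        assert not report.loc["b", "pass"]
        assert report.loc["c", "pass"]

    def test_missing_gene_rule(self):
        # 22 of 72 genes at zero (30.6%) fails; 21 of 72 (29.2%) passes
        genes = [f"G{i}" for i in range(72)]
        col_fail = [0] * 22 + [1000] * 50
        col_pass = [0] * 21 + [1000] * 51
        t = make_table({"fail": col_fail, "ok": col_pass}, genes=genes)
        _, report = qc_filter(t, panel_size=72)
        assert not report.loc["fail", "pass"]
        assert "missing gene fraction" in report.loc["fail", "reasons"]
        assert report.loc["ok", "pass"]

    def test_pass_case(self):
        genes = [f"G{i}" for i in range(72)]
        col = [0] * 5 + [300] * 67
        t = make_table({"s": col}, genes=genes)
        passed, report = qc_filter(t)
        assert report.loc["s", "pass"]
        assert passed.sample_ids == ["s"]

    def test_decisions_are_per_sample(self):
        genes = [f"G{i}" for i in range(72)]
        rng = np.random.default_rng(0)
        cols = {f"s{i}": rng.integers(0, 2000, size=72) for i in range(6)}
        t = make_table(cols, genes=genes)
        _, rep_all = qc_filter(t)
        # same decision when each sample is QC'ed alone
        for s in cols:
            t1 = make_table({s: cols[s]}, genes=genes)
            _, rep1 = qc_filter(t1)
            assert rep1.loc[s, "pass"] == rep_all.loc[s, "pass"]


class TestNormalizeCounts:
    def test_cpm_proportions(self):
        t = make_table({"s": [10, 90]}, genes=["A", "B"])
        m = normalize_counts(t)
        # CPM 1e5 and 9e5 before log
        assert m.values.loc["A", "s"] == pytest.approx(np.log2(1 + 1e5))
        assert m.values.loc["B", "s"] == pytest.approx(np.log2(1 + 9e5))
        assert m.state == "cpm_log2"

    def test_library_size_invariance(self):
        t1 = make_table({"s": [10, 90, 50]}, genes=["A", "B", "C"])
        t2 = make_table({"s": [20, 180, 100]}, genes=["A", "B", "C"])
        pd.testing.assert_frame_equal(
            normalize_counts(t1).values, normalize_counts(t2).values
        )

    def test_length_halving_doubles_share(self):
        t1 = make_table({"s": [100, 100]}, lengths=[1000.0, 1000.0], genes=["A", "B"])
        t2 = make_table({"s": [100, 100]}, lengths=[500.0, 1000.0], genes=["A", "B"])
        cpm1 = 2 ** normalize_counts(t1).values - 1
        cpm2 = 2 ** normalize_counts(t2).values - 1
        share1 = cpm1.loc["A", "s"] / cpm1.loc["B", "s"]
        share2 = cpm2.loc["A", "s"] / cpm2.loc["B", "s"]
        assert share2 == pytest.approx(2 * share1)

    def test_zero_counts_become_missing(self):
        t = make_table({"s": [0, 90], "t": [10, 90]}, genes=["A", "B"])
        m = normalize_counts(t)
        assert np.isnan(m.values.loc["A", "s"])
        assert not np.isnan(m.values.loc["A", "t"])

    def test_all_zero_sample_fails(self):
        t = make_table({"s": [0, 0], "t": [5, 5]}, genes=["A", "B"])
        with pytest.raises(ValueError):
            normalize_counts(t)


class TestKnnImpute:
    def test_single_missing_nearest_neighbor(self):
        vals = pd.DataFrame(
            {
                "a": [1.0, 2.0, 3.0],
                "b": [1.1, 2.1, np.nan],
                "c": [9.0, 9.0, 5.0],
                "d": [8.5, 9.5, 6.0],
            },
            index=["G0", "G1", "G2"],
        )
        m = ExpressionMatrix(vals, state="cpm_log2")
        out = knn_impute(m, k=1)
        # nearest sample to b (over shared genes) is a -> imputed 3.0
        assert out.values.loc["G2", "b"] == pytest.approx(3.0)

    def test_no_missing_identity(self):
        vals = pd.DataFrame(np.arange(12.0).reshape(4, 3), columns=["a", "b", "c"])
        vals.index = [f"G{i}" for i in range(4)]
        m = ExpressionMatrix(vals, state="cpm_log2")
        out = knn_impute(m)
        assert np.array_equal(out.values.to_numpy(), vals.to_numpy())

    def test_imputed_within_observed_range_and_observed_untouched(self):
        rng = np.random.default_rng(1)
        for rep in range(25):
            vals = rng.normal(size=(10, 12))
            mask = rng.uniform(size=vals.shape) < 0.15
            # cap per-gene missing below 30%
            for i in range(10):
                while mask[i].mean() >= 0.3:
                    mask[i, rng.integers(0, 12)] = False
            data = np.where(mask, np.nan, vals)
            df = pd.DataFrame(
                data, index=[f"G{i}" for i in range(10)],
                columns=[f"s{j}" for j in range(12)],
            )
            out = knn_impute(ExpressionMatrix(df, state="cpm_log2"), k=4).values.to_numpy()
            obs = ~np.isnan(data)
            assert np.array_equal(out[obs], data[obs])
            for i in range(10):
                if (~obs[i]).any():
                    lo, hi = np.nanmin(data[i]), np.nanmax(data[i])
                    assert (out[i][~obs[i]] >= lo - 1e-9).all()
                    assert (out[i][~obs[i]] <= hi + 1e-9).all()

    def test_over_missing_gene_rejected(self):
        vals = pd.DataFrame(
            {"a": [1.0, np.nan], "b": [1.0, np.nan], "c": [1.0, 5.0]},
            index=["G0", "G1"],
        )
        with pytest.raises(ValueError, match="G1"):
            knn_impute(ExpressionMatrix(vals, state="cpm_log2"))

    def test_wrong_state_rejected(self):
        m = ExpressionMatrix(
            pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["G0"]), state="raw_counts"
        )
        with pytest.raises(ValueError):
            knn_impute(m)


class TestCenterStandardize:
    def test_row_median_example(self):
        vals = pd.DataFrame(
            np.array([[1.0, 2.0, 3.0], [4.0, 8.0, 5.0], [0.0, -3.0, 7.0]]),
            index=["A", "B", "C"],
            columns=["a", "b", "c"],
        )
        out = center_standardize(ExpressionMatrix(vals, state="cpm_log2"))
        med = out.values.median(axis=1)
        sd = out.values.std(axis=0, ddof=1)
        assert med.abs().max() < 1e-9
        assert (sd - 1).abs().max() < 1e-9
        assert out.state == "centered_standardized"
        out.validate()

    def test_constant_column_named(self):
        vals = pd.DataFrame(
            {"good": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]},
            index=["A", "B", "C"],
        )
        with pytest.raises(ValueError, match="flat"):
            center_standardize(ExpressionMatrix(vals, state="cpm_log2"))

    def test_missing_values_rejected(self):
        vals = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]}, index=["A", "B"])
        with pytest.raises(ValueError):
            center_standardize(ExpressionMatrix(vals, state="cpm_log2"))

    def test_wrong_state_rejected(self):
        vals = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}, index=["A", "B"])
        m = center_standardize(ExpressionMatrix(vals, state="cpm_log2"))
        with pytest.raises(ValueError):
            center_standardize(m)  # already centered_standardized


class TestPipeline:
    def test_full_chain_on_synthetic_counts(self):
        cohort = irdm.generate_cohort(irdm.CohortSpec(n_samples=25, seed=3))
        table = irdm.generate_counts(
            cohort, depth=200_000, dropout=0.03, low_read_samples=["S0001"]
        )
        final, report = run_pipeline(table)
        assert not report.loc["S0001", "pass"]
        assert final.state == "centered_standardized"
        assert final.n_samples == int(report["pass"].sum())
        assert not final.values.isna().any().any()
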