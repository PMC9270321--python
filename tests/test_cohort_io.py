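"""Cohort IO: schema validation, exclusion accounting, IPW, asset index,
multimorbidity categories and design-based prevalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import morbinet as mn
from morbinet.cohort_io import (
    CohortTable,
    SchemaError,
    Variable,
    VariableSchema,
    Z95,
)
from tests.conftest import flat_table, small_schema


class TestReadWrite:
    def test_round_trip(self, tmp_path, rng):
        cfg = mn.SimulationConfig(n_subjects=400, p_diseases=5, seed=3)
        table, _ = mn.generate_cohort(cfg)
        path = tmp_path / "cohort.csv"
        mn.write_cohort(table, path)
        back = mn.read_cohort(path, table.schema)
        a = table.df.astype(object).where(table.df.notna(), None)
        b = back.df.astype(object).where(back.df.notna(), None)
        for col in table.schema.names():
            av, bv = a[col].tolist(), b[col].tolist()
            if table.schema[col].vtype == "continuous":
                assert np.allclose(
                    [x for x in av if x is not None],
                    [x for x in bv if x is not None],
                )
            else:
                assert av == bv

    def test_non_binary_disease_value_reports_location(self, tmp_path, rng):
        table = flat_table(5, rng)
        path = tmp_path / "bad.csv"
        mn.write_cohort(table, path)
        raw = path.read_text().splitlines()
        fields = raw[3].split(",")
        fields[0] = "2"  # d1 of row index 2
        raw[3] = ",".join(fields)
        path.write_text("\n".join(raw) + "\n")
        with pytest.raises(SchemaError, match=r"row 2.*'d1'"):
            mn.read_cohort(path, table.schema)

    def test_missing_weight_column_is_fatal(self, tmp_path, rng):
        table = flat_table(5, rng)
        path = tmp_path / "noweight.csv"
        table.df.drop(columns=["weight"]).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="design"):
            mn.read_cohort(path, table.schema)

    def test_schema_yaml_round_trip(self, tmp_path):
        schema = small_schema()
        p = tmp_path / "schema.yml"
        schema.to_yaml(p)
        back = VariableSchema.from_yaml(p)
        assert back.to_dict() == schema.to_dict()


class TestExclusionReport:
    def test_counts_and_percentage(self, rng):
        table = flat_table(1000, rng)
        df = table.df.copy()
        df.loc[df.index[:64], "d1"] = np.nan
        report, kept = mn.exclusion_report(CohortTable(df, table.schema), ["d1", "d2"])
        assert report.n_baseline == 1000
        assert report.n_missing == 64
        assert report.n_final == 936
        assert report.pct_missing == 6.4
        assert len(kept) == 936

    def test_no_missing_leaves_table_unchanged(self, rng):
        table = flat_table(50, rng)
        report, kept = mn.exclusion_report(table, ["d1", "d2"])
        assert report.n_missing == 0
        pd.testing.assert_frame_equal(kept.df, table.df)

    def test_all_missing_warns_and_empties(self, rng, caplog):
        table = flat_table(10, rng)
        df = table.df.copy()
        df["d1"] = np.nan
        with caplog.at_level("WARNING"):
            report, kept = mn.exclusion_report(CohortTable(df, table.schema), ["d1"])
        assert report.n_final == 0 and len(kept) == 0
        assert any("excluded" in r.message for r in caplog.records)

    def test_empty_analysis_vars_rejected(self, rng):
        with pytest.raises(ValueError):
            mn.exclusion_report(flat_table(5, rng), [])

    @settings(deadline=None, max_examples=20)
    @given(n_miss=st.integers(0, 40))
    def test_row_conservation(self, n_miss):
        rng = np.random.default_rng(7)
        table = flat_table(40, rng)
        df = table.df.copy()
        df.loc[df.index[:n_miss], "d2"] = np.nan
        report, kept = mn.exclusion_report(CohortTable(df, table.schema), ["d2"])
        assert report.n_final + report.n_missing == report.n_baseline == 40
        assert len(kept) == report.n_final


class TestIPW:
    def test_no_missing_rows_all_multipliers_one(self, rng):
        table = flat_table(100, rng)
        mult = mn.compute_ipw(table, ["g"], analysis_vars=["d1"])
        assert np.allclose(mult, 1.0)

    def test_mcar_multiplier_is_inverse_complete_rate(self, rng):
        table = flat_table(4000, rng)
        df = table.df.copy()
        drop = rng.random(4000) < 0.25
        df.loc[drop, "d1"] = np.nan
        mult = mn.compute_ipw(CohortTable(df, table.schema), ["g"], analysis_vars=["d1"])
        rate = 1 - drop.mean()
        got = mult[~drop].to_numpy()
        assert np.allclose(got, 1 / rate, rtol=0.05)
        assert mult[drop].isna().all()

    def test_constant_indicator_all_missing_refused(self, rng):
        table = flat_table(20, rng)
        df = table.df.copy()
        df["d1"] = np.nan
        with pytest.raises(ValueError, match="constant"):
            mn.compute_ipw(CohortTable(df, table.schema), ["g"], analysis_vars=["d1"])

    def test_mar_debiasing_beats_naive(self):
        """IPW-weighted mean is less biased than the naive complete-case mean
        when missingness and the variable both depend on a covariate."""
        true_mean = 0.5 * 0.2 + 0.5 * 0.6
        naive_err, ipw_err = [], []
        for r in range(50):
            rng = np.random.default_rng(30000 + r)
            n = 2000
            xb = rng.integers(0, 2, n)
            d1 = (rng.random(n) < np.where(xb == 1, 0.6, 0.2)).astype(float)
            d1m = pd.array(
                np.where(rng.random(n) < np.where(xb == 1, 0.35, 0.05), np.nan, d1),
                dtype="Float64",
            )
            table = flat_table(n, rng, extra_cols={"d1": d1m, "g": np.where(xb == 1, "b", "a")})
            mult = mn.compute_ipw(table, ["g"], analysis_vars=["d1"])
            cc = table.df["d1"].notna()
            vals = table.df.loc[cc, "d1"].astype(float)
            naive_err.append(vals.mean() - true_mean)
            ipw_err.append(np.average(vals, weights=mult[cc]) - true_mean)
        assert abs(np.mean(ipw_err)) < abs(np.mean(naive_err))


class TestAssetIndex:
    @staticmethod
    def _assets(rng, n=600, dominant=False):
        X = rng.normal(0, 1, size=(n, 12))
        if dominant:
            # a high-variance variable echoed by several indicators dominates
            # the correlation structure (the score is correlation-scale PCA)
            X[:, 0] = rng.normal(0, 20, size=n)
            for j in range(1, 5):
                X[:, j] = X[:, 0] / 20 + rng.normal(0, 0.05, size=n)
        return X

    @staticmethod
    def _table_with(rng, X):
        cols = {f"a{i + 1}": X[:, i] for i in range(X.shape[1])}
        extra = tuple(Variable(f"a{i + 1}", "continuous", "covariate") for i in range(12))
        return flat_table(len(X), rng, extra_cols=cols, extra_vars=extra)

    def test_dominant_variable_drives_score(self, rng):
        X = self._assets(rng, dominant=True)
        table = self._table_with(rng, X)
        _, score, _ = mn.asset_index(table, [f"a{i + 1}" for i in range(12)])
        assert abs(np.corrcoef(score, X[:, 0])[0, 1]) > 0.99

    def test_quintiles_are_balanced_on_equal_weights(self, rng):
        X = self._assets(rng, n=1000)
        table = self._table_with(rng, X)
        cats, _, _ = mn.asset_index(table, [f"a{i + 1}" for i in range(12)])
        counts = cats.value_counts()
        assert counts.max() - counts.min() <= 2

    def test_sign_flip_of_inputs_keeps_categories(self, rng):
        X = self._assets(rng)
        X[:, 0] += 0.5 * np.abs(rng.normal(size=len(X)))  # give the score some skew
        names = [f"a{i + 1}" for i in range(12)]
        t1 = self._table_with(rng, X)
        t2 = self._table_with(rng, -X)
        c1, s1, _ = mn.asset_index(t1, names)
        c2, s2, _ = mn.asset_index(t2, names)
        assert np.allclose(s1, s2)
        assert (c1 == c2).all()

    def test_fewer_than_12_vars_rejected(self, rng):
        table = self._table_with(rng, self._assets(rng))
        with pytest.raises(ValueError, match="12"):
            mn.asset_index(table, ["a1", "a2"])


class TestMultimorbidity:
    def test_categories_from_counts(self, rng):
        table = flat_table(4, rng)
        df = table.df.copy()
        df["d1"] = [0.0, 1.0, 1.0, np.nan]
        df["d2"] = [0.0, 1.0, 1.0, 1.0]
        extra = pd.DataFrame({"d3": [0.0, 0.0, 1.0, 1.0]})
        schema = VariableSchema(
            [Variable("d3", "binary", "disease")] + list(table.schema.variables)
        )
        df.insert(0, "d3", extra["d3"])
        cats = mn.multimorbidity_category(CohortTable(df, schema))
        assert list(cats.astype(object))[:3] == ["<=1", "2", ">=3"]
        assert pd.isna(cats.iloc[3])


class TestWeightedPrevalence:
    def test_unit_weights_single_stratum_equals_classic(self, rng):
        table = flat_table(400, rng)
        pe = mn.weighted_prevalence(table, "y")
        y = table.df["y"].astype(float).to_numpy()
        n, p = len(y), y.mean()
        assert pe.estimate == pytest.approx(p, abs=1e-12)
        se_logit = np.sqrt(p * (1 - p) / (n - 1)) / (p * (1 - p))
        logit = np.log(p / (1 - p))
        lo = 1 / (1 + np.exp(-(logit - Z95 * se_logit)))
        hi = 1 / (1 + np.exp(-(logit + Z95 * se_logit)))
        assert pe.ci_low == pytest.approx(lo, abs=1e-12)
        assert pe.ci_high == pytest.approx(hi, abs=1e-12)

    def test_zero_prevalence_degenerate_interval(self, rng):
        table = flat_table(50, rng, extra_cols={"y": 0.0})
        pe = mn.weighted_prevalence(table, "y")
        assert (pe.estimate, pe.ci_low, pe.ci_high) == (0.0, 0.0, 0.0)

    def test_single_psu_stratum_errors_and_collapses(self, rng):
        table = flat_table(60, rng, n_psu=5)
        df = table.df.copy()
        df.loc[df.index[0], "stratum"] = "s2"
        df.loc[df.index[0], "psu"] = 999
        lone = CohortTable(df, table.schema)
        with pytest.raises(ValueError, match="s2"):
            mn.weighted_prevalence(lone, "y")
        pe = mn.weighted_prevalence(lone, "y", single_psu="collapse")
        assert 0 <= pe.ci_low <= pe.estimate <= pe.ci_high <= 1

    def test_ci_covers_true_prevalence(self):
        """Moderate-replicate version of the design-based coverage check."""
        cover = 0
        B = 60
        for r in range(B):
            cfg = mn.SimulationConfig(
                n_subjects=2000, p_diseases=8, missing_fraction=0.0, seed=40000 + r
            )
            table, _ = mn.generate_cohort(cfg)
            pe = mn.weighted_prevalence(table, "hospitalisation")
            cover += pe.ci_low <= 0.10 <= pe.ci_high
        assert cover / B > 0.88
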