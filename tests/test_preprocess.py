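"""Curation: sparsity pruning, one-hot expansion, token collapse, phi filter."""

import warnings

import numpy as np
import pandas as pd
import pytest

from cohortnet.preprocess import (
    FeatureMatrix,
    correlation_filter,
    curate,
    drop_sparse_features,
    one_hot_encode,
    skipped_to_no,
)
from cohortnet.synthetic import SurveyTable


def _table(columns: dict) -> SurveyTable:
    n = len(next(iter(columns.values())))
    idx = pd.Index([f"S{i}" for i in range(n)], name="subject_id")
    return SurveyTable(data=pd.DataFrame(columns, index=idx, dtype=object))


class TestDropSparse:
    def test_retained_set_matches_direct_missing_count(self):
        rng = np.random.default_rng(0)
        miss = [0.0, 0.1, 0.2, 0.3, 0.39, 0.41, 0.5, 0.7, 0.9, 0.99]
        n = 1000
        cols = {}
        for j, rate in enumerate(miss):
            vals = np.full(n, "yes", dtype=object)
            vals[rng.random(n) < rate] = ""
            cols[f"f{j}"] = vals
        table = _table(cols)
        kept = drop_sparse_features(table, 0.6)
        observed_missing = (table.data == "").mean(axis=0)
        expected = [c for c in table.data.columns if observed_missing[c] < 0.4]
        assert list(kept.data.columns) == expected
        assert "f0" in kept.data.columns       # fully observed feature retained
        assert "f9" not in kept.data.columns   # 99%-missing feature dropped

    def test_all_features_dropped_is_an_error(self):
        table = _table({"f": [""] * 10})
        with pytest.raises(ValueError):
            drop_sparse_features(table, 0.6)

    def test_keep_exempts_protected_columns(self):
        table = _table({"f": [""] * 9 + ["yes"], "g": ["yes"] * 10})
        kept = drop_sparse_features(table, 0.6, keep=["f"])
        assert set(kept.data.columns) == {"f", "g"}


class TestOneHot:
    def test_three_level_variable_becomes_three_columns(self):
        table = _table({"age": ["18-30", "31-45", "46+", "18-30"]})
        out, prov = one_hot_encode(table)
        assert sorted(out.data.columns) == ["age=18-30", "age=31-45", "age=46+"]
        assert prov["age=46+"] == ("age", "46+")
        # exactly one derived column is yes per observed subject
        yes = (out.data == "yes").sum(axis=1)
        assert (yes == 1).all()

    def test_binary_column_passes_through(self):
        table = _table({"q": ["yes", "no", "skipped", ""]})
        out, _ = one_hot_encode(table)
        assert list(out.data.columns) == ["q"]
        assert list(out.data["q"]) == ["yes", "no", "skipped", ""]

    def test_expanded_column_count_equals_level_sum(self):
        # 36 binary pass-throughs plus 12 multi-level questions whose level
        # counts sum to 62 expand to 98 columns in total.
        rng = np.random.default_rng(1)
        n = 60
        cols = {f"b{j}": rng.choice(["yes", "no"], n) for j in range(36)}
        level_counts = [5] * 10 + [6, 6]
        assert sum(level_counts) == 62
        for j, levels in enumerate(level_counts):
            cols[f"m{j}"] = rng.choice([f"v{l}" for l in range(levels)], n)
        out, _ = one_hot_encode(_table(cols))
        assert out.data.shape[1] == 36 + 62 == 98

    def test_missing_source_propagates_to_derived_columns(self):
        table = _table({"m": ["a", "b", "", "a"]})
        out, _ = one_hot_encode(table)
        assert (out.data.loc["S2"] == "").all()

    def test_single_level_column_warns(self):
        table = _table({"m": ["only", "only", "only", ""]})
        with pytest.warns(UserWarning, match="single observed level"):
            one_hot_encode(table)


class TestSkippedToNo:
    def test_token_domain_enumeration(self):
        table = _table({"q": ["yes", "no", "skipped", ""]})
        out = skipped_to_no(table)
        assert list(out.data["q"]) == [1, 0, 0, 0]


class TestCorrelationFilter:
    def _matrix(self, frame: pd.DataFrame) -> FeatureMatrix:
        return FeatureMatrix(data=frame)

    def test_duplicated_column_dropped(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 50)
        frame = pd.DataFrame({"a": a, "dup": a, "b": rng.integers(0, 2, 50)})
        log = []
        out = correlation_filter(self._matrix(frame), 0.8, log=log)
        assert out.data.shape[1] == 2
        assert len(log) == 1
        assert {log[0]["dropped"], log[0]["partner"]} == {"a", "dup"}
        assert log[0]["r"] == pytest.approx(1.0)

    def test_independent_columns_both_retained(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(
            {"a": rng.integers(0, 2, 400), "b": rng.integers(0, 2, 400)}
        )
        out = correlation_filter(self._matrix(frame), 0.8)
        assert list(out.data.columns) == ["a", "b"]

    def test_exactly_one_member_of_high_pair_removed(self):
        # 5 features where only one pair exceeds |r| = 0.8; verify against a
        # recomputed full correlation matrix afterwards.
        rng = np.random.default_rng(2)
        n = 40
        base = rng.integers(0, 2, n)
        near = base.copy()
        near[:2] = 1 - near[:2]  # |phi| close to 0.9 for n=40
        frame = pd.DataFrame(
            {
                "p1": base,
                "p2": near,
                "r1": rng.integers(0, 2, n),
                "r2": rng.integers(0, 2, n),
                "r3": rng.integers(0, 2, n),
            }
        )
        corr = frame.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert (corr > 0.8).sum() == 2  # the planted pair only (both triangles)
        out = correlation_filter(self._matrix(frame), 0.8)
        assert out.data.shape[1] == 4
        surviving = out.data.corr().abs().to_numpy()
        np.fill_diagonal(surviving, 0)
        assert surviving.max() <= 0.8

    def test_zero_variance_feature_retained_with_warning(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(
            {"const": np.zeros(30, dtype=int), "a": rng.integers(0, 2, 30)}
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            out = correlation_filter(self._matrix(frame), 0.8)
        assert "const" in out.data.columns

    def test_protected_partner_survives(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 2, 50)
        frame = pd.DataFrame({"keepme": a, "dup": a, "b": rng.integers(0, 2, 50)})
        out = correlation_filter(self._matrix(frame), 0.8, protected=["keepme"])
        assert "keepme" in out.data.columns
        assert "dup" not in out.data.columns


class TestCurate:
    def test_output_is_complete_binary(self, tiny_survey_config):
        from cohortnet.synthetic import generate_survey

        table = generate_survey(tiny_survey_config)
        matrix, report = curate(table, protected=("flag",))
        values = matrix.data.to_numpy()
        assert np.isin(values, (0, 1)).all()
        assert not matrix.data.isna().any().any()
        assert "flag" in matrix.data.columns
        assert report["n_subjects"] == 120

    def test_pipeline_idempotent_on_own_output(self, tiny_survey_config):
        from cohortnet.synthetic import generate_survey

        table = generate_survey(tiny_survey_config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            matrix, _ = curate(table, protected=("flag",))
            as_tokens = matrix.data.replace({1: "yes", 0: "no"}).astype(object)
            again, _ = curate(
                SurveyTable(data=as_tokens), protected=("flag",)
            )
        pd.testing.assert_frame_equal(
            matrix.data.astype(np.int8), again.data.astype(np.int8)
        )

    def test_excluded_metadata_columns_removed(self, tiny_survey_config):
        from cohortnet.synthetic import generate_survey

        table = generate_survey(tiny_survey_config)
        table.data["site"] = "chicago"
        matrix, report = curate(table, exclude=("site",), protected=("flag",))
        assert "site" not in matrix.data.columns
        assert report["excluded"] == ["site"]
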