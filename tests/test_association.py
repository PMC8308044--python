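import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import entropy as shannon

from ceda.association import (
    directed_conditional_entropy,
    extract_feature_groups,
    label_feature_ranking,
    mce_matrix,
    mutual_conditional_entropy,
)
from ceda.binning import ContingencyTable


def table_from(counts):
    counts = np.asarray(counts, dtype=int)
    return ContingencyTable(
        tuple(range(counts.shape[0])), tuple(range(counts.shape[1])), counts
    )


def oracle_directed(counts):
    """Independent direct Shannon-formula evaluation, H(col|row)/H(col)."""
    m = np.asarray(counts, dtype=float)
    n = m.sum()
    col = m.sum(axis=0)
    h_col = shannon(col / col.sum(), base=2)
    if h_col == 0:
        return 0.0
    num = 0.0
    for row in m:
        if row.sum() > 0:
            num += (row.sum() / n) * shannon(row / row.sum(), base=2)
    return num / h_col


nonempty_tables = arrays(
    np.int64, st.tuples(st.integers(1, 6), st.integers(1, 6)), elements=st.integers(0, 50)
).filter(lambda m: m.sum() > 0)


class TestConditionalEntropy:
    def test_independent_product_table_is_one(self):
        assert mutual_conditional_entropy(table_from([[1, 1], [1, 1]])) == pytest.approx(1.0)
        assert directed_conditional_entropy(table_from([[2, 4], [1, 2]])) == pytest.approx(1.0)

    def test_permutation_table_is_zero(self):
        t = table_from([[3, 0], [0, 5]])
        assert directed_conditional_entropy(t) == 0.0
        assert mutual_conditional_entropy(t) == 0.0

    def test_worked_asymmetric_example(self):
        t = table_from([[2, 0], [1, 1]])
        # frozen values computed with the direct Shannon-formula oracle:
        # row->col = 0.5 / H(3/4,1/4); col->row = (3/4) H(2/3,1/3) / H(1/2,1/2)
        assert directed_conditional_entropy(t, "row_to_col") == pytest.approx(
            0.6163114534036557, abs=1e-9
        )
        assert directed_conditional_entropy(t, "col_to_row") == pytest.approx(
            0.6887218755408672, abs=1e-9
        )
        assert mutual_conditional_entropy(t) == pytest.approx(0.6525166644722614, abs=1e-9)

    @settings(max_examples=200, deadline=None)
    @given(nonempty_tables)
    def test_matches_direct_formula_and_stays_in_unit_interval(self, counts):
        t = table_from(counts)
        v = directed_conditional_entropy(t, "row_to_col")
        assert abs(v - oracle_directed(counts)) < 1e-12
        assert 0.0 <= v <= 1.0
        assert 0.0 <= directed_conditional_entropy(t, "col_to_row") <= 1.0

    @settings(max_examples=100, deadline=None)
    @given(nonempty_tables)
    def test_symmetry_and_permutation_invariance(self, counts):
        rng = np.random.default_rng(0)
        t = table_from(counts)
        m = mutual_conditional_entropy(t)
        assert m == pytest.approx(mutual_conditional_entropy(table_from(counts.T)), abs=1e-12)
        perm = counts[rng.permutation(counts.shape[0])][:, rng.permutation(counts.shape[1])]
        assert m == pytest.approx(mutual_conditional_entropy(table_from(perm)), abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(nonempty_tables)
    def test_empty_row_and_column_leave_measures_unchanged(self, counts):
        padded = np.pad(counts, ((0, 1), (0, 1)))
        for d in ("row_to_col", "col_to_row"):
            assert directed_conditional_entropy(table_from(counts), d) == pytest.approx(
                directed_conditional_entropy(table_from(padded), d), abs=1e-12
            )

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            directed_conditional_entropy(table_from([[0, 0]]))


class TestMCEMatrix:
    def test_duplicated_feature_has_zero_mce_and_merges_first(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=300)
        df = pd.DataFrame({"a": f, "copy_of_a": f, "b": rng.normal(size=300)})
        m = mce_matrix(df)
        i, j = m.feature_names.index("a"), m.feature_names.index("copy_of_a")
        assert m.values[i, j] == 0.0
        first_merge = set(m.linkage[0, :2].astype(int))
        assert first_merge == {i, j}

    def test_independent_features_near_one(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.uniform(size=(2000, 4)), columns=list("abcd"))
        m = mce_matrix(df, method="equal_frequency", n_bins=10)
        off = m.values[np.triu_indices(4, 1)]
        assert np.all(off >= 0.9)

    def test_iris_minimum_is_petal_pair(self, iris):
        feats = iris[["sepal_length", "sepal_width", "petal_length", "petal_width"]]
        m = mce_matrix(feats)
        off = m.values + np.eye(4) * 9
        i, j = np.unravel_index(np.argmin(off), off.shape)
        assert {m.feature_names[i], m.feature_names[j]} == {"petal_length", "petal_width"}
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)

    def test_single_bin_feature_warns_and_pins_to_one(self):
        df = pd.DataFrame({"const": np.ones(50), "x": np.random.default_rng(3).normal(size=50)})
        with pytest.warns(UserWarning):
            m = mce_matrix(df)
        assert m.values[0, 1] == 1.0


class TestLabelRanking:
    def test_label_duplicate_ranks_first_noise_last(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 3, 600)
        df = pd.DataFrame(
            {
                "leak": y.astype(float),
                "partial": y + rng.normal(0, 0.8, 600),
                "noise": rng.normal(size=600),
            }
        )
        r = label_feature_ranking(df, y)
        assert r.iloc[0]["feature"] == "leak"
        assert r.iloc[0]["mce"] == pytest.approx(0.0, abs=1e-12)
        assert r.iloc[-1]["feature"] == "noise"
        assert r.iloc[-1]["mce"] > 0.85

    def test_iris_petal_features_outrank_sepal_width(self, iris):
        feats = iris[["sepal_length", "sepal_width", "petal_length", "petal_width"]]
        r = label_feature_ranking(feats, iris["species"]).set_index("feature")
        assert r.loc["petal_length", "mce"] < r.loc["sepal_width", "mce"]
        assert r.loc["petal_width", "mce"] < r.loc["sepal_width", "mce"]
        assert {"feature_to_label", "label_to_feature", "mce"} <= set(r.columns)

    def test_single_label_level_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            label_feature_ranking(df, ["a", "a", "a"])


class TestFeatureGroups:
    def test_planted_two_block_structure_recovered(self):
        rng = np.random.default_rng(5)
        u, v = rng.normal(size=400), rng.normal(size=400)
        df = pd.DataFrame(
            {
                "u1": u,
                "u2": u + rng.normal(0, 0.05, 400),
                "v1": v,
                "v2": v + rng.normal(0, 0.05, 400),
            }
        )
        m = mce_matrix(df)
        groups = extract_feature_groups(m)
        members = {frozenset(g.members) for g in groups}
        assert frozenset({"u1", "u2"}) in members
        assert frozenset({"v1", "v2"}) in members

    def test_groups_partition_features(self, iris):
        feats = iris[["sepal_length", "sepal_width", "petal_length", "petal_width"]]
        m = mce_matrix(feats)
        groups = extract_feature_groups(m)
        flat = [f for g in groups for f in g.members]
        assert sorted(flat) == sorted(m.feature_names)
        petal_group = next(g for g in groups if "petal_length" in g.members)
        assert "petal_width" in petal_group.members
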