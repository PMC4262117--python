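import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from bicopam import dataio
from bicopam.binarization import BinarizedPartition
from bicopam.dataio import (
    ExpressionDataset,
    PreprocessingState,
    ReplicateMap,
    StateError,
    align_gene_universe,
    quantile_normalize,
    read_expression_matrix,
    standardize_genes,
    summarize_replicates,
    write_expression_matrix,
)


def raw(values, gene_ids=None, dataset_id="D"):
    values = np.asarray(values, dtype=float)
    return ExpressionDataset(
        dataset_id=dataset_id,
        gene_ids=gene_ids or [f"g{i + 1}" for i in range(values.shape[0])],
        values=values,
        condition_labels=[f"s{j + 1}" for j in range(values.shape[1])],
    )


class TestReadWrite:
    def test_identity_readback(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("gene\ts1\ts2\ng1\t1.0\t2.0\ng2\t3.5\t4.5\ng3\t5\t6\n")
        ds = read_expression_matrix(p)
        assert ds.gene_ids == ["g1", "g2", "g3"]
        assert ds.condition_labels == ["s1", "s2"]
        np.testing.assert_array_equal(ds.values, [[1, 2], [3.5, 4.5], [5, 6]])
        assert ds.state is PreprocessingState.RAW

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("gene\ts1\nYAL001C\t1\nYAL001C\t2\n")
        with pytest.raises(ValueError, match="YAL001C"):
            read_expression_matrix(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("gene\ts1\ts2\ng1\t1\t2\ng2\t3\n")
        with pytest.raises(ValueError, match="line 3"):
            read_expression_matrix(p)

    def test_non_numeric_cell_names_coordinates(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("gene\ts1\ts2\ng1\t1\tNA\n")
        with pytest.raises(ValueError, match="line 2"):
            read_expression_matrix(p)

    def test_round_trip(self, tmp_path):
        ds = raw([[1.25, 2.5], [3.0, -4.125]])
        write_expression_matrix(ds, tmp_path / "out.tsv")
        back = read_expression_matrix(tmp_path / "out.tsv", dataset_id="D")
        np.testing.assert_allclose(back.values, ds.values)
        assert back.gene_ids == ds.gene_ids


class TestAlignUniverse:
    def test_reorder_and_drop(self):
        d1 = raw([[1, 1], [2, 2]], gene_ids=["g2", "g1"])
        d2 = raw([[3, 3], [4, 4], [5, 5]], gene_ids=["g1", "g2", "g3"])
        out, uni = align_gene_universe([d1, d2], ["g1", "g2"])
        assert uni == ["g1", "g2"]
        assert out[0].gene_ids == out[1].gene_ids == ["g1", "g2"]
        np.testing.assert_array_equal(out[0].values, [[2, 2], [1, 1]])
        np.testing.assert_array_equal(out[1].values, [[3, 3], [4, 4]])

    def test_strict_mode_missing_gene(self):
        d1 = raw([[1, 1]], gene_ids=["g1"])
        with pytest.raises(ValueError, match="g2.*absent|absent.*g2"):
            align_gene_universe([d1], ["g1", "g2"], mode="strict")

    def test_intersection_mode_shrinks(self):
        d1 = raw([[1, 1]], gene_ids=["g1"])
        d2 = raw([[1, 1], [2, 2]], gene_ids=["g1", "g2"])
        _, uni = align_gene_universe([d1, d2], ["g1", "g2"], mode="intersection")
        assert uni == ["g1"]


class TestQuantileNormalize:
    def test_hand_example(self):
        # columns (1,3) and (2,4): rank means are (1.5, 3.5)
        ds = quantile_normalize(raw([[1, 2], [3, 4]]))
        np.testing.assert_allclose(ds.values, [[1.5, 1.5], [3.5, 3.5]])
        assert ds.state is PreprocessingState.NORMALIZED

    def test_identical_columns_fixed_point(self):
        ds = quantile_normalize(raw([[1, 1], [5, 5], [2, 2]]))
        np.testing.assert_allclose(ds.values, [[1, 1], [5, 5], [2, 2]])

    def test_tie_handling_bolstad(self):
        # ties within a column get the mean of the spanned rank values
        ds = quantile_normalize(raw([[1, 10], [1, 20], [4, 30]]))
        col0 = ds.values[:, 0]
        assert col0[0] == col0[1] == pytest.approx((col0[0] + col0[1]) / 2)

    @given(
        arrays(
            np.float64,
            st.tuples(st.integers(3, 12), st.integers(2, 5)),
            elements=st.floats(-50, 50, allow_nan=False),
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_column_multisets_equal(self, X):
        # exact multiset equality is the defining property on tie-free
        # columns (ties are averaged Bolstad-style and tested separately);
        # a deterministic jitter removes coincidental ties
        X = X + np.linspace(0, 1e-6, X.size).reshape(X.shape)
        for j in range(X.shape[1]):
            assume(len(np.unique(X[:, j])) == X.shape[0])
        ds = quantile_normalize(raw(X))
        cols = [np.sort(ds.values[:, j]) for j in range(ds.n_conditions)]
        for c in cols[1:]:
            np.testing.assert_allclose(c, cols[0], atol=1e-9)


class TestSummarizeReplicates:
    def test_median_robust_to_outlier(self):
        ds = ExpressionDataset(
            "D", ["g1"], [[1.0, 3.0, 100.0]], ["s1", "s2", "s3"],
            state=PreprocessingState.NORMALIZED,
        )
        out = summarize_replicates(
            ds, ReplicateMap({"s1": "c1", "s2": "c1", "s3": "c1"})
        )
        np.testing.assert_array_equal(out.values, [[3.0]])

    def test_singleton_groups_identity(self):
        ds = ExpressionDataset(
            "D", ["g1"], [[1.0, 2.0]], ["s1", "s2"],
            state=PreprocessingState.NORMALIZED,
        )
        out = summarize_replicates(ds, ReplicateMap({"s1": "c1", "s2": "c2"}))
        np.testing.assert_array_equal(out.values, ds.values)

    def test_even_group_midpoint(self):
        ds = ExpressionDataset(
            "D", ["g1"], [[1.0, 2.0]], ["s1", "s2"],
            state=PreprocessingState.NORMALIZED,
        )
        out = summarize_replicates(ds, ReplicateMap({"s1": "c1", "s2": "c1"}))
        np.testing.assert_array_equal(out.values, [[1.5]])


class TestStandardize:
    def test_hand_example(self):
        ds = ExpressionDataset(
            "D", ["g1"], [[1.0, 2.0, 3.0]], ["c1", "c2", "c3"],
            state=PreprocessingState.SUMMARIZED,
        )
        out = standardize_genes(ds)
        np.testing.assert_allclose(
            out.values, [[-1.224744871, 0.0, 1.224744871]], atol=1e-8
        )

    def test_constant_row_flagged(self):
        ds = ExpressionDataset(
            "D", ["g1", "g2"], [[5.0, 5.0, 5.0], [1, 2, 3]],
            ["c1", "c2", "c3"], state=PreprocessingState.SUMMARIZED,
        )
        out = standardize_genes(ds)
        np.testing.assert_array_equal(out.values[0], [0, 0, 0])
        assert out.flagged_genes == ["g1"]

    @given(
        arrays(
            np.float64,
            st.tuples(st.integers(2, 8), st.integers(3, 6)),
            elements=st.floats(-10, 10, allow_nan=False),
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_rows_zero_mean_unit_sd_or_flagged(self, X):
        ds = ExpressionDataset(
            "D",
            [f"g{i}" for i in range(X.shape[0])],
            X,
            [f"c{j}" for j in range(X.shape[1])],
            state=PreprocessingState.SUMMARIZED,
        )
        out = standardize_genes(ds)
        flagged = set(out.flagged_genes)
        for g, row in zip(out.gene_ids, out.values):
            if g in flagged:
                np.testing.assert_array_equal(row, 0.0)
            else:
                assert abs(row.mean()) < 1e-9
                assert abs(row.std() - 1) < 1e-9

    def test_idempotent_after_restate(self):
        rng = np.random.default_rng(0)
        ds = ExpressionDataset(
            "D", ["g1", "g2"], rng.normal(size=(2, 5)), [f"c{j}" for j in range(5)],
            state=PreprocessingState.SUMMARIZED,
        )
        once = standardize_genes(ds)
        again = standardize_genes(
            ExpressionDataset(
                "D", once.gene_ids, once.values, once.condition_labels,
                state=PreprocessingState.SUMMARIZED,
            )
        )
        np.testing.assert_allclose(again.values, once.values, atol=1e-12)


class TestStateMachine:
    def test_out_of_order_raises(self):
        ds = raw([[1, 2], [3, 4]])
        with pytest.raises(StateError):
            standardize_genes(ds)
        with pytest.raises(StateError):
            summarize_replicates(ds, None)
        normalized = quantile_normalize(ds)
        with pytest.raises(StateError):
            quantile_normalize(normalized)


class TestMembershipTable:
    def test_unassigned_marker_and_round_trip(self, tmp_path):
        parts = [
            BinarizedPartition(
                membership=np.array([[1, 1], [0, 0]]), technique="DTB", delta=0.0
            ),
            BinarizedPartition(
                membership=np.array([[1, 0], [0, 0]]), technique="DTB", delta=0.4
            ),
        ]
        path = tmp_path / "members.tsv"
        dataio.write_membership_table(parts, ["gA", "gB"], path)
        back = dataio.read_membership_table(path)
        assert back.loc["gA"].tolist() == ["C1", "C1"]
        assert back.loc["gB"].tolist() == ["C1", "-"]

    def test_empty_partition_all_unassigned(self, tmp_path):
        part = BinarizedPartition(
            membership=np.zeros((2, 3), dtype=int), technique="DTB", delta=1.0
        )
        path = tmp_path / "members.tsv"
        dataio.write_membership_table([part], ["a", "b", "c"], path)
        back = dataio.read_membership_table(path)
        assert (back["delta=1"] == "-").all()
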