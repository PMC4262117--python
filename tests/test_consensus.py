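import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bicopam.base_clustering import HardPartition, labels_to_membership
from bicopam.consensus import (
    CoPaM,
    build_final_copam,
    build_intermediate_copam,
    min_min_permutation,
    push_memberships,
    read_copam,
    relabel_min_min,
    write_copam,
)
from tests.conftest import random_copam


def hard(labels, k, tag="kmeans_ka", ds="D1"):
    return HardPartition(
        membership=labels_to_membership(np.array(labels), k),
        method_tag=tag,
        dataset_id=ds,
    )


class TestRelabel:
    def test_inverts_row_permutation(self, rng):
        ref = hard([0, 1, 2, 0, 1, 2, 2], 3)
        perm = [2, 0, 1]
        target = HardPartition(
            membership=ref.membership[perm, :],
            method_tag="hc_ward",
            dataset_id="D1",
        )
        out = relabel_min_min(ref, target)
        np.testing.assert_array_equal(out.membership, ref.membership)

    def test_idempotent(self, rng):
        ref_u = rng.dirichlet(np.ones(3), size=8).T
        ref = CoPaM(membership=ref_u, level="intermediate")
        target = hard(rng.integers(0, 3, 8).tolist(), 3)
        once = relabel_min_min(ref, target)
        twice = relabel_min_min(ref, once)
        np.testing.assert_array_equal(once.membership, twice.membership)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="shape"):
            min_min_permutation(np.ones((2, 4)), np.ones((3, 4)))

    def test_greedy_vs_exhaustive_logs_disagreements(self, rng):
        """Greedy min-min compared to the K!-optimal matching (K<=6).

        Greedy is not guaranteed optimal; disagreements are tolerated but
        counted, and the greedy total can never beat the optimum.
        """
        disagreements = 0
        for _ in range(60):
            K = int(rng.integers(2, 7))
            ref = rng.dirichlet(np.ones(K), size=10).T
            tgt = labels_to_membership(rng.integers(0, K, 10), K).astype(float)
            perm = min_min_permutation(ref, tgt, method="greedy")
            greedy_cost = sum(
                np.linalg.norm(ref[i] - tgt[perm[i]]) for i in range(K)
            )
            best = min(
                sum(np.linalg.norm(ref[i] - tgt[p[i]]) for i in range(K))
                for p in itertools.permutations(range(K))
            )
            assert greedy_cost >= best - 1e-12
            if greedy_cost > best + 1e-9:
                disagreements += 1
        # greedy should agree with the optimum most of the time
        assert disagreements < 30

    def test_optimal_mode_matches_hungarian_cost(self, rng):
        K = 5
        ref = rng.dirichlet(np.ones(K), size=12).T
        tgt = labels_to_membership(rng.integers(0, K, 12), K).astype(float)
        perm = min_min_permutation(ref, tgt, method="optimal")
        cost = sum(np.linalg.norm(ref[i] - tgt[perm[i]]) ** 2 for i in range(K))
        best = min(
            sum(np.linalg.norm(ref[i] - tgt[p[i]]) ** 2 for i in range(K))
            for p in itertools.permutations(range(K))
        )
        assert cost == pytest.approx(best)


class TestIntermediateCoPaM:
    def test_unanimity(self):
        parts = [hard([0, 1, 1, 0], 2, tag=t) for t in ("a", "b", "c")]
        copam = build_intermediate_copam(parts)
        np.testing.assert_array_equal(
            copam.membership, parts[0].membership.astype(float)
        )
        assert copam.level == "intermediate"

    def test_two_vote_average(self):
        p1 = hard([0, 0], 3)
        p2 = hard([0, 1], 3, tag="hc_ward")
        copam = build_intermediate_copam([p1, p2])
        np.testing.assert_array_equal(copam.membership[:, 0], [1, 0, 0])
        # the disagreeing gene splits 0.5/0.5 between the agreed cluster and
        # one other row (which empty row hosts it is a relabeling tie)
        col = copam.membership[:, 1]
        assert col[0] == pytest.approx(0.5)
        np.testing.assert_allclose(sorted(col), [0.0, 0.5, 0.5])

    def test_empty_list_error(self):
        with pytest.raises(ValueError):
            build_intermediate_copam([])

    def test_column_sums_one(self, rng):
        parts = [hard(rng.integers(0, 4, 20).tolist(), 4, tag=str(i)) for i in range(5)]
        copam = build_intermediate_copam(parts)
        np.testing.assert_allclose(copam.membership.sum(axis=0), 1.0, atol=1e-12)


class TestPushMemberships:
    def test_symmetric_column_unchanged(self):
        U = np.array([[0.5, 1.0], [0.5, 0.0], [0.0, 0.0], [0.0, 0.0]])
        copam = CoPaM(membership=U, level="intermediate")
        out = push_memberships(copam)
        np.testing.assert_allclose(out.membership, U)

    def test_hand_example_sub_mean_zeroed(self):
        U = np.array([[0.7], [0.2], [0.1], [0.0]])
        out = push_memberships(CoPaM(membership=U, level="intermediate"))
        np.testing.assert_allclose(out.membership, [[1], [0], [0], [0]])

    def test_binary_fixed_point(self):
        U = np.zeros((4, 3))
        U[0, :] = 1.0
        out = push_memberships(CoPaM(membership=U, level="intermediate"))
        np.testing.assert_array_equal(out.membership, U)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_never_gains_support_and_stays_stochastic(self, seed):
        rng = np.random.default_rng(seed)
        copam = random_copam(rng, n_clusters=6, n_genes=15, level="intermediate")
        out = push_memberships(copam)
        before = (copam.membership > 0).sum(axis=0)
        after = (out.membership > 0).sum(axis=0)
        assert (after <= before).all()
        np.testing.assert_allclose(out.membership.sum(axis=0), 1.0, atol=1e-9)

    def test_requires_intermediate(self, rng):
        copam = random_copam(rng, level="final")
        with pytest.raises(ValueError):
            push_memberships(copam)


class TestFinalCoPaM:
    def test_unanimity_over_forty_copies(self):
        part = hard([0, 1, 2, 1, 0], 3)
        inter = build_intermediate_copam([part])
        final = build_final_copam([inter] * 40)
        np.testing.assert_allclose(
            final.membership, part.membership.astype(float)
        )
        assert final.level == "final"

    def test_disagreeing_gene_averaged(self):
        a = build_intermediate_copam([hard([0, 0], 2)])
        b = build_intermediate_copam([hard([0, 1], 2, tag="x")])
        final = build_final_copam([a, b])
        np.testing.assert_allclose(final.membership[:, 1], [0.5, 0.5])

    def test_column_sums(self, rng):
        inters = [
            push_memberships(
                build_intermediate_copam(
                    [hard(rng.integers(0, 4, 25).tolist(), 4, ds=f"D{i}")]
                )
            )
            for i in range(6)
        ]
        final = build_final_copam(inters)
        np.testing.assert_allclose(final.membership.sum(axis=0), 1.0, atol=1e-9)

    def test_unanimous_inputs_order_invariant(self, rng):
        part = hard(rng.integers(0, 3, 15).tolist(), 3)
        inters = [build_intermediate_copam([part]) for _ in range(5)]
        f1 = build_final_copam(inters)
        f2 = build_final_copam(inters[::-1])
        np.testing.assert_allclose(f1.membership, f2.membership)


def test_copam_serialization_round_trip(tmp_path, rng):
    copam = random_copam(rng, n_clusters=5, n_genes=12)
    write_copam(copam, tmp_path / "c.tsv")
    back = read_copam(tmp_path / "c.tsv")
    np.testing.assert_allclose(back.membership, copam.membership, atol=1e-11)
    assert back.level == copam.level
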