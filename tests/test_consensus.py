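import itertools

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from demandclust import (
    LabelMatrix,
    PruneConfig,
    build_consensus,
    cosine_similarity,
    one_hot_encode,
    partition_similarity,
    reassign_small_groups,
    run_battery,
)
from demandclust.consensus import (
    LEVEL_HIGH,
    LEVEL_LOW,
    LEVEL_MIDDLE,
    DegeneratePartitionError,
    SimilarityPartition,
)
from demandclust.features import FeatureMatrix, _standardize

import pandas as pd


def blob_feature_matrix(centers, per_blob, noise, seed=0, n_dim=2):
    """A FeatureMatrix with one group of well-separated Gaussian blobs."""
    rng = np.random.default_rng(seed)
    rows, ids, truth = [], [], []
    for b, c in enumerate(centers):
        for j in range(per_blob):
            rows.append(c + noise * rng.standard_normal(n_dim))
            ids.append(f"b{b}-{j}")
            truth.append(b)
    df = pd.DataFrame(np.array(rows), index=ids)
    return (
        FeatureMatrix(series_ids=tuple(ids), raw={"g": df}, standardized={"g": _standardize(df)}),
        truth,
    )


def manual_partition(ids, high_pairs, low_pairs=()):
    """A SimilarityPartition with hand-chosen levels (middle elsewhere)."""
    n = len(ids)
    idx = {s: i for i, s in enumerate(ids)}
    level = np.full((n, n), LEVEL_MIDDLE, dtype=np.int64)
    sim = np.full((n, n), 0.5)
    for a, b in high_pairs:
        i, j = idx[a], idx[b]
        level[i, j] = level[j, i] = LEVEL_HIGH
        sim[i, j] = sim[j, i] = 0.9
    for a, b in low_pairs:
        i, j = idx[a], idx[b]
        level[i, j] = level[j, i] = LEVEL_LOW
        sim[i, j] = sim[j, i] = 0.1
    np.fill_diagonal(level, LEVEL_HIGH)
    np.fill_diagonal(sim, 1.0)
    return SimilarityPartition(
        series_ids=tuple(ids), similarity=sim, level=level, centroids=(0.1, 0.5, 0.9)
    )


class TestBattery:
    def test_run_count_is_groups_times_linkages(self):
        fm, _ = blob_feature_matrix([np.zeros(2), np.ones(2) * 10], 3, 0.1)
        fm6 = FeatureMatrix(
            series_ids=fm.series_ids,
            raw={f"g{i}": fm.raw["g"] for i in range(6)},
            standardized={f"g{i}": fm.standardized["g"] for i in range(6)},
        )
        lm = run_battery(fm6, k=2)
        assert lm.n_runs == 24
        assert len(lm.runs) == len(set(lm.runs))

    def test_identical_series_get_identical_label_rows(self):
        fm, _ = blob_feature_matrix([np.zeros(2), np.ones(2) * 10], 3, 0.0)
        lm = run_battery(fm, k=2)
        # first three rows are copies of the same point
        assert (lm.labels[0] == lm.labels[1]).all()
        assert (lm.labels[0] == lm.labels[2]).all()

    def test_separated_blobs_recovered_by_every_run(self):
        centers = [np.zeros(2), 10 * np.ones(2), 20 * np.ones(2), 30 * np.ones(2)]
        fm, truth = blob_feature_matrix(centers, 5, noise=0.2, seed=1)
        lm = run_battery(fm, k=4)
        for r in range(lm.n_runs):
            assert adjusted_rand_score(truth, lm.labels[:, r]) == 1.0

    def test_fewer_series_than_k_rejected(self):
        fm, _ = blob_feature_matrix([np.zeros(2)], 3, 0.1)
        with pytest.raises(ValueError):
            run_battery(fm, k=4)


class TestOneHotAndCosine:
    def test_single_run_label_three(self):
        lm = LabelMatrix(series_ids=("a",), runs=(("g", "ward"),), labels=[[3]], k=4)
        assert one_hot_encode(lm).tolist() == [[0.0, 0.0, 1.0, 0.0]]

    def test_row_sums_equal_run_count(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(1, 5, size=(6, 24))
        lm = LabelMatrix(
            series_ids=tuple(f"s{i}" for i in range(6)),
            runs=tuple(("g", str(r)) for r in range(24)),
            labels=labels,
        )
        v = one_hot_encode(lm)
        assert (v.sum(axis=1) == 24).all()
        np.testing.assert_allclose(np.linalg.norm(v, axis=1), np.sqrt(24))

    def test_cosine_equals_agreement_fraction(self):
        labels = np.array([[1, 2, 3], [1, 2, 4], [4, 1, 1]])
        lm = LabelMatrix(
            series_ids=("a", "b", "c"),
            runs=(("g", "1"), ("g", "2"), ("g", "3")),
            labels=labels,
        )
        sim = cosine_similarity(one_hot_encode(lm))
        assert sim[0, 1] == pytest.approx(2 / 3)
        assert sim[0, 2] == pytest.approx(0.0)
        assert sim[0, 0] == 1.0

    def test_agreement_in_18_of_24_runs_gives_075(self):
        labels = np.ones((2, 24), dtype=int)
        labels[1, :6] = 2
        lm = LabelMatrix(
            series_ids=("a", "b"),
            runs=tuple(("g", str(r)) for r in range(24)),
            labels=labels,
        )
        sim = cosine_similarity(one_hot_encode(lm))
        assert sim[0, 1] == pytest.approx(0.75)

    def test_consensus_invariant_to_label_permutation_within_runs(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(1, 5, size=(8, 10))
        ids = tuple(f"s{i}" for i in range(8))
        runs = tuple(("g", str(r)) for r in range(10))
        sim1 = cosine_similarity(one_hot_encode(LabelMatrix(ids, runs, labels)))
        permuted = labels.copy()
        for r in range(10):
            perm = rng.permutation(4) + 1
            permuted[:, r] = perm[labels[:, r] - 1]
        sim2 = cosine_similarity(one_hot_encode(LabelMatrix(ids, runs, permuted)))
        np.testing.assert_allclose(sim1, sim2)


def sim_from_values(vals):
    """Symmetric 4x4 similarity matrix whose 6 off-diagonal values are vals."""
    n = 4
    sim = np.eye(n)
    iu = np.triu_indices(n, 1)
    sim[iu] = vals
    sim[(iu[1], iu[0])] = vals
    return sim


class TestPartitionSimilarity:
    def test_three_well_separated_bands(self):
        vals = [0.10, 0.15, 0.50, 0.55, 0.90, 0.95]
        sp = partition_similarity(sim_from_values(vals), list("abcd"))
        assert sp.centroids == pytest.approx((0.125, 0.525, 0.925))
        iu = np.triu_indices(4, 1)
        got = {
            round(v, 2): lev for v, lev in zip(vals, sp.level[iu])
        }
        assert got[0.9] == LEVEL_HIGH and got[0.95] == LEVEL_HIGH
        assert got[0.1] == LEVEL_LOW and got[0.15] == LEVEL_LOW
        assert got[0.5] == LEVEL_MIDDLE and got[0.55] == LEVEL_MIDDLE

    def test_all_equal_values_degenerate(self):
        with pytest.raises(DegeneratePartitionError):
            partition_similarity(sim_from_values([0.5] * 6), list("abcd"))

    def test_shift_invariance_of_level_assignment(self):
        vals = np.array([0.10, 0.15, 0.50, 0.55, 0.90, 0.95])
        sp1 = partition_similarity(sim_from_values(vals), list("abcd"))
        sp2 = partition_similarity(sim_from_values(vals + 0.04), list("abcd"))
        np.testing.assert_array_equal(sp1.level, sp2.level)

    def test_matches_exhaustive_oracle_on_random_sets(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(4, 10))
            vals = np.round(rng.random(n * (n - 1) // 2), 3)
            if np.unique(vals).size < 3:
                continue
            sim = np.eye(n)
            iu = np.triu_indices(n, 1)
            sim[iu] = vals
            sim[(iu[1], iu[0])] = vals
            sp = partition_similarity(sim, [f"s{i}" for i in range(n)])
            x = np.sort(vals)
            best = min(
                (
                    np.var(x[:i]) * i + np.var(x[i:j]) * (j - i) + np.var(x[j:]) * (len(x) - j)
                    for i, j in itertools.combinations(range(1, len(x)), 2)
                )
            )
            got = sum(
                ((v - sp.centroids[lev]) ** 2)
                for v, lev in zip(vals, sp.level[iu])
            )
            assert got == pytest.approx(best, abs=1e-9)


class TestBuildConsensus:
    def test_two_cliques_no_cross_edges(self):
        ids = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
        high = [(u, v) for u, v in itertools.combinations(ids[:3], 2)]
        high += [(u, v) for u, v in itertools.combinations(ids[3:], 2)]
        cr = build_consensus(manual_partition(ids, high))
        assert cr.fine_groups == (("a0", "a1", "a2"), ("b0", "b1", "b2"))

    def test_fully_connected_graph_is_one_group(self):
        ids = list("abcd")
        high = list(itertools.combinations(ids, 2))
        cr = build_consensus(manual_partition(ids, high))
        assert len(cr.fine_groups) == 1

    def test_sparse_bridge_through_one_node_is_pruned(self):
        # two dense cliques joined only through v's two cross-edges:
        # pruning should cut them and keep v on its denser side
        A = ["a0", "a1", "a2", "a3", "v"]
        B = ["b0", "b1", "b2", "b3"]
        high = list(itertools.combinations(A, 2)) + list(itertools.combinations(B, 2))
        high += [("v", "b0"), ("v", "b1")]
        sp = manual_partition(A + B, high)

        unpruned = build_consensus(sp, PruneConfig(enabled=False))
        assert len(unpruned.fine_groups) == 1  # bridge connects everything

        cr = build_consensus(sp, PruneConfig())
        assert set(cr.pruned_edges) == {("b0", "v"), ("b1", "v")}
        assert cr.fine_groups == (
            ("a0", "a1", "a2", "a3", "v"),
            ("b0", "b1", "b2", "b3"),
        )
        # brute-force component check after removing the pruned edges
        G = nx.Graph(high)
        G.remove_edges_from(cr.pruned_edges)
        assert len(list(nx.connected_components(G))) == 2

    def test_dense_cross_connection_is_not_pruned(self):
        A = ["a0", "a1", "a2"]
        B = ["b0", "b1", "b2"]
        high = list(itertools.combinations(A, 2)) + list(itertools.combinations(B, 2))
        high += [(a, b) for a in A for b in B]  # many independent cross edges
        cr = build_consensus(manual_partition(A + B, high))
        assert len(cr.fine_groups) == 1
        assert not cr.pruned_edges


class TestReassignSmallGroups:
    def _partition(self, low_pairs):
        A = [f"a{i}" for i in range(4)]
        B = [f"b{i}" for i in range(4)]
        S = ["s0", "s1"]
        high = (
            list(itertools.combinations(A, 2))
            + list(itertools.combinations(B, 2))
            + [("s0", "s1")]
        )
        return manual_partition(A + B + S, high, low_pairs), A, B, S

    def test_merged_towards_fewer_low_links(self):
        # 3 low links to the A side, 1 to the B side -> merged into B
        sp, A, B, S = self._partition(
            [("s0", "a0"), ("s0", "a1"), ("s1", "a2"), ("s1", "b0")]
        )
        cr = reassign_small_groups(build_consensus(sp), sp, max_small=2)
        assert cr.reassignments == ((("s0", "s1"), tuple(B)),)
        assert tuple(sorted(B + S)) in cr.pattern_groups
        assert cr.fine_groups != cr.pattern_groups  # fine structure retained

    def test_no_small_groups_unchanged(self):
        sp, A, B, S = self._partition([])
        cr0 = build_consensus(sp)
        cr = reassign_small_groups(cr0, sp, max_small=1)  # S has size 2 > 1
        assert cr.pattern_groups == cr0.pattern_groups

    def test_equal_low_counts_flagged_unresolved(self):
        sp, A, B, S = self._partition([("s0", "a0"), ("s0", "b0")])
        cr = reassign_small_groups(build_consensus(sp), sp, max_small=2)
        assert cr.unresolved == (("s0", "s1"),)
        assert tuple(S) in cr.pattern_groups  # left standing


class TestDeterminism:
    def test_same_inputs_same_groups(self):
        centers = [np.zeros(3), 4 * np.ones(3), np.array([4.0, 0, 4]), np.array([0.0, 4, 0])]
        fm, _ = blob_feature_matrix(centers, 4, 2.0, seed=7, n_dim=3)
        results = []
        for _ in range(2):
            lm = run_battery(fm, k=4)
            sim = cosine_similarity(one_hot_encode(lm))
            sp = partition_similarity(sim, lm.series_ids)
            cr = reassign_small_groups(build_consensus(sp), sp)
            results.append(cr.pattern_groups)
        assert results[0] == results[1]
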