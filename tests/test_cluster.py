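import itertools

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from gbdphylo import cluster
from gbdphylo.cluster import (
    ClusterParams,
    blocks,
    mri,
    optimize_threshold,
    rank_pipeline,
    threshold_cluster,
)
from gbdphylo.errors import UsageError, ValidationError
from gbdphylo.gbdp import DistanceMatrix

import pandas as pd


def dm(labels, rows):
    return DistanceMatrix(list(labels), np.array(rows, dtype=float))


def random_matrix(rng, n):
    m = rng.uniform(0, 1, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix([f"g{i:02d}" for i in range(n)], m)


def pair_count_ari(p1, p2):
    """Independent ARI oracle from pair-concordance counts.

    a: pairs together in both; b: separated in both; c/d: mixed.
    ARI = 2(ab - cd) / ((a+d)(d+b) + (a+c)(c+b)); the degenerate case
    (no disagreeing pairs) is 1.0.
    """
    items = sorted(p1)
    a = b = c = d = 0
    for x, y in itertools.combinations(items, 2):
        s1 = p1[x] == p1[y]
        s2 = p2[x] == p2[y]
        if s1 and s2:
            a += 1
        elif not s1 and not s2:
            b += 1
        elif s1 and not s2:
            c += 1
        else:
            d += 1
    denom = (a + d) * (d + b) + (a + c) * (c + b)
    if denom == 0:
        return 1.0
    return 2.0 * (a * b - c * d) / denom


def connected_component_partition(matrix, T):
    adj = (matrix.values <= T).astype(int)
    np.fill_diagonal(adj, 0)
    _, comp = connected_components(csr_matrix(adj), directed=False)
    out = {}
    for cid in set(comp):
        members = [matrix.labels[i] for i in np.flatnonzero(comp == cid)]
        lab = min(members)
        for m in members:
            out[m] = lab
    return out


class TestThresholdCluster:
    def test_chain_splits_under_fraction_rule(self):
        # A-B and B-C linked, A-C not: with F=1 the chain cannot fully merge
        m = dm("ABC", [[0, 0.1, 0.6], [0.1, 0, 0.1], [0.6, 0.1, 0]])
        p_half = threshold_cluster(m, T=0.2, F=0.5)
        assert blocks(p_half) == [frozenset("ABC")]
        p_clique = threshold_cluster(m, T=0.2, F=1.0)
        assert sorted(len(b) for b in blocks(p_clique)) == [1, 2]

    def test_all_linked_single_cluster(self):
        m = dm("ABCD", np.full((4, 4), 0.1) - 0.1 * np.eye(4))
        p = threshold_cluster(m, T=0.2, F=1.0)
        assert blocks(p) == [frozenset("ABCD")]
        assert set(p.values()) == {"A"}

    def test_none_linked_all_singletons(self):
        m = dm("ABCD", np.full((4, 4), 0.9) - 0.9 * np.eye(4))
        p = threshold_cluster(m, T=0.2, F=0.5)
        assert p == {x: x for x in "ABCD"}

    @pytest.mark.parametrize("seed", range(6))
    def test_f_zero_equals_connected_components(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, int(rng.integers(4, 12)))
        T = float(rng.uniform(0.1, 0.9))
        assert threshold_cluster(m, T, F=0.0) == connected_component_partition(m, T)

    @pytest.mark.parametrize("seed", range(6))
    def test_f_one_yields_cliques(self, seed):
        rng = np.random.default_rng(100 + seed)
        m = random_matrix(rng, 10)
        T = float(rng.uniform(0.2, 0.8))
        p = threshold_cluster(m, T, F=1.0)
        idx = {lab: i for i, lab in enumerate(m.labels)}
        for block in blocks(p):
            for x, y in itertools.combinations(sorted(block), 2):
                assert m.values[idx[x], idx[y]] <= T

    @pytest.mark.parametrize("seed", range(4))
    def test_largest_cluster_monotone_in_threshold_at_f_zero(self, seed):
        rng = np.random.default_rng(200 + seed)
        m = random_matrix(rng, 9)
        sizes = [
            max(len(b) for b in blocks(threshold_cluster(m, T, F=0.0)))
            for T in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert sizes == sorted(sizes)

    def test_params_validation(self):
        with pytest.raises(ValidationError):
            ClusterParams(T=0.5, F=1.5)
        with pytest.raises(ValidationError):
            ClusterParams(T=-0.1, F=0.5)


class TestMri:
    def test_identical_partitions_equal_one(self):
        p = {"a": 1, "b": 1, "c": 2}
        assert mri(p, dict(p)) == 1.0

    def test_label_names_irrelevant(self):
        p1 = {"a": "x", "b": "x", "c": "y"}
        p2 = {"a": 7, "b": 7, "c": 9}
        assert mri(p1, p2) == 1.0

    def test_worse_than_chance_is_negative(self):
        p1 = {"a": 1, "b": 1, "c": 2, "d": 2}
        p2 = {"a": 1, "b": 2, "c": 1, "d": 2}
        assert mri(p1, p2) == pytest.approx(-0.5)

    def test_different_element_sets_rejected(self):
        with pytest.raises(UsageError):
            mri({"a": 1}, {"b": 1})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_count_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        items = [f"e{i}" for i in range(12)]
        p1 = {x: int(rng.integers(0, 4)) for x in items}
        p2 = {x: int(rng.integers(0, 4)) for x in items}
        assert mri(p1, p2) == pytest.approx(pair_count_ari(p1, p2), abs=1e-12)

    def test_matches_pair_count_oracle_exhaustively(self):
        # all set partitions of 4 elements (Bell(4) = 15), all pairs
        items = ["a", "b", "c", "d"]

        def all_partitions(elems):
            if not elems:
                yield []
                return
            head, rest = elems[0], elems[1:]
            for part in all_partitions(rest):
                for i in range(len(part)):
                    yield part[:i] + [part[i] | {head}] + part[i + 1 :]
                yield part + [{head}]

        parts = [
            {x: i for i, block in enumerate(p) for x in block}
            for p in all_partitions(items)
        ]
        assert len(parts) == 15
        for p1, p2 in itertools.product(parts, repeat=2):
            assert mri(p1, p2) == pytest.approx(pair_count_ari(p1, p2), abs=1e-12)


class TestOptimizeThreshold:
    def test_perfect_separation_recovers_reference(self):
        m = dm(
            "ABCD",
            [
                [0, 0.05, 0.8, 0.8],
                [0.05, 0, 0.8, 0.8],
                [0.8, 0.8, 0, 0.05],
                [0.8, 0.8, 0.05, 0],
            ],
        )
        ref = {"A": "s1", "B": "s1", "C": "s2", "D": "s2"}
        T, score, part = optimize_threshold(m, ref)
        assert score == 1.0
        assert 0.05 <= T < 0.8
        assert blocks(part) == blocks(ref)

    def test_all_singleton_reference_pushes_t_below_min(self):
        m = dm("ABC", [[0, 0.3, 0.5], [0.3, 0, 0.4], [0.5, 0.4, 0]])
        ref = {"A": 1, "B": 2, "C": 3}
        T, score, part = optimize_threshold(m, ref)
        assert score == 1.0
        assert T < 0.3
        assert len(blocks(part)) == 3

    @pytest.mark.parametrize("seed", range(4))
    def test_result_is_argmax_over_candidates(self, seed):
        rng = np.random.default_rng(300 + seed)
        m = random_matrix(rng, 8)
        ref = {lab: int(rng.integers(0, 3)) for lab in m.labels}
        T, score, _ = optimize_threshold(m, ref, F=0.5)
        for cand in cluster.candidate_thresholds(m):
            other = mri(threshold_cluster(m, cand, 0.5), ref)
            assert other <= score + 1e-12

    def test_missing_reference_labels_rejected(self):
        m = dm("AB", [[0, 0.2], [0.2, 0]])
        with pytest.raises(UsageError):
            optimize_threshold(m, {"A": 1})


class TestRankPipeline:
    @staticmethod
    def taxonomy(rows):
        return pd.DataFrame(
            [
                dict(
                    genome_id=g, species=sp, genus="", subfamily="", family=""
                )
                for g, sp in rows
            ]
        )

    def test_unassigned_genomes_dropped(self):
        m = dm(
            "ABC", [[0, 0.05, 0.9], [0.05, 0, 0.9], [0.9, 0.9, 0]]
        )
        tax = self.taxonomy([("A", "s1"), ("B", "s1"), ("C", "")])
        T, score, part = rank_pipeline(m, tax, "species")
        assert set(part) == {"A", "B"}
        assert score == 1.0

    def test_fixed_threshold_mode(self):
        m = dm(
            "ABCD",
            [
                [0, 0.05, 0.8, 0.8],
                [0.05, 0, 0.8, 0.8],
                [0.8, 0.8, 0, 0.05],
                [0.8, 0.8, 0.05, 0],
            ],
        )
        tax = self.taxonomy(
            [("A", "s1"), ("B", "s1"), ("C", "s2"), ("D", "s2")]
        )
        T, score, part = rank_pipeline(m, tax, "species", T=0.1)
        assert T == 0.1
        assert score == 1.0
        T2, score2, part2 = rank_pipeline(m, tax, "species", T=0.9)
        assert score2 < 1.0
        assert blocks(part2) == [frozenset("ABCD")]

    def test_unknown_rank_rejected(self):
        m = dm("AB", [[0, 0.2], [0.2, 0]])
        with pytest.raises(UsageError):
            rank_pipeline(m, self.taxonomy([("A", "s"), ("B", "s")]), "order")

    def test_no_assignments_rejected(self):
        m = dm("AB", [[0, 0.2], [0.2, 0]])
        with pytest.raises(UsageError):
            rank_pipeline(m, self.taxonomy([("A", ""), ("B", "")]), "species")


class TestClusterTreeConsistency:
    def test_species_clusters_are_tree_monophyletic(
        self, separated_matrix, separated_dataset
    ):
        from gbdphylo.phylo import MONOPHYLETIC, classify_taxon, nj_tree

        matrix = separated_matrix
        _, _, taxonomy, _ = separated_dataset
        T, score, part = rank_pipeline(matrix, taxonomy, "species")
        assert score == 1.0
        tree = nj_tree(matrix)
        for block in blocks(part):
            if len(block) > 1:
                assert classify_taxon(tree, set(block)) == MONOPHYLETIC
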