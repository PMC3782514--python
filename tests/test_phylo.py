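"""Neighbor joining, bootstrap, and matrix I/O."""

from __future__ import annotations

import numpy as np
import pytest
import skbio

from syntevol.phylo import (
    DistanceMatrix,
    bootstrap_support,
    nj_tree,
    parse_newick,
    read_phylip_matrix,
    write_phylip_matrix,
)
from syntevol.simulate import decode, mutate_k2p


def _branch_lengths(tree) -> dict[str, float]:
    return {
        t.name: t.branch_length for t in tree.tree.get_terminals()
    }


def _random_additive_matrix(n_taxa: int, rng: np.random.Generator):
    """Distances from a random binary tree with positive branch lengths.

    Returns (taxa, matrix, true_bipartitions)."""
    import itertools

    taxa = [f"t{i}" for i in range(n_taxa)]
    # build a random topology by sequential leaf attachment; store the tree
    # as an adjacency map with branch lengths, then distances via paths
    next_id = [0]

    def new_node():
        next_id[0] += 1
        return f"internal{next_id[0]}"

    edges: dict[str, dict[str, float]] = {t: {} for t in taxa[:3]}
    center = new_node()
    edges[center] = {}
    for t in taxa[:3]:
        w = float(rng.uniform(0.5, 2.0))
        edges[center][t] = w
        edges[t][center] = w
    for t in taxa[3:]:
        # pick a random existing edge and subdivide it
        pairs = [(u, v) for u in edges for v in edges[u] if u < v]
        u, v = pairs[rng.integers(len(pairs))]
        w = edges[u][v]
        mid = new_node()
        split = float(rng.uniform(0.25, 0.75))
        del edges[u][v], edges[v][u]
        edges[mid] = {u: w * split, v: w * (1 - split)}
        edges[u][mid] = w * split
        edges[v][mid] = w * (1 - split)
        leaf_w = float(rng.uniform(0.5, 2.0))
        edges[mid][t] = leaf_w
        edges.setdefault(t, {})[mid] = leaf_w

    def dist(a: str, b: str) -> float:
        # BFS path length
        stack = [(a, 0.0, None)]
        while stack:
            node, d, prev = stack.pop()
            if node == b:
                return d
            for nxt, w in edges[node].items():
                if nxt != prev:
                    stack.append((nxt, d + w, node))
        raise AssertionError("disconnected")

    m = np.zeros((n_taxa, n_taxa))
    for i, j in itertools.combinations(range(n_taxa), 2):
        m[i, j] = m[j, i] = dist(taxa[i], taxa[j])

    # true bipartitions: leaves on each side of every internal edge
    def leaves_from(node: str, banned: str) -> set[str]:
        out = set()
        stack = [(node, banned)]
        while stack:
            cur, prev = stack.pop()
            if not cur.startswith("internal"):
                out.add(cur)
            for nxt in edges[cur]:
                if nxt != prev:
                    stack.append((nxt, cur))
        return out

    first = min(taxa)
    bips = set()
    for u in edges:
        for v in edges[u]:
            if u.startswith("internal") and v.startswith("internal") and u < v:
                side = leaves_from(u, v)
                if first in side:
                    side = set(taxa) - side
                if 1 < len(side) < n_taxa - 1:
                    bips.add(frozenset(side))
    return taxa, m, bips


class TestDistanceMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], np.array([[1, 1], [1, 0]]))
        with pytest.raises(ValueError, match="non-negative"):
            DistanceMatrix(["a", "b"], np.array([[0, -1], [-1, 0]]))
        with pytest.raises(ValueError, match="shape"):
            DistanceMatrix(["a"], np.zeros((2, 2)))

    def test_from_alignments(self):
        dm = DistanceMatrix.from_alignments(
            {"a": "ACGT" * 50, "b": "ACGT" * 50, "c": "ACGG" * 50}
        )
        assert dm.matrix[0, 1] == 0.0
        assert dm.matrix[0, 2] > 0.0


class TestNJ:
    def test_three_taxon_exact(self):
        # d(AB)=2, d(AC)=4, d(BC)=4 -> branches A:1, B:1, C:3
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        )
        tree = nj_tree(dm)
        assert _branch_lengths(tree) == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,C:3,D:4) -> additive distances
        dm = DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array(
                [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
            ),
        )
        tree = nj_tree(dm)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        assert tree.negative_branches_clamped == 0

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
    def test_random_additive_exact_recovery(self, n_taxa, rng):
        taxa, m, true_bips = _random_additive_matrix(n_taxa, rng)
        tree = nj_tree(DistanceMatrix(taxa, m))
        assert tree.bipartitions() == true_bips
        assert tree.negative_branches_clamped == 0

    def test_matches_skbio_distances(self, rng):
        taxa, m, _ = _random_additive_matrix(6, rng)
        ours = nj_tree(DistanceMatrix(taxa, m))
        ref = skbio.tree.nj(skbio.DistanceMatrix(m, ids=taxa))
        # identical topologies: compare bipartition sets
        leaves = set(taxa)
        first = min(leaves)
        ref_bips = set()
        for node in ref.non_tips():
            side = {t.name for t in node.tips()}
            if first in side:
                side = leaves - side
            if 1 < len(side) < len(leaves) - 1:
                ref_bips.add(frozenset(side))
        assert ours.bipartitions() == ref_bips

    def test_zero_matrix_star_flag(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        tree = nj_tree(dm)
        assert "zero_length_star" in tree.flags

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_newick_round_trip(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        )
        tree = nj_tree(dm)
        back = parse_newick(tree.to_newick())
        assert back.leaf_names() == {"A", "B", "C"}


def _diverged_seqs(rng) -> dict[str, str]:
    """Four aligned sequences with a clean ((a,b),(c,d)) signal."""
    root = rng.integers(0, 4, size=4000).astype(np.uint8)
    left = mutate_k2p(root, 0.05, 2.0, rng)
    right = mutate_k2p(root, 0.05, 2.0, rng)
    return {
        "a": decode(mutate_k2p(left, 0.01, 2.0, rng)),
        "b": decode(mutate_k2p(left, 0.01, 2.0, rng)),
        "c": decode(mutate_k2p(right, 0.01, 2.0, rng)),
        "d": decode(mutate_k2p(right, 0.01, 2.0, rng)),
    }


class TestBootstrap:
    def test_clean_signal_full_support(self, rng):
        seqs = _diverged_seqs(rng)
        tree = bootstrap_support(seqs, n_reps=50, seed=0)
        assert tree.supports  # one internal bipartition for 4 taxa
        assert all(v == 100.0 for v in tree.supports.values())

    def test_determinism(self, rng):
        seqs = _diverged_seqs(rng)
        t1 = bootstrap_support(seqs, n_reps=20, seed=7)
        t2 = bootstrap_support(seqs, n_reps=20, seed=7)
        assert t1.supports == t2.supports

    def test_single_replicate_support_binary(self, rng):
        seqs = _diverged_seqs(rng)
        tree = bootstrap_support(seqs, n_reps=1, seed=3)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_unaligned_input_error(self):
        with pytest.raises(ValueError, match="equal length"):
            bootstrap_support({"a": "ACGT", "b": "ACG"})

    def test_n_reps_validation(self, rng):
        with pytest.raises(ValueError):
            bootstrap_support(_diverged_seqs(rng), n_reps=0)


class TestPhylipIO:
    def test_round_trip(self, rng):
        taxa, m, _ = _random_additive_matrix(5, rng)
        dm = DistanceMatrix(taxa, m)
        back = read_phylip_matrix(write_phylip_matrix(dm))
        assert back.taxa == taxa
        assert np.allclose(back.matrix, m, atol=1e-6)
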