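"""Neighbor-joining trees from distance matrices, with column bootstrap.

Implements Saitou & Nei's neighbor joining with deterministic tie-breaking
(the joined pair with the lexicographically smallest label pair wins) and
clamping of negative branch lengths to zero. NJ is exact on additive
matrices, which is the main correctness property the tests exploit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import Phylo
from Bio.Phylo.BaseTree import Clade, Tree

from .molevol import PairwiseAlignment, SaturationError, k2p_distance


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.all(np.isfinite(m)):
            raise ValueError("matrix entries must be finite")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("matrix diagonal must be zero")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        self.matrix = m

    @classmethod
    def from_alignments(cls, seqs: dict[str, str]) -> "DistanceMatrix":
        """K2P distances between equal-length aligned sequences."""
        taxa = list(seqs)
        n = len(taxa)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                aln = PairwiseAlignment(seqs[taxa[i]], seqs[taxa[j]])
                m[i, j] = m[j, i] = k2p_distance(aln).K
        return cls(taxa=taxa, matrix=m)


@dataclass
class PhyloTree:
    tree: Tree
    negative_branches_clamped: int = 0
    supports: dict[frozenset, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_newick(self) -> str:
        buf = io.StringIO()
        Phylo.write(self.tree, buf, "newick")
        return buf.getvalue().strip()

    def leaf_names(self) -> set[str]:
        return {t.name for t in self.tree.get_terminals()}

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each normalised to the side not
        containing the lexicographically first leaf."""
        leaves = self.leaf_names()
        first = min(leaves)
        out = set()
        for clade in self.tree.get_nonterminals():
            side = frozenset(t.name for t in clade.get_terminals())
            if first in side:
                side = frozenset(leaves - side)
            if 1 < len(side) < len(leaves) - 1:
                out.add(side)
        return out


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with lexicographic tie-breaking."""
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d = dm.matrix.copy()
    nodes: list[Clade] = [Clade(name=t) for t in dm.taxa]
    # sort key per node: smallest leaf label in its clade
    keys: list[str] = list(dm.taxa)
    clamped = 0

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        best_q = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12
                    and best is not None
                    and pair_key < best[2]
                ):
                    best_q = q
                    best = (i, j, pair_key)
        i, j, _ = best
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, clamped = 0.0, clamped + 1
        if lj < 0:
            lj, clamped = 0.0, clamped + 1
        ci, cj = nodes[i], nodes[j]
        ci.branch_length = li
        cj.branch_length = lj
        parent = Clade(clades=[ci, cj])
        new_key = min(keys[i], keys[j])
        # updated distances
        dk = np.array(
            [0.5 * (d[i, x] + d[j, x] - dij) for x in range(m) if x not in (i, j)]
        )
        keep = [x for x in range(m) if x not in (i, j)]
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = dk
        d[:-1, -1] = dk
        nodes = [nodes[x] for x in keep] + [parent]
        keys = [keys[x] for x in keep] + [new_key]

    # resolve the final three nodes as an unrooted star (three-point formulas)
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    lengths = []
    for node, length in zip(nodes, (la, lb, lc)):
        if length < 0:
            length, clamped = 0.0, clamped + 1
        node.branch_length = length
        lengths.append(length)
    root = Clade(clades=list(nodes))
    tree = Tree(root=root, rooted=False)
    flags = []
    if all(
        (cl.branch_length or 0.0) == 0.0 for cl in tree.find_clades() if cl is not root
    ):
        flags.append("zero_length_star")
    return PhyloTree(tree=tree, negative_branches_clamped=clamped, flags=flags)


def bootstrap_support(
    seqs: dict[str, str],
    n_reps: int = 100,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree with column-resampling bootstrap supports (percent).

    ``seqs`` maps taxa to equal-length aligned sequences. Each replicate
    resamples alignment columns with replacement, rebuilds the K2P distance
    matrix and NJ tree, and each original bipartition's support is the
    percentage of replicates containing it. Replicates whose resampled
    distances saturate are skipped (and do not count as containing any
    bipartition).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    (length,) = lengths
    base = nj_tree(DistanceMatrix.from_alignments(seqs))
    target = base.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    taxa = list(seqs)
    cols = {t: np.frombuffer(seqs[t].encode(), dtype=np.uint8) for t in taxa}
    for _ in range(n_reps):
        idx = rng.integers(0, length, size=length)
        resampled = {t: bytes(cols[t][idx]).decode() for t in taxa}
        try:
            rep = nj_tree(DistanceMatrix.from_alignments(resampled))
        except (SaturationError, ValueError):
            continue
        rep_bps = rep.bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    # annotate internal clades with their support
    leaves = base.leaf_names()
    first = min(leaves)
    for clade in base.tree.get_nonterminals():
        side = frozenset(t.name for t in clade.get_terminals())
        if first in side:
            side = frozenset(leaves - side)
        if side in supports:
            clade.confidence = supports[side]
    base.supports = supports
    return base


def parse_newick(text: str) -> PhyloTree:
    tree = Phylo.read(io.StringIO(text), "newick")
    return PhyloTree(tree=tree)


def write_phylip_matrix(dm: DistanceMatrix) -> str:
    lines = [f"    {len(dm.taxa)}"]
    for i, t in enumerate(dm.taxa):
        row = "  ".join(f"{x:.6f}" for x in dm.matrix[i])
        lines.append(f"{t:<10s}  {row}")
    return "\n".join(lines) + "\n"


def read_phylip_matrix(text: str) -> DistanceMatrix:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    n = int(lines[0].strip())
    taxa, rows = [], []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        taxa.append(parts[0])
        rows.append([float(x) for x in parts[1 : n + 1]])
    return DistanceMatrix(taxa=taxa, matrix=np.array(rows))
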