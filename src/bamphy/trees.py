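"""Distance-based gene-tree estimation: K2P distances, neighbor joining,
nonparametric bootstrap support, and majority-rule consensus.

Neighbor joining on Kimura two-parameter distances is the built-in
estimator for every tree in the pipeline; any external FASTA-in/newick-out
inference tool can be substituted through ``external_tree``.  Bootstrap
support resamples alignment columns with replacement and counts, for each
internal edge of the point-estimate tree, the fraction of pseudoreplicate
trees containing the same bipartition.  The majority-rule consensus keeps
exactly the bipartitions occurring in strictly more than the threshold
fraction of input trees (mutually compatible for thresholds >= 0.5).
"""

from __future__ import annotations

import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from ._errors import ArgumentError, DataError
from .align import Alignment

#: distances are capped here when the K2P log argument is non-positive
SATURATION_CAP = 10.0

_PURINE = {"A", "G"}
_NUC = "ACGT"

__all__ = [
    "DistanceMatrix", "TreeWithSupport", "SATURATION_CAP",
    "k2p_distance_matrix", "neighbor_joining", "bootstrap_support",
    "majority_consensus", "tree_bipartitions", "external_tree",
]


@dataclass
class DistanceMatrix:
    """Pairwise K2P distances with the underlying transition (P) and
    transversion (Q) proportions."""

    taxa: list[str]
    d: np.ndarray
    P: np.ndarray
    Q: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise DataError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise DataError("distance matrix must be symmetric with zero diagonal")


@dataclass
class TreeWithSupport:
    """An unrooted tree whose internal edges carry bootstrap support in
    [0, 1], from ``n_replicates`` pseudoreplicates."""

    tree: dendropy.Tree
    n_replicates: int
    supports: dict[frozenset, float]


def _encode(rows: Sequence[str]) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int8)
    for i, c in enumerate(_NUC):
        lut[ord(c)] = i
    return lut[np.frombuffer("".join(rows).encode(), dtype=np.uint8)].reshape(
        len(rows), -1
    )


def k2p_distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """Kimura two-parameter distances with pairwise deletion.

    For each pair only columns where both rows hold unambiguous A/C/G/T are
    compared; P and Q are the transition and transversion proportions and
    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)).  Saturated pairs (log argument
    <= 0) are capped at ``SATURATION_CAP`` with a warning.
    """
    n = len(alignment.ids)
    codes = _encode(alignment.rows)
    is_purine = (codes == 0) | (codes == 2)
    valid = codes >= 0
    d = np.zeros((n, n))
    P = np.zeros((n, n))
    Q = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m < 1:
                raise DataError(
                    f"no shared ungapped columns between {alignment.ids[i]} "
                    f"and {alignment.ids[j]}"
                )
            diff = both & (codes[i] != codes[j])
            ts = diff & (is_purine[i] == is_purine[j])
            p = float(ts.sum()) / m
            q = float((diff & ~ts).sum()) / m
            arg = (1.0 - 2.0 * p - q) * np.sqrt(max(1.0 - 2.0 * q, 0.0))
            if arg <= 0.0:
                warnings.warn(
                    f"saturated pair ({alignment.ids[i]}, {alignment.ids[j]}); "
                    f"distance capped at {SATURATION_CAP}",
                    stacklevel=2,
                )
                dist = SATURATION_CAP
            else:
                dist = -0.5 * float(np.log(arg))
            d[i, j] = d[j, i] = dist
            P[i, j] = P[j, i] = p
            Q[i, j] = Q[j, i] = q
    return DistanceMatrix(taxa=list(alignment.ids), d=d, P=P, Q=Q)


def neighbor_joining(matrix: DistanceMatrix) -> dendropy.Tree:
    """Classical neighbor joining (Saitou-Nei Q criterion).

    Negative branch-length estimates are clamped to zero.  Q-criterion ties
    break lexicographically on the pair of clade labels (each internal node
    carries the smallest leaf label of its clade), so the returned topology
    does not depend on input order.
    """
    n = len(matrix.taxa)
    if n < 3:
        raise ArgumentError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(matrix.taxa)
    nodes = []
    labels = []
    for t in matrix.taxa:
        nd = dendropy.Node(taxon=tns.get_taxon(t))
        nodes.append(nd)
        labels.append(t)
    D = matrix.d.astype(float).copy()
    active = list(range(n))
    lengths: dict[int, float] = {}
    while len(active) > 3:
        m = len(active)
        sums = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - sums[i] - sums[j]
                pair = tuple(sorted((labels[i], labels[j])))
                key = (q, pair)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # reuse slot i for the new node
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        active.remove(j)
    # endgame: join the last three nodes at a trifurcation with the
    # closed-form pendant lengths l_x = (d_xy + d_xz - d_yz) / 2
    root = dendropy.Node()
    i, j, k = active
    for x, y, z in ((i, j, k), (j, i, k), (k, i, j)):
        lx = 0.5 * (D[x, y] + D[x, z] - D[y, z])
        root.add_child(nodes[x])
        nodes[x].edge.length = max(lx, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def tree_bipartitions(tree: dendropy.Tree, internal_only: bool = True) -> set[frozenset]:
    """Nontrivial bipartitions as frozensets of leaf labels.

    Each bipartition is represented by the side not containing the
    lexicographically smallest leaf, so representations are comparable
    across trees on the same leaf set.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    anchor = min(leaves)
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = frozenset(leaves - clade) if anchor in clade else clade
        if internal_only and (len(side) < 2 or len(side) > len(leaves) - 2):
            continue
        out.add(side)
    return out


def bootstrap_support(
    alignment: Alignment, n_replicates: int = 1000, seed: int = 0
) -> TreeWithSupport:
    """NJ point estimate with column-resampling bootstrap supports.

    Each pseudoreplicate resamples alignment columns with replacement (same
    column count), re-estimates the NJ tree, and every internal bipartition
    of the point-estimate tree receives the fraction of pseudoreplicates
    containing it.  Fixed seed implies identical supports.
    """
    if n_replicates < 1:
        raise ArgumentError("need at least one pseudoreplicate")
    point = neighbor_joining(k2p_distance_matrix(alignment))
    target = tree_bipartitions(point)
    counts = {b: 0 for b in target}
    rng = np.random.default_rng(seed)
    cols = alignment.columns
    rows = np.array([list(r) for r in alignment.rows])
    for _ in range(n_replicates):
        idx = rng.integers(0, cols, size=cols)
        resampled = Alignment(
            ids=list(alignment.ids),
            rows=["".join(r) for r in rows[:, idx]],
            source=alignment.source,
        )
        rep = neighbor_joining(k2p_distance_matrix(resampled))
        for b in tree_bipartitions(rep):
            if b in counts:
                counts[b] += 1
    supports = {b: c / n_replicates for b, c in counts.items()}
    # annotate internal nodes with their support
    leaves = {lf.taxon.label for lf in point.leaf_node_iter()}
    anchor = min(leaves)
    for node in point.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = frozenset(leaves - clade) if anchor in clade else clade
        if side in supports:
            node.label = f"{supports[side]:.3f}"
    return TreeWithSupport(tree=point, n_replicates=n_replicates, supports=supports)


def majority_consensus(
    trees: Sequence[dendropy.Tree], threshold: float = 0.5
) -> dendropy.Tree:
    """Majority-rule consensus: exactly the bipartitions with frequency
    strictly greater than ``threshold``.

    For thresholds >= 0.5 the retained bipartitions are mutually compatible
    and the (possibly multifurcating) consensus is built directly from the
    laminar family they induce; each retained split's node is labeled with
    its frequency.
    """
    if not trees:
        raise ArgumentError("no trees given")
    if threshold < 0.5:
        raise ArgumentError("threshold below 0.5 can retain incompatible splits")
    leafsets = [frozenset(lf.taxon.label for lf in t.leaf_node_iter()) for t in trees]
    leaves = leafsets[0]
    for ls in leafsets[1:]:
        if ls != leaves:
            raise DataError("trees do not share one leaf set")
    anchor = min(leaves)
    counts: dict[frozenset, int] = {}
    for t in trees:
        for b in tree_bipartitions(t):
            counts[b] = counts.get(b, 0) + 1
    n = len(trees)
    kept = {b: c / n for b, c in counts.items() if c / n > threshold}
    # build rooted-at-anchor hierarchy from the laminar family of kept splits
    tns = dendropy.TaxonNamespace(sorted(leaves))
    root = dendropy.Node()
    split_nodes: dict[frozenset, dendropy.Node] = {}
    for split in sorted(kept, key=len, reverse=True):
        node = dendropy.Node()
        node.label = f"{kept[split]:.3f}"
        parent = root
        best_size = None
        for other, nd in split_nodes.items():
            if split < other and (best_size is None or len(other) < best_size):
                parent, best_size = nd, len(other)
        parent.add_child(node)
        split_nodes[split] = node
    for leaf in sorted(leaves):
        node = dendropy.Node(taxon=tns.get_taxon(leaf))
        parent = root
        best_size = None
        for split, nd in split_nodes.items():
            if leaf in split and (best_size is None or len(split) < best_size):
                parent, best_size = nd, len(split)
        parent.add_child(node)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def external_tree(alignment: Alignment, command: str) -> dendropy.Tree:
    """Run any FASTA-in/newick-out tree program (e.g. ``"fasttree -nt"``)."""
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "aln.fasta"
        with open(fin, "w") as fh:
            for i, row in zip(alignment.ids, alignment.rows):
                fh.write(f">{i}\n{row}\n")
        out = subprocess.run(
            command.split() + [str(fin)], capture_output=True, text=True, check=True
        ).stdout
    return dendropy.Tree.get(data=out, schema="newick")
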