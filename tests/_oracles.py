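"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles, sharing no
code with the package: plain-Python dynamic programming for local
alignment, exhaustive topology enumeration for bipartitions and monophyly,
and random additive matrices from explicitly constructed trees.
"""

from __future__ import annotations

import itertools

NEG = float("-inf")


def sw_affine_best_score(q, s, score_fn, gap_open, gap_extend):
    """Smith-Waterman best local score with affine gaps, O(nm) DP.

    ``score_fn(a, b)`` returns the substitution score; a gap of length L
    costs ``gap_open + L * gap_extend``.
    """
    n, m = len(q), len(s)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0)
            M[i][j] = diag + score_fn(q[i - 1], s[j - 1])
            X[i][j] = max(M[i - 1][j] - gap_open - gap_extend, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open - gap_extend, Y[i][j - 1] - gap_extend)
            if M[i][j] > best:
                best = M[i][j]
    return best


def nuc_score_fn(match, mismatch):
    return lambda a, b: match if a == b else mismatch


REVCOMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(REVCOMP)[::-1]


def kmers(seq: str, k: int) -> set:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


# ---------------------------------------------------------------------------
# exhaustive tree topology machinery (nested-tuple representation; a leaf is
# a string, an internal node a tuple of children)


def all_unrooted_topologies(labels):
    """Every unrooted binary topology on the labels, as a trifurcating
    nested-tuple root (the standard unrooted representation)."""
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")
    base = (labels[0], labels[1], labels[2])
    trees = [base]
    for label in labels[3:]:
        nxt = []
        for t in trees:
            for i in range(count_edges(t)):
                nxt.append(insert_on_edge(t, i, label))
        trees = nxt
    return trees


def count_edges(node, is_root=True):
    if isinstance(node, str):
        return 0
    total = 0
    for child in node:
        total += 1 + count_edges(child, False)
    return total


def insert_on_edge(node, edge_idx, label, is_root=True):
    """Insert a new leaf in the middle of the edge with preorder index
    ``edge_idx`` (edges indexed over child edges, recursively)."""

    def rec(nd, idx):
        # returns (new_node, remaining_idx or None when inserted)
        if isinstance(nd, str):
            return nd, idx
        out = []
        for child in nd:
            if idx == 0:
                out.append((child, label))
                idx = None
            elif idx is not None:
                idx -= 1
                new_child, idx = rec(child, idx)
                if idx is None:
                    out.append(new_child)
                    continue
                out.append(new_child)
            else:
                out.append(child)
        return tuple(out), idx

    new, rest = rec(node, edge_idx)
    assert rest is None
    return new


def leaves_of(node):
    if isinstance(node, str):
        return {node}
    out = set()
    for child in node:
        out |= leaves_of(child)
    return out


def clades_of(node, is_root=True):
    """All descendant leaf sets of internal positions (rooted reading)."""
    out = []
    if not isinstance(node, str):
        if not is_root:
            out.append(frozenset(leaves_of(node)))
        for child in node:
            if isinstance(child, str):
                out.append(frozenset({child}))
            else:
                out.extend(clades_of(child, False))
    return out


def bipartitions_of(topo, all_leaves=None):
    """Nontrivial bipartitions of an unrooted nested-tuple tree, each
    represented by the side not containing the smallest label."""
    leaves = frozenset(all_leaves or leaves_of(topo))
    anchor = min(leaves)
    out = set()
    for clade in clades_of(topo):
        if len(clade) < 2 or len(clade) > len(leaves) - 2:
            continue
        side = frozenset(leaves - clade) if anchor in clade else clade
        out.add(side)
    return out


def to_newick(node):
    if isinstance(node, str):
        return node
    return "(" + ",".join(to_newick(c) for c in node) + ")"


def rooted_descendant_sets(node):
    """Descendant leaf sets of every node of a rooted nested-tuple tree."""
    out = [frozenset(leaves_of(node))]
    if not isinstance(node, str):
        for child in node:
            if isinstance(child, str):
                out.append(frozenset({child}))
            else:
                out.extend(rooted_descendant_sets(child))
    return out


# ---------------------------------------------------------------------------
# random additive distance matrices


def random_binary_tree_matrix(labels, rng, blen_lo=0.1, blen_hi=1.0):
    """A random unrooted binary tree with uniform branch lengths, returned
    as (parent links, path-distance matrix) built by explicit path walks."""
    import numpy as np

    nodes = {i: None for i in range(len(labels))}  # leaf ids
    next_id = len(labels)
    active = list(range(len(labels)))
    parent = {}
    blen = {}
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[i], active[j]
        parent[a] = parent[b] = next_id
        blen[a] = rng.uniform(blen_lo, blen_hi)
        blen[b] = rng.uniform(blen_lo, blen_hi)
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    root = next_id
    for a in active:
        parent[a] = root
        blen[a] = rng.uniform(blen_lo, blen_hi)

    def path_to_root(x):
        out = []
        while x in parent:
            out.append(x)
            x = parent[x]
        return out

    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = path_to_root(i), path_to_root(j)
            si, sj = set(pi), set(pj)
            d = sum(blen[x] for x in pi if x not in sj)
            d += sum(blen[x] for x in pj if x not in si)
            D[i, j] = D[j, i] = d
    return D
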