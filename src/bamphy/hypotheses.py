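"""Rooting gene trees, testing clade monophyly against competing
hypotheses, and tabulating support with truncated percentages.

The headline statistic of the analysis: each per-gene tree is rooted at a
designated outgroup and checked, hypothesis by hypothesis, for the
monophyly of the required taxon sets (for example woody-bamboo monophyly
under the nuclear hypothesis versus the herbaceous + tropical pairing under
the plastid hypothesis).  Percentages in the report are floored (truncated)
to two decimals, never rounded: 2374/3878 prints as 61.21 even though the
exact value is 61.2171 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

from ._errors import ArgumentError, DataError

__all__ = [
    "Hypothesis", "SupportReport",
    "root_tree", "is_monophyletic", "classify_trees",
    "support_report", "truncated_percentage", "subtree_category",
    "write_support_report",
]


@dataclass(frozen=True)
class Hypothesis:
    """A named set of clades that must each be monophyletic after rooting."""

    name: str
    required_clades: tuple[frozenset, ...]

    @classmethod
    def of(cls, name: str, *clades: Iterable[str]) -> "Hypothesis":
        return cls(name=name, required_clades=tuple(frozenset(c) for c in clades))


@dataclass
class SupportReport:
    """Per-hypothesis gene-tree counts with floored two-decimal percentages."""

    total_trees: int
    entries: dict[str, tuple[int, float]] = field(default_factory=dict)


def truncated_percentage(count: int, total: int) -> float:
    """floor(count/total * 10^4) / 10^2, computed in exact integer
    arithmetic before the final division."""
    if total < 1:
        raise ArgumentError("total must be >= 1")
    if count > total or count < 0:
        raise DataError(f"count {count} outside [0, {total}]")
    return (count * 10_000 // total) / 100.0


def root_tree(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root on the edge subtending the outgroup leaf; ingroup topology is
    preserved.  Idempotent when already rooted there."""
    rooted = tree.clone(depth=1)
    leaf = None
    for lf in rooted.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == outgroup:
            leaf = lf
            break
    if leaf is None:
        raise DataError(f"outgroup {outgroup!r} is not a leaf of the tree")
    length = leaf.edge.length
    if length is not None:
        rooted.reroot_at_edge(
            leaf.edge, length1=length / 2.0, length2=length / 2.0,
            update_bipartitions=False,
        )
    else:
        rooted.reroot_at_edge(leaf.edge, update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


def _leafset(node: dendropy.Node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def is_monophyletic(rooted_tree: dendropy.Tree, taxa: Iterable[str]) -> bool:
    """True iff some node's descendant leaf set equals ``taxa`` exactly.

    Singleton sets are always monophyletic.  A polytomy counts only when
    the exact leaf-set match exists (no soft-polytomy credit).
    """
    want = frozenset(taxa)
    leaves = {lf.taxon.label for lf in rooted_tree.leaf_node_iter()}
    unknown = want - leaves
    if unknown:
        raise DataError(f"taxa {sorted(unknown)} absent from the tree")
    if len(want) <= 1:
        return True
    for node in rooted_tree.preorder_internal_node_iter():
        if _leafset(node) == want:
            return True
    return False


def classify_trees(
    trees: Sequence[dendropy.Tree],
    outgroup: str,
    hypotheses: Sequence[Hypothesis],
) -> dict[str, int]:
    """Count, per hypothesis, the trees in which every required clade is
    monophyletic after rooting at the outgroup.

    Hypotheses are evaluated independently; one tree may count toward
    several.  Trees where the outgroup attaches inside a hypothesized clade
    simply fail that clade's monophyly.
    """
    counts = {h.name: 0 for h in hypotheses}
    for tree in trees:
        rooted = root_tree(tree, outgroup)
        for h in hypotheses:
            if all(is_monophyletic(rooted, clade) for clade in h.required_clades):
                counts[h.name] += 1
    return counts


def support_report(counts: Mapping[str, int], total: int) -> SupportReport:
    """Attach floored two-decimal percentages to per-hypothesis counts."""
    report = SupportReport(total_trees=total)
    for name, count in counts.items():
        report.entries[name] = (count, truncated_percentage(count, total))
    return report


def write_support_report(path, report: SupportReport) -> None:
    with open(path, "w") as fh:
        fh.write(f"total_trees\t{report.total_trees}\n")
        fh.write("hypothesis\tcount\tpercent\n")
        for name, (count, pct) in report.entries.items():
            fh.write(f"{name}\t{count}\t{pct:.2f}\n")


def subtree_category(
    tree: dendropy.Tree,
    taxon_of: Mapping[str, str],
    bamboo_taxa: Iterable[str],
    ref1_taxon: str,
    ref2_taxon: str,
) -> int | None:
    """Classify a rooted gene-family tree into the three reference-placement
    categories, or ``None``.

    With the bamboo copies monophyletic: category 1 when their clade is
    sister to a clade of reference copies containing both references;
    2 when second-reference copies alone are sister to the bamboo clade and
    that larger clade is sister to first-reference copies; 3 symmetric with
    the references swapped.  Returns ``None`` when bamboo copies are not
    monophyletic or no pattern matches.
    """
    bamboo = set(bamboo_taxa)
    leaf_ids = [lf.taxon.label for lf in tree.leaf_node_iter()]
    bamboo_ids = {i for i in leaf_ids if taxon_of.get(i) in bamboo}
    if not bamboo_ids:
        return None
    node = None
    for nd in tree.preorder_node_iter():
        if _leafset(nd) == bamboo_ids:
            node = nd
            break
    if node is None or node.parent_node is None:
        return None

    def taxa_of(ids: Iterable[str]) -> set:
        return {taxon_of.get(i, "?") for i in ids}

    sibling_ids: set[str] = set()
    for sib in node.parent_node.child_nodes():
        if sib is not node:
            sibling_ids |= _leafset(sib)
    sib_taxa = taxa_of(sibling_ids)
    refs = {ref1_taxon, ref2_taxon}
    if sibling_ids and sib_taxa <= refs:
        if sib_taxa == refs:
            return 1
        inner_ref = next(iter(sib_taxa))
        outer_ref = ref1_taxon if inner_ref == ref2_taxon else ref2_taxon
        grand = node.parent_node.parent_node
        if grand is not None:
            uncle_ids: set[str] = set()
            for sib in grand.child_nodes():
                if sib is not node.parent_node:
                    uncle_ids |= _leafset(sib)
            if uncle_ids and taxa_of(uncle_ids) == {outer_ref}:
                return 2 if inner_ref == ref2_taxon else 3
    return None
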