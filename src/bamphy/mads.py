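"""MADS-box homologue identification, redundancy merging, family
assignment via anchored trees, and copy-count tabulation.

MADS-box transcription factors control floral organ identity (the ABCDE
model) and flowering time (SOC1- and SVP-like genes).  Candidate copies are
found by protein-mode homology search of labeled reference proteins against
translated transcripts, kept when longer than 100 amino acids, and
conspecific copies sharing more than 95 % identity (assembly redundancy)
are reduced to one copy or merged into a consensus spanning the union of
their aligned positions.  Families are then assigned from a neighbor-joining
tree over all copies plus the labeled references: each copy takes the family
of the smallest enclosing clade whose references belong to exactly one
family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._errors import ArgumentError, DataError
from .align import Alignment, progressive_align
from .search import (
    FilterPolicy,
    ScoringScheme,
    filter_hits,
    seeded_search,
)
from .trees import DistanceMatrix, neighbor_joining

__all__ = [
    "MadsCopy",
    "translate_longest_orf",
    "find_homologues",
    "merge_conspecific_copies",
    "assign_families",
    "copy_count_table",
    "sister_bamboo_fraction",
    "write_copy_report",
]

MIN_COPY_LENGTH = 101  # "over 100 amino acids": strict


@dataclass
class MadsCopy:
    """One candidate MADS-box protein copy from one taxon."""

    copy_id: str
    taxon: str
    sequence: str
    family: str = "unassigned"
    merged_from: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) <= 100:
            raise DataError("MADS copies must exceed 100 aa")
        if not self.merged_from:
            self.merged_from = [self.copy_id]


def translate_longest_orf(nuc_seq: str, min_aa: int = MIN_COPY_LENGTH) -> str | None:
    """Longest stop-free translation across the six reading frames.

    A deliberately simple stand-in for full ORF prediction: no start-codon
    requirement, standard genetic code.  Returns ``None`` when no frame
    yields at least ``min_aa`` residues.
    """
    best = ""
    for strand_seq in (nuc_seq, str(Seq(nuc_seq).reverse_complement())):
        for frame in range(3):
            sub = strand_seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            peptide = str(Seq(sub).translate())
            for chunk in peptide.split("*"):
                if len(chunk) > len(best):
                    best = chunk
    return best if len(best) >= min_aa else None


def find_homologues(
    references: Sequence[tuple[str, str]],
    translations: Mapping[str, Sequence[tuple[str, str]]],
    scheme: ScoringScheme | None = None,
    policy: FilterPolicy | None = None,
) -> list[MadsCopy]:
    """Candidate copies: translated transcripts with at least one filtered
    protein hit from the reference set and length > 100 aa, deduplicated."""
    scheme = scheme or ScoringScheme.protein()
    policy = policy or FilterPolicy(min_aln_length=50)
    copies: list[MadsCopy] = []
    for taxon in sorted(translations):
        subjects = [(i, s) for i, s in translations[taxon] if len(s) > 100]
        if not subjects:
            continue
        hits = filter_hits(
            seeded_search(list(references), subjects, scheme=scheme), policy
        )
        hit_ids = {h.subject_id for h in hits}
        seqs = dict(subjects)
        for sid in sorted(hit_ids):
            copies.append(MadsCopy(copy_id=sid, taxon=taxon, sequence=seqs[sid]))
    return copies


def _overlap_identity(a: str, b: str, scheme: ScoringScheme) -> tuple[float, Alignment]:
    """Identity over overlap-only columns (both residues aligned) of a
    pairwise global alignment; end gaps are free so partial assemblies of
    the same protein overlap cleanly."""
    from Bio import Align as _Align

    aligner = _Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = scheme.substitution_table
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -float(scheme.gap_extend)
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    best = aligner.align(a, b)[0]
    from .search import _rows_from_alignment

    ra, rb = _rows_from_alignment(best)
    overlap = [(x, y) for x, y in zip(ra, rb) if x != "-" and y != "-"]
    if not overlap:
        return 0.0, Alignment(ids=["a", "b"], rows=[ra, rb])
    ident = sum(x == y for x, y in overlap) / len(overlap)
    return ident, Alignment(ids=["a", "b"], rows=[ra, rb])


def merge_conspecific_copies(
    copies: Sequence[MadsCopy],
    identity_threshold: float = 0.95,
    scheme: ScoringScheme | None = None,
) -> list[MadsCopy]:
    """Collapse same-species assembly redundancy.

    Single-linkage groups at pairwise overlap identity strictly above the
    threshold (the two most similar distinct reference copies are 93 %
    identical, so 95 % separates assembly artifacts from real paralogues).
    Each group collapses to one copy: the majority-residue consensus over
    the union of aligned positions, ties resolved from the longer source;
    ``merged_from`` records the sources.
    """
    scheme = scheme or ScoringScheme.protein()
    if not copies:
        return []
    taxa = {c.taxon for c in copies}
    if len(taxa) > 1:
        raise ArgumentError("merge operates within one taxon at a time")
    n = len(copies)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            ident, _ = _overlap_identity(copies[i].sequence, copies[j].sequence, scheme)
            if ident > identity_threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged: list[MadsCopy] = []
    for members in sorted(groups.values(), key=lambda g: g[0]):
        if len(members) == 1:
            merged.append(copies[members[0]])
            continue
        group = [copies[i] for i in members]
        group.sort(key=lambda c: (-len(c.sequence), c.copy_id))
        consensus = _consensus_over_union(group, scheme)
        merged.append(
            MadsCopy(
                copy_id=group[0].copy_id,
                taxon=group[0].taxon,
                sequence=consensus,
                merged_from=sorted(x for c in group for x in c.merged_from),
            )
        )
    return merged


def _consensus_over_union(group: Sequence[MadsCopy], scheme: ScoringScheme) -> str:
    """Majority residue per column of the group's multiple alignment; ties
    go to the residue of the longest (first-sorted) source; columns where
    only some sources align contribute their covering residues."""
    aln = progressive_align(
        [(c.copy_id, c.sequence) for c in group], scheme=scheme
    )
    out = []
    for col in range(aln.columns):
        residues = [row[col] for row in aln.rows if row[col] != "-"]
        if not residues:
            continue
        counts: dict[str, int] = {}
        for r in residues:
            counts[r] = counts.get(r, 0) + 1
        top = max(counts.values())
        # first row order = longest source first; its residue wins ties
        winner = next(
            row[col]
            for row in aln.rows
            if row[col] != "-" and counts[row[col]] == top
        )
        out.append(winner)
    return "".join(out)


def _p_distance_matrix(
    named_seqs: Sequence[tuple[str, str]], scheme: ScoringScheme
) -> DistanceMatrix:
    """Protein p-distances (1 - identity on the pairwise global alignment,
    gaps in the denominator)."""
    from .search import percent_identity

    n = len(named_seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, aln = _overlap_identity(named_seqs[i][1], named_seqs[j][1], scheme)
            ident = percent_identity(aln.rows[0], aln.rows[1])
            d[i, j] = d[j, i] = 1.0 - ident
    return DistanceMatrix(
        taxa=[i for i, _ in named_seqs], d=d, P=np.zeros((n, n)), Q=np.zeros((n, n))
    )


def assign_families(
    copies: Sequence[MadsCopy],
    references: Sequence[tuple[str, str, str]],
) -> tuple[list[MadsCopy], dict[str, dendropy.Tree], dendropy.Tree]:
    """Assign each copy the family of its smallest single-family enclosing
    clade in an NJ tree over all copies plus labeled references.

    ``references`` are ``(ref_id, family, sequence)``.  The tree is rooted
    at its midpoint; a copy whose smallest reference-containing clade mixes
    families stays ``unassigned``.  Per-family subtrees are then re-aligned
    and re-estimated separately; each family tree is rooted at the
    lexicographically first reference copy of the family.

    Returns ``(assigned copies, family trees, the full guide tree)``.
    """
    if not references:
        raise ArgumentError("at least one labeled reference is required")
    scheme = ScoringScheme.protein()
    named = [(c.copy_id, c.sequence) for c in copies] + [
        (rid, seq) for rid, _, seq in references
    ]
    ref_family = {rid: fam for rid, fam, _ in references}
    tree = neighbor_joining(_p_distance_matrix(named, scheme))
    rooted = tree.clone(depth=1)
    rooted.reroot_at_midpoint(update_bipartitions=False)
    leaf_node = {
        lf.taxon.label: lf for lf in rooted.leaf_node_iter()
    }
    assigned: list[MadsCopy] = []
    for c in copies:
        node = leaf_node[c.copy_id].parent_node
        family = "unassigned"
        while node is not None:
            fams = {
                ref_family[lf.taxon.label]
                for lf in node.leaf_iter()
                if lf.taxon.label in ref_family
            }
            if fams:
                family = fams.pop() if len(fams) == 1 else "unassigned"
                break
            node = node.parent_node
        assigned.append(
            MadsCopy(
                copy_id=c.copy_id, taxon=c.taxon, sequence=c.sequence,
                family=family, merged_from=list(c.merged_from),
            )
        )
    family_trees: dict[str, dendropy.Tree] = {}
    for family in sorted({a.family for a in assigned} - {"unassigned"}):
        members = [(a.copy_id, a.sequence) for a in assigned if a.family == family]
        refs = sorted(
            (rid, seq) for rid, fam, seq in references if fam == family
        )
        named_fam = members + refs
        if len(named_fam) < 3:
            continue
        progressive_align(named_fam, scheme=scheme)  # re-alignment stage
        ftree = neighbor_joining(_p_distance_matrix(named_fam, scheme))
        if refs:
            froot = ftree.clone(depth=1)
            out_leaf = next(
                lf for lf in froot.leaf_node_iter()
                if lf.taxon.label == refs[0][0]
            )
            length = out_leaf.edge.length or 0.0
            froot.reroot_at_edge(
                out_leaf.edge, length1=length / 2.0, length2=length / 2.0,
                update_bipartitions=False,
            )
            froot.is_rooted = True
            ftree = froot
        family_trees[family] = ftree
    return assigned, family_trees, rooted


def copy_count_table(
    copies: Sequence[MadsCopy],
    taxa: Sequence[str],
    families: Sequence[str],
) -> tuple[pd.DataFrame, list[MadsCopy]]:
    """Family x taxon copy counts with row/column/grand totals.

    Unassigned copies are excluded from the table and returned separately.
    """
    table = pd.DataFrame(0, index=list(families), columns=list(taxa), dtype=int)
    unassigned: list[MadsCopy] = []
    for c in copies:
        if c.family == "unassigned" or c.family not in table.index:
            unassigned.append(c)
            continue
        if c.taxon not in table.columns:
            raise DataError(f"copy {c.copy_id} has unknown taxon {c.taxon!r}")
        table.loc[c.family, c.taxon] += 1
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table, unassigned


def sister_bamboo_fraction(
    family_trees: Mapping[str, dendropy.Tree],
    taxon: str,
    bamboo_taxa: Iterable[str],
    taxon_of: Mapping[str, str],
) -> float:
    """Floored percentage of the taxon's copies whose sister group consists
    exclusively of bamboo copies from other species."""
    from .hypotheses import truncated_percentage

    bamboo = set(bamboo_taxa)
    total = 0
    sister_count = 0
    for tree in family_trees.values():
        for leaf in tree.leaf_node_iter():
            cid = leaf.taxon.label
            if taxon_of.get(cid) != taxon:
                continue
            total += 1
            sib_ids: set[str] = set()
            if leaf.parent_node is None:
                continue
            for sib in leaf.parent_node.child_nodes():
                if sib is not leaf:
                    sib_ids |= {lf.taxon.label for lf in sib.leaf_iter()}
            sib_taxa = {taxon_of.get(i, "?") for i in sib_ids}
            if sib_ids and sib_taxa <= (bamboo - {taxon}):
                sister_count += 1
    if total == 0:
        raise DataError(f"taxon {taxon!r} absent from all family trees")
    return truncated_percentage(sister_count, total)


def write_copy_report(path, copies: Sequence[MadsCopy]) -> None:
    with open(path, "w") as fh:
        fh.write("copy_id\ttaxon\tfamily\tlength\tmerged_from\n")
        for c in copies:
            fh.write(
                f"{c.copy_id}\t{c.taxon}\t{c.family}\t{len(c.sequence)}\t"
                f"{','.join(c.merged_from)}\n"
            )
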