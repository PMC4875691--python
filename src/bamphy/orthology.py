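"""Single-copy orthologue clusters from filtered homology-search tables.

Clusters are anchored on reciprocally unique gene pairs between the two
reference gene sets: an anchor pair (a, b) is accepted only when a's sole
filtered hit among the second reference's genes is b and vice versa.  Each
bamboo taxon then contributes the homologous region of its best-scoring
transcript (highest bit score), and only clusters with a member for every
required taxon survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from ._errors import DataError
from .search import LocalHit

__all__ = [
    "AnchorPair", "ClusterMember", "OrthoCluster",
    "reciprocal_unique_pairs", "best_bamboo_hits",
    "extract_homologous_region", "assemble_clusters",
    "write_cluster_fastas",
]


@dataclass(frozen=True)
class AnchorPair:
    """A reciprocally unique gene pair between the two reference sets."""

    ref1_id: str
    ref2_id: str


@dataclass
class ClusterMember:
    seq_id: str
    sequence: str
    bit_score: float


@dataclass
class OrthoCluster:
    """One anchor gene plus the extracted homologous region per taxon."""

    anchor: AnchorPair
    members: dict[str, ClusterMember] = field(default_factory=dict)

    @property
    def taxa(self) -> set[str]:
        return set(self.members)


def reciprocal_unique_pairs(
    hits_12: Iterable[LocalHit], hits_21: Iterable[LocalHit]
) -> list[AnchorPair]:
    """Anchor pairs (a, b) where a's only subject is b and b's only subject
    is a, after filtering.

    "Exactly one hit" counts distinct subjects (the search already collapses
    multiple segments per subject pair to the best one).  The output is a
    one-to-one partial matching, ordered by ref1 id.
    """
    fwd: dict[str, set[str]] = {}
    for h in hits_12:
        fwd.setdefault(h.query_id, set()).add(h.subject_id)
    rev: dict[str, set[str]] = {}
    for h in hits_21:
        rev.setdefault(h.query_id, set()).add(h.subject_id)
    pairs = []
    for a in sorted(fwd):
        subjects = fwd[a]
        if len(subjects) != 1:
            continue
        (b,) = subjects
        if rev.get(b) == {a}:
            pairs.append(AnchorPair(ref1_id=a, ref2_id=b))
    return pairs


def best_bamboo_hits(
    anchor_ids: Iterable[str],
    per_taxon_hits: Mapping[str, Iterable[LocalHit]],
) -> dict[tuple[str, str], LocalHit]:
    """Best filtered hit per (anchor, taxon), by highest bit score.

    Ties break deterministically: higher identity, then the
    lexicographically smaller subject id.  Taxa without any hit for an
    anchor get no entry (the cluster later fails the completeness rule).
    """
    anchor_set = set(anchor_ids)
    best: dict[tuple[str, str], LocalHit] = {}
    for taxon in sorted(per_taxon_hits):
        for h in per_taxon_hits[taxon]:
            if h.query_id not in anchor_set:
                continue
            key = (h.query_id, taxon)
            cur = best.get(key)
            if cur is None or (
                (h.bit_score, h.identity, [cur.subject_id])
                > (cur.bit_score, cur.identity, [h.subject_id])
            ):
                best[key] = h
    return best


def extract_homologous_region(hit: LocalHit, subject_seq: str) -> str:
    """Subject span of a hit, reverse-complemented for minus-strand hits so
    every cluster member is co-oriented with its anchor."""
    if not (0 <= hit.s_start <= hit.s_end <= len(subject_seq)):
        raise DataError(
            f"hit coordinates [{hit.s_start}, {hit.s_end}) out of range for "
            f"subject of length {len(subject_seq)}"
        )
    region = subject_seq[hit.s_start:hit.s_end]
    if hit.subject_strand == "-":
        region = str(Seq(region).reverse_complement())
    return region


def assemble_clusters(
    anchor_pairs: Sequence[AnchorPair],
    best_hits: Mapping[tuple[str, str], LocalHit],
    require_taxa: Iterable[str],
    anchor_sequences: Mapping[str, str],
    subject_sequences: Mapping[str, Mapping[str, str]],
    ref1_taxon: str,
    ref2_taxon: str,
    hits_12: Iterable[LocalHit] = (),
) -> list[OrthoCluster]:
    """Build complete clusters: anchor + second reference + one region per
    required taxon; clusters missing any required taxon are discarded.

    ``subject_sequences`` maps taxon -> {seq_id: sequence} for every taxon
    appearing in ``best_hits``.  The second reference joins through the
    anchor-defining forward hit (its homologous span on the ref2 gene).
    """
    require = set(require_taxa)
    pair_hit = {(h.query_id, h.subject_id): h for h in hits_12}
    clusters: list[OrthoCluster] = []
    for pair in anchor_pairs:
        members: dict[str, ClusterMember] = {}
        aseq = anchor_sequences[pair.ref1_id]
        members[ref1_taxon] = ClusterMember(pair.ref1_id, aseq, float("inf"))
        h12 = pair_hit.get((pair.ref1_id, pair.ref2_id))
        if h12 is not None:
            ref2_seq = subject_sequences[ref2_taxon][pair.ref2_id]
            members[ref2_taxon] = ClusterMember(
                pair.ref2_id, extract_homologous_region(h12, ref2_seq), h12.bit_score
            )
        for taxon in sorted(require - {ref1_taxon, ref2_taxon}):
            hit = best_hits.get((pair.ref1_id, taxon))
            if hit is None:
                continue
            sseq = subject_sequences[taxon][hit.subject_id]
            members[taxon] = ClusterMember(
                hit.subject_id, extract_homologous_region(hit, sseq), hit.bit_score
            )
        cluster = OrthoCluster(anchor=pair, members=members)
        if require <= cluster.taxa:
            clusters.append(cluster)
    return clusters


def write_cluster_fastas(out_dir, clusters: Sequence[OrthoCluster]) -> None:
    """One FASTA per cluster plus a tab-separated manifest."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "clusters.tsv", "w") as manifest:
        manifest.write("anchor\ttaxon\tmember_id\tbit_score\n")
        for cl in clusters:
            with open(out / f"cluster_{cl.anchor.ref1_id}.fasta", "w") as fh:
                for taxon in sorted(cl.members):
                    m = cl.members[taxon]
                    fh.write(f">{taxon} {m.seq_id}\n{m.sequence}\n")
                    manifest.write(
                        f"{cl.anchor.ref1_id}\t{taxon}\t{m.seq_id}\t{m.bit_score}\n"
                    )
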