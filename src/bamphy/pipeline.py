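"""End-to-end orchestration of the orthologue phylogenomics workflow.

simulate (or load) transcript sets -> reciprocal homology search between
the two reference gene sets -> single-copy anchor pairs -> best-bit-score
bamboo hits -> complete clusters -> per-cluster alignment -> NJ gene trees
-> hypothesis classification and the support report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .align import Alignment, concatenate_supermatrix, progressive_align, strip_gap_columns
from .hypotheses import Hypothesis, SupportReport, classify_trees, support_report
from .orthology import (
    OrthoCluster,
    assemble_clusters,
    best_bamboo_hits,
    reciprocal_unique_pairs,
)
from .search import FilterPolicy, ScoringScheme, filter_hits, seeded_search
from .simulate import SimConfig, TruthSet, make_transcript_sets
from .trees import k2p_distance_matrix, majority_consensus, neighbor_joining

__all__ = [
    "PipelineResult", "default_hypotheses", "apply_dropout",
    "build_clusters", "cluster_gene_trees", "run_orthologue_pipeline",
]


@dataclass
class PipelineResult:
    clusters: list[OrthoCluster]
    alignments: list[Alignment]
    gene_trees: list[dendropy.Tree]
    counts: dict[str, int]
    report: SupportReport
    consensus: dendropy.Tree | None
    truth: TruthSet | None = None
    extras: dict = field(default_factory=dict)

    def fraction(self, hypothesis: str) -> float:
        count = self.counts[hypothesis]
        return count / max(len(self.gene_trees), 1)


def default_hypotheses(taxa: Sequence[str]) -> list[Hypothesis]:
    """The two competing tribe arrangements, on 6 or 7 study taxa.

    ``woody_monophyly``: tropical + temperate woody bamboos form a clade
    (the nuclear hypothesis).  ``plastid_hypothesis``: the herbaceous
    lineage groups with the tropical woody clade instead.  Also reported:
    monophyly of all bamboos, and the two within-tribe pairs when present.
    """
    taxa = list(taxa)
    herb, t1, t2 = taxa[2], taxa[3], taxa[4]
    temperate = taxa[5:]
    woody = frozenset([t1, t2, *temperate])
    hyps = [
        Hypothesis.of("bamboo_monophyly", [herb, *woody]),
        Hypothesis.of("woody_monophyly", woody),
        Hypothesis.of("plastid_hypothesis", [herb, t1, t2]),
        Hypothesis.of("tropical_pair", [t1, t2]),
    ]
    if len(temperate) == 2:
        hyps.append(Hypothesis.of("temperate_pair", temperate))
    return hyps


def apply_dropout(
    transcripts: Mapping[str, Sequence[tuple[str, str]]],
    dropout: float,
    seed: int,
) -> dict[str, list[tuple[str, str]]]:
    """Remove each transcript independently with probability ``dropout``."""
    rng = np.random.default_rng(seed)
    out: dict[str, list[tuple[str, str]]] = {}
    for taxon in sorted(transcripts):
        out[taxon] = [r for r in transcripts[taxon] if rng.random() >= dropout]
    return out


def build_clusters(
    transcripts: Mapping[str, Sequence[tuple[str, str]]],
    references: Mapping[str, Sequence[tuple[str, str]]],
    ref_taxa: Sequence[str],
    policy: FilterPolicy | None = None,
    scheme: ScoringScheme | None = None,
    require_taxa: Sequence[str] | None = None,
    word_size: int = 16,
) -> tuple[list[OrthoCluster], dict]:
    """Search, anchor, and assemble complete orthologue clusters.

    ``word_size`` defaults to 16 here (longer than the search module's
    BLASTN-style 11): genome-scale gene sets make chance 11-mer sharing
    between unrelated kilobase genes common, while true homologs at the
    divergences the filters admit still share hundreds of exact 16-mers.
    """
    policy = policy or FilterPolicy()
    scheme = scheme or ScoringScheme.nucleotide()
    ref1, ref2 = ref_taxa
    ref1_records = list(references[ref1])
    ref2_records = list(references[ref2])
    hits_12 = filter_hits(
        seeded_search(ref1_records, ref2_records, scheme=scheme, word_size=word_size),
        policy,
    )
    hits_21 = filter_hits(
        seeded_search(ref2_records, ref1_records, scheme=scheme, word_size=word_size),
        policy,
    )
    pairs = reciprocal_unique_pairs(hits_12, hits_21)
    anchor_ids = [p.ref1_id for p in pairs]
    per_taxon_hits = {}
    for taxon in sorted(transcripts):
        per_taxon_hits[taxon] = filter_hits(
            seeded_search(
                ref1_records, list(transcripts[taxon]),
                scheme=scheme, word_size=word_size,
            ),
            policy,
        )
    best = best_bamboo_hits(anchor_ids, per_taxon_hits)
    require = list(require_taxa) if require_taxa else [ref2, *sorted(transcripts)]
    subject_sequences = {t: dict(transcripts[t]) for t in transcripts}
    subject_sequences[ref2] = dict(ref2_records)
    clusters = assemble_clusters(
        pairs, best, require,
        anchor_sequences=dict(ref1_records),
        subject_sequences=subject_sequences,
        ref1_taxon=ref1, ref2_taxon=ref2,
        hits_12=hits_12,
    )
    diagnostics = {
        "n_anchor_pairs": len(pairs),
        "n_best_hits": len(best),
        "hits_12": hits_12, "hits_21": hits_21,
        "per_taxon_hits": per_taxon_hits,
    }
    return clusters, diagnostics


def cluster_gene_trees(
    clusters: Sequence[OrthoCluster],
    scheme: ScoringScheme | None = None,
) -> tuple[list[Alignment], list[dendropy.Tree]]:
    """Align each cluster (rows keyed by taxon) and estimate its NJ tree."""
    scheme = scheme or ScoringScheme.nucleotide()
    alignments: list[Alignment] = []
    gene_trees: list[dendropy.Tree] = []
    for cl in clusters:
        records = [
            (taxon, cl.members[taxon].sequence) for taxon in sorted(cl.members)
        ]
        aln = progressive_align(records, scheme=scheme, source=cl.anchor.ref1_id)
        alignments.append(aln)
        gene_trees.append(neighbor_joining(k2p_distance_matrix(aln)))
    return alignments, gene_trees


def run_orthologue_pipeline(
    config: SimConfig,
    policy: FilterPolicy | None = None,
    hypotheses: Sequence[Hypothesis] | None = None,
    with_consensus: bool = True,
    with_supermatrix: bool = False,
) -> PipelineResult:
    """Simulate transcript sets under ``config`` and run the full workflow."""
    transcripts, references, truth = make_transcript_sets(config)
    ref1, ref2 = config.taxa[:2]
    clusters, diagnostics = build_clusters(
        transcripts, references, (ref1, ref2), policy=policy
    )
    alignments, gene_trees = cluster_gene_trees(clusters)
    hyps = list(hypotheses) if hypotheses else default_hypotheses(config.taxa)
    counts = classify_trees(gene_trees, outgroup=ref1, hypotheses=hyps)
    report = support_report(counts, total=max(len(gene_trees), 1))
    consensus = (
        majority_consensus(gene_trees) if with_consensus and gene_trees else None
    )
    extras = dict(diagnostics)
    if with_supermatrix and alignments:
        sm = concatenate_supermatrix(alignments)
        extras["supermatrix"] = sm
        extras["supermatrix_stripped"] = strip_gap_columns(sm)
    return PipelineResult(
        clusters=clusters,
        alignments=alignments,
        gene_trees=gene_trees,
        counts=counts,
        report=report,
        consensus=consensus,
        truth=truth,
        extras=extras,
    )
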