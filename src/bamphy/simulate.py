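"""Seeded synthetic data: species/gene trees, evolved sequences, transcript sets.

The generator emulates the statistical structure the downstream analysis
assumes: a six- or seven-taxon grass species tree with the woody bamboos
monophyletic, per-gene trees drawn with a controlled concordance proportion
(the discordant alternative defaults to the "plastid" rearrangement in which
the herbaceous tribe is sister to the tropical woody tribe), coding sequences
evolved along those trees under an HKY substitution process, transcript sets
with paralogous extra copies and conspecific near-duplicate variants, and a
MADS-like protein family with known class labels.

Indels are not simulated: raw sequences contain only A/C/G/T (or amino
acids), and gaps arise downstream from alignment of truncated paralogues.
Every output is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.linalg import expm

from ._errors import ArgumentError, DataError

NUCS = np.array(list("ACGT"))
AMINO_ACIDS = list("ACDEFGHIKLMNPQRSTVWY")

#: The study's taxa: two outgroup references, then the four sequenced bamboos
#: plus the bamboo reference genome (herbaceous, tropical x2, temperate x2).
DEFAULT_TAXA = (
    "Osativa", "Bdistachyon", "Lpauciflora",
    "Ginermis", "Oacuminata", "Paurea", "Pheterocycla",
)
REFERENCE_TAXA = ("Osativa", "Bdistachyon")

MADS_CLASSES = ("A", "B", "C/D", "E", "SOC-like", "SVP-like")

__all__ = [
    "SimConfig", "TruthSet", "DEFAULT_TAXA", "REFERENCE_TAXA", "MADS_CLASSES",
    "make_species_tree", "plastid_alternative_tree", "sample_gene_trees",
    "evolve_sequences", "make_transcript_sets", "make_mads_truth_set",
    "write_truth_table", "write_config", "write_gene_trees",
]


@dataclass
class TruthSet:
    """Ground truth for a simulated data set.

    ``copy_labels`` maps every emitted sequence id to
    ``(taxon, gene_id, label)`` where label is a gene-family class for
    protein sets or one of ``orthologue``/``paralogue``/``variant`` for
    transcript sets.
    """

    gene_trees: list[str] = field(default_factory=list)
    copy_labels: dict[str, tuple[str, str, str]] = field(default_factory=dict)


def make_species_tree(taxa: Sequence[str]) -> dendropy.Tree:
    """Rooted species tree under the nuclear hypothesis, unit branch lengths.

    ``taxa`` must be ordered (outgroup1, outgroup2, herbaceous, tropical1,
    tropical2, temperate1[, temperate2]): the woody bamboos (tropical +
    temperate) form a clade, the herbaceous lineage is their sister, and the
    two reference outgroups attach successively below.
    """
    taxa = list(taxa)
    if len(taxa) not in (6, 7):
        raise ArgumentError(f"expected 6 or 7 taxa, got {len(taxa)}")
    o1, o2, herb, t1, t2 = taxa[:5]
    if len(taxa) == 7:
        temperate = f"({taxa[5]}:1,{taxa[6]}:1):1"
    else:
        temperate = f"{taxa[5]}:1"
    nwk = f"({o1}:1,({o2}:1,({herb}:1,(({t1}:1,{t2}:1):1,{temperate}):1):1):1):0;"
    return dendropy.Tree.get(data=nwk, schema="newick", rooting="force-rooted")


def plastid_alternative_tree(taxa: Sequence[str]) -> dendropy.Tree:
    """The competing rearrangement: herbaceous + tropical woody as sisters,
    temperate woody outside them (woody bamboos paraphyletic)."""
    taxa = list(taxa)
    if len(taxa) not in (6, 7):
        raise ArgumentError(f"expected 6 or 7 taxa, got {len(taxa)}")
    o1, o2, herb, t1, t2 = taxa[:5]
    if len(taxa) == 7:
        temperate = f"({taxa[5]}:1,{taxa[6]}:1):1"
    else:
        temperate = f"{taxa[5]}:1"
    nwk = (
        f"({o1}:1,({o2}:1,(({herb}:1,({t1}:1,{t2}:1):1):1,{temperate}):1):1):0;"
    )
    return dendropy.Tree.get(data=nwk, schema="newick", rooting="force-rooted")


@dataclass
class SimConfig:
    """Study conditions for one simulated data set.

    Defaults are the conditions the analysis assumes: the seven study taxa,
    gene-tree concordance 0.62 with the plastid rearrangement as the single
    discordant alternative, HKY with kappa 2 and mildly AT-rich base
    frequencies, 0.02 expected substitutions/site per unit branch, and mild
    paralogue/variant noise in the transcript sets.
    """

    seed: int = 0
    taxa: tuple[str, ...] = DEFAULT_TAXA
    species_topology: str | None = None
    n_genes: int = 500
    concordance: float = 0.62
    alt_topologies: tuple[tuple[str, float], ...] | None = None
    gene_length_range: tuple[int, int] = (300, 1500)
    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    branch_scale: float = 0.02
    paralogue_rate: float = 0.1
    variant_rate: float = 0.1
    jitter_sigma: float = 0.3

    def __post_init__(self) -> None:
        if self.species_topology is None:
            self.species_topology = make_species_tree(self.taxa).as_string(
                schema="newick", suppress_rooting=True
            ).strip()
        if self.alt_topologies is None:
            alt = plastid_alternative_tree(self.taxa).as_string(
                schema="newick", suppress_rooting=True
            ).strip()
            self.alt_topologies = ((alt, 1.0 - self.concordance),)
        total = self.concordance + sum(w for _, w in self.alt_topologies)
        if abs(total - 1.0) > 1e-12:
            raise ArgumentError(f"topology probabilities sum to {total}, not 1")
        if abs(sum(self.base_freqs) - 1.0) > 1e-12:
            raise ArgumentError("base frequencies must sum to 1")
        if self.kappa <= 0:
            raise ArgumentError("kappa must be > 0")
        if self.gene_length_range[0] < 3:
            raise ArgumentError("minimum gene length is 3 bp")
        if not (0.0 <= self.concordance <= 1.0):
            raise ArgumentError("concordance must be a probability")


def _jitter_branch_lengths(tree: dendropy.Tree, rng: np.random.Generator, sigma: float) -> None:
    # Lognormal multiplicative jitter with mean 1 (mu = -sigma^2/2).
    mu = -0.5 * sigma * sigma
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.head_node.parent_node is not None:
            edge.length = float(edge.length) * float(np.exp(rng.normal(mu, sigma)))


def sample_gene_trees(config: SimConfig) -> tuple[list[dendropy.Tree], TruthSet]:
    """Draw ``n_genes`` gene trees with concordance ``p``.

    Each tree independently equals the species topology with probability
    ``concordance``, otherwise one alternative by its weight; branch lengths
    receive positive multiplicative lognormal jitter.
    """
    rng = np.random.default_rng(config.seed)
    choices = [(config.species_topology, config.concordance)] + list(config.alt_topologies)
    newicks = [n for n, _ in choices]
    weights = np.array([w for _, w in choices])
    weights = weights / weights.sum()
    trees: list[dendropy.Tree] = []
    truth = TruthSet()
    for g in range(config.n_genes):
        idx = int(rng.choice(len(newicks), p=weights))
        tree = dendropy.Tree.get(
            data=newicks[idx], schema="newick", rooting="force-rooted"
        )
        _jitter_branch_lengths(tree, rng, config.jitter_sigma)
        tree.label = "concordant" if idx == 0 else f"discordant_{idx}"
        trees.append(tree)
        truth.gene_trees.append(
            tree.as_string(schema="newick", suppress_rooting=True).strip()
        )
    return trees, truth


def _hky_rate_matrix(kappa: float, freqs: Sequence[float]) -> np.ndarray:
    """HKY85 instantaneous rate matrix normalized to one expected
    substitution per site per unit branch length."""
    pi = np.asarray(freqs, dtype=float)
    # order A, C, G, T; transitions: A<->G, C<->T
    Q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = (kappa if (i, j) in transitions else 1.0) * pi[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(Q)))
    return Q / mu


def evolve_sequences(
    tree: dendropy.Tree,
    length: int,
    kappa: float = 2.0,
    base_freqs: Sequence[float] = (0.3, 0.2, 0.2, 0.3),
    scale: float = 0.02,
    seed: int = 0,
) -> dict[str, str]:
    """Evolve one ungapped sequence per leaf along a rooted tree.

    The root sequence is drawn from ``base_freqs``; each branch applies the
    HKY transition matrix ``expm(Q * scale * branch_length)`` independently
    per site.  Identical seeds give identical output.
    """
    if length < 3:
        raise ArgumentError("length must be >= 3")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise DataError("negative branch length")
    rng = np.random.default_rng(seed)
    Q = _hky_rate_matrix(kappa, base_freqs)
    root_states = rng.choice(4, size=length, p=np.asarray(base_freqs, float))
    states = {id(tree.seed_node): root_states}
    leaves: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            parent_states = states[id(node)]
        else:
            blen = float(node.edge.length or 0.0)
            parent_states = states[id(node.parent_node)]
            t = scale * blen
            if t == 0.0:
                child = parent_states.copy()
            else:
                P = expm(Q * t)
                P = np.clip(P, 0.0, None)
                P = P / P.sum(axis=1, keepdims=True)
                child = np.empty(length, dtype=np.int64)
                for a in range(4):
                    mask = parent_states == a
                    n = int(mask.sum())
                    if n:
                        child[mask] = rng.choice(4, size=n, p=P[a])
            states[id(node)] = child
            parent_states = child
        if node.is_leaf():
            leaves[node.taxon.label] = "".join(NUCS[states[id(node)]])
    return leaves


def _mutate_nucleotides(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Apply iid substitutions at expected ``divergence`` per site (each hit
    site changes to one of the three other bases)."""
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < divergence
    if hit.any():
        idx = np.flatnonzero(hit)
        current = np.searchsorted(NUCS, arr[idx])
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = NUCS[(current + shift) % 4]
    return "".join(arr)


def make_transcript_sets(
    config: SimConfig,
) -> tuple[dict[str, list[tuple[str, str]]], dict[str, list[tuple[str, str]]], TruthSet]:
    """Per-taxon transcript sets plus the two reference anchor gene sets.

    Returns ``(transcripts, references, truth)``: ``transcripts`` maps each
    bamboo taxon to its (id, sequence) records, including paralogous extra
    copies (further diverged and truncated to 50-100 % of length) and
    near-duplicate variants (< 5 % divergence); ``references`` holds the two
    anchor taxa's gene sets, emitted noise-free as curated single-copy sets.
    """
    trees, truth = sample_gene_trees(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB00]))
    lo, hi = config.gene_length_range
    ref_taxa = set(config.taxa[:2])
    transcripts: dict[str, list[tuple[str, str]]] = {
        t: [] for t in config.taxa if t not in ref_taxa
    }
    references: dict[str, list[tuple[str, str]]] = {t: [] for t in config.taxa[:2]}
    for g, tree in enumerate(trees):
        gene_id = f"g{g:04d}"
        length = int(rng.integers(lo, hi + 1))
        leaf_seqs = evolve_sequences(
            tree, length, config.kappa, config.base_freqs,
            config.branch_scale, seed=int(rng.integers(0, 2**31 - 1)),
        )
        for taxon in config.taxa:
            seq = leaf_seqs[taxon]
            base_id = f"{taxon}_{gene_id}"
            if taxon in ref_taxa:
                references[taxon].append((base_id, seq))
                truth.copy_labels[base_id] = (taxon, gene_id, "orthologue")
                continue
            transcripts[taxon].append((base_id, seq))
            truth.copy_labels[base_id] = (taxon, gene_id, "orthologue")
            # paralogues: extra diverged copies, truncated at 50-100 % length
            n_para = int(rng.poisson(config.paralogue_rate))
            for p in range(n_para):
                para = _mutate_nucleotides(seq, 0.25, rng)
                keep = int(round(len(para) * rng.uniform(0.5, 1.0)))
                para = para[:max(keep, 3)]
                pid = f"{base_id}_p{p + 1}"
                transcripts[taxon].append((pid, para))
                truth.copy_labels[pid] = (taxon, gene_id, "paralogue")
            # near-duplicate variant of the orthologous copy (< 5 % divergence)
            if rng.random() < config.variant_rate:
                var = _mutate_nucleotides(seq, float(rng.uniform(0.005, 0.04)), rng)
                vid = f"{base_id}_v1"
                transcripts[taxon].append((vid, var))
                truth.copy_labels[vid] = (taxon, gene_id, "variant")
    return transcripts, references, truth


def _mutate_protein(seq: str, divergence: float, rng: np.random.Generator) -> str:
    arr = list(seq)
    hit = rng.random(len(arr)) < divergence
    for i in np.flatnonzero(hit):
        choices = [a for a in AMINO_ACIDS if a != arr[i]]
        arr[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(arr)


def make_mads_truth_set(
    copies_per_taxon: Mapping[str, Mapping[str, int]],
    classes: Sequence[str] = MADS_CLASSES,
    taxa: Sequence[str] | None = None,
    seed: int = 0,
    n_decoys_per_taxon: int = 3,
    protein_length: int = 220,
    class_divergence: float = 0.35,
    copy_divergence: float = 0.10,
    anchor_divergence: float = 0.08,
) -> tuple[dict[str, list[tuple[str, str]]], list[tuple[str, str, str]], TruthSet]:
    """Simulate a labeled MADS-like protein family.

    ``copies_per_taxon`` maps class -> taxon -> copy count.  One ancestral
    protein is simulated per class (classes mutually diverged well beyond
    the 95 % merge threshold), diversified per taxon to the requested copy
    numbers; two labeled reference anchors per class and random decoy
    proteins are emitted alongside.  All family copies are > 100 aa.

    Returns ``(per_taxon_proteins, reference_anchors, truth)`` where
    ``reference_anchors`` is a list of ``(anchor_id, class, sequence)``.
    """
    bad = set(copies_per_taxon) - set(classes)
    if bad:
        raise ArgumentError(f"unknown classes {sorted(bad)}")
    if protein_length <= 100:
        raise ArgumentError("family proteins must exceed 100 aa")
    rng = np.random.default_rng(seed)
    if taxa is None:
        taxa = sorted({t for row in copies_per_taxon.values() for t in row})
    family_root = "".join(
        AMINO_ACIDS[int(i)] for i in rng.integers(0, 20, size=protein_length)
    )
    truth = TruthSet()
    per_taxon: dict[str, list[tuple[str, str]]] = {t: [] for t in taxa}
    anchors: list[tuple[str, str, str]] = []
    for cls in classes:
        ancestor = _mutate_protein(family_root, class_divergence, rng)
        safe = cls.replace("/", "").replace("-like", "")
        for ref in REFERENCE_TAXA:
            aid = f"{ref}_MADS_{safe}"
            anchors.append((aid, cls, _mutate_protein(ancestor, anchor_divergence, rng)))
        counts = copies_per_taxon.get(cls, {})
        for taxon in taxa:
            for c in range(int(counts.get(taxon, 0))):
                cid = f"{taxon}_{safe}_{c + 1}"
                per_taxon[taxon].append((cid, _mutate_protein(ancestor, copy_divergence, rng)))
                truth.copy_labels[cid] = (taxon, f"MADS_{safe}", cls)
    for taxon in taxa:
        for d in range(n_decoys_per_taxon):
            did = f"{taxon}_decoy_{d + 1}"
            seq = "".join(AMINO_ACIDS[int(i)] for i in rng.integers(0, 20, size=150))
            per_taxon[taxon].append((did, seq))
            truth.copy_labels[did] = (taxon, "decoy", "decoy")
    return per_taxon, anchors, truth


def write_gene_trees(path, truth: TruthSet) -> None:
    """One newick per line, in gene order."""
    with open(path, "w") as fh:
        for nwk in truth.gene_trees:
            fh.write(nwk + "\n")


def write_truth_table(path, truth: TruthSet) -> None:
    with open(path, "w") as fh:
        fh.write("copy_id\ttaxon\tgene_id\tlabel\n")
        for cid in sorted(truth.copy_labels):
            taxon, gene, label = truth.copy_labels[cid]
            fh.write(f"{cid}\t{taxon}\t{gene}\t{label}\n")


def write_config(path, config: SimConfig) -> None:
    """Single structured text file, one ``key: value`` per line."""
    with open(path, "w") as fh:
        for key in (
            "seed", "taxa", "species_topology", "n_genes", "concordance",
            "alt_topologies", "gene_length_range", "kappa", "base_freqs",
            "branch_scale", "paralogue_rate", "variant_rate", "jitter_sigma",
        ):
            fh.write(f"{key}: {getattr(config, key)}\n")
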