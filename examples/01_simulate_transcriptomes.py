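"""Simulate a six-taxon bamboo transcriptome study and inspect the truth set.

Generates gene trees at 62 % concordance with the species tree, evolves
coding sequences along them under HKY, and emits per-taxon transcript sets
with paralogue and near-duplicate noise plus the two reference anchor sets.
"""

from bamphy import DEFAULT_TAXA, SimConfig, make_transcript_sets

config = SimConfig(seed=1, n_genes=25, taxa=DEFAULT_TAXA[:6])
transcripts, references, truth = make_transcript_sets(config)

print(f"species tree: {config.species_topology}")
print(f"simulated {config.n_genes} genes at concordance {config.concordance}")
for taxon, records in references.items():
    print(f"  reference {taxon}: {len(records)} anchor genes")
for taxon, records in transcripts.items():
    labels = [truth.copy_labels[i][2] for i, _ in records]
    print(
        f"  {taxon}: {len(records)} transcripts "
        f"({labels.count('paralogue')} paralogues, {labels.count('variant')} variants)"
    )
first = truth.gene_trees[0]
print(f"first true gene tree: {first[:70]}...")
# The extra paralogue/variant copies are the noise the orthologue filters
# must reject; the truth table ties every emitted id back to its gene.
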