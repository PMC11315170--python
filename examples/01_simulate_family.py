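"""Simulate a receptor family across species with complete ground truth.

Generates a species tree, evolves a gene family on it by duplication/loss,
realises multi-exon gene sequences and emits a fragmented assembly.
"""

from paraloscope import SimulationConfig, simulate

bundle = simulate(SimulationConfig(n_taxa=6, root_genes=4, seed=7))

n_split = sum(t.is_split for t in bundle.truth.records)
print(f"taxa:        {sorted(bundle.history.leaf_genes)}")
print(f"subfamilies: {bundle.history.subfamilies}")
print(f"genes:       {len(bundle.truth.records)} "
      f"({n_split} split across contigs by fragmentation)")
print(f"contigs:     {len(bundle.genome.contigs)}")
print(f"events:      {len(bundle.history.events)} duplication/loss events")
# Each truth record pins a gene's exons to contig coordinates, so any
# downstream prediction can be scored exactly against what was planted.
t = bundle.truth.records[0]
print(f"example truth gene {t.gene_id} ({t.strand} strand): "
      + ", ".join(f"{e.contig}:{e.start}-{e.end}" for e in t.exons))
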