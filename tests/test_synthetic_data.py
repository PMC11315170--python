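"""Generator invariants: tree shape, birth-death bookkeeping, splice grammar,
fragmentation conservation and the FASTA/GFF3 round trip."""

import dendropy
import numpy as np
import pytest

from paraloscope import io as pio
from paraloscope.synthetic_data import (
    SimulationConfig,
    emit_fragmented_assembly,
    evolve_gene_family,
    mutate_gene_sequences,
    simulate,
    simulate_species_tree,
    taxa_by_patristic_distance,
    tree_height,
)


class TestSpeciesTree:
    def test_two_taxa_is_a_cherry(self):
        tree = simulate_species_tree(2, seed=0)
        assert len(tree.leaf_nodes()) == 2
        internals = [n for n in tree if not n.is_leaf()]
        assert len(internals) == 1

    @pytest.mark.parametrize("n", [2, 5, 8, 13])
    def test_binary_tree_internal_node_count(self, n):
        tree = simulate_species_tree(n, seed=3)
        internals = [x for x in tree if not x.is_leaf()]
        assert len(internals) == n - 1
        assert all((e.length or 0) >= 0 for e in tree.edges())

    def test_deterministic_newick(self):
        a = simulate_species_tree(8, seed=42).as_string(schema="newick")
        b = simulate_species_tree(8, seed=42).as_string(schema="newick")
        assert a == b

    def test_ultrametric_unit_height(self):
        tree = simulate_species_tree(9, seed=7)
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert np.allclose(depths, 1.0, atol=1e-6)

    def test_invalid_n_taxa(self):
        with pytest.raises(ValueError):
            simulate_species_tree(0, seed=1)

    def test_patristic_order_starts_at_query(self):
        tree = simulate_species_tree(8, seed=7)
        order = taxa_by_patristic_distance(tree, "T03")
        assert order[0] == "T03"
        assert sorted(order) == [f"T{i + 1:02d}" for i in range(8)]


class TestGeneFamily:
    def test_no_events_means_constant_copy_number(self):
        tree = simulate_species_tree(6, seed=2)
        hist = evolve_gene_family(tree, 0.0, 0.0, root_genes=4, seed=9)
        for taxon, genes in hist.leaf_genes.items():
            assert len(genes) == 4
        assert hist.events == []

    def test_births_only_counts_nondecreasing(self):
        # with loss_rate 0 every root gene survives in every leaf
        tree = simulate_species_tree(6, seed=2)
        hist = evolve_gene_family(tree, 0.5, 0.0, root_genes=2, seed=9)
        for taxon, genes in hist.leaf_genes.items():
            assert len(genes) >= 2
            per_sf = {}
            for _, sf in genes:
                per_sf[sf] = per_sf.get(sf, 0) + 1
            assert set(per_sf) == {"SF1", "SF2"}

    def test_negative_rates_rejected(self):
        tree = simulate_species_tree(4, seed=2)
        with pytest.raises(ValueError):
            evolve_gene_family(tree, -0.1, 0.0, 1, seed=0)

    def test_birth_death_expectation(self):
        # E[leaves per root gene] = exp((dup-loss) * T); tree height T = 1
        tree = simulate_species_tree(2, seed=4)
        dup, loss, reps = 0.3, 0.1, 2000
        counts = []
        for s in range(reps):
            hist = evolve_gene_family(tree, dup, loss, root_genes=1, seed=s)
            counts.append(len(hist.leaf_genes["T01"]))
        mean = np.mean(counts)
        expected = np.exp((dup - loss) * tree_height(tree))
        se = np.std(counts, ddof=1) / np.sqrt(reps)
        assert abs(mean - expected) < 3 * se + 1e-9

    def test_event_bookkeeping_against_gene_tree(self):
        tree = simulate_species_tree(5, seed=3)
        hist = evolve_gene_family(tree, 0.4, 0.3, root_genes=3, seed=17)
        n_leaf_total = sum(len(v) for v in hist.leaf_genes.values())
        from_tree = sum(
            1 for root in hist.roots for _ in root.leaf_iter()
        )
        assert n_leaf_total == from_tree


class TestSequences:
    def test_zero_divergence_identical_peptides(self):
        tree = simulate_species_tree(5, seed=1)
        hist = evolve_gene_family(tree, 0.0, 0.0, 2, seed=2)
        seqs = mutate_gene_sequences(hist, subst_scale=0.0, seed=3)
        by_sf = {}
        for g in seqs.values():
            by_sf.setdefault(g.subfamily, set()).add(g.protein)
        for sf, prots in by_sf.items():
            assert len(prots) == 1

    def test_exon_count_conserved_within_subfamily(self, default_bundle):
        by_sf = {}
        for g in default_bundle.sequences.values():
            by_sf.setdefault(g.subfamily, set()).add(g.exon_count)
        for sf, counts in by_sf.items():
            assert len(counts) == 1

    def test_introns_have_canonical_splice_sites(self, default_bundle):
        for g in default_bundle.sequences.values():
            for intron in g.introns:
                assert intron.startswith("GT") and intron.endswith("AG")
                assert len(intron) >= 60

    def test_identity_decreases_with_patristic_distance(self):
        tree = simulate_species_tree(12, seed=6)
        hist = evolve_gene_family(tree, 0.0, 0.0, 1, seed=7)
        seqs = mutate_gene_sequences(hist, subst_scale=0.4, seed=8)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        gene_of = {g.taxon: g for g in seqs.values()}
        rng = np.random.default_rng(0)
        labels = sorted(gene_of)
        dists, idents = [], []
        pairs = set()
        while len(pairs) < 10:
            a, b = rng.choice(labels, size=2, replace=False)
            pairs.add((min(a, b), max(a, b)))
        for a, b in sorted(pairs):
            d = pdm.patristic_distance(taxa[a], taxa[b])
            pa, pb = gene_of[a].protein, gene_of[b].protein
            ident = np.mean([x == y for x, y in zip(pa, pb)])
            dists.append(d)
            idents.append(ident)
        from scipy.stats import spearmanr

        rho, _ = spearmanr(dists, idents)
        assert rho < 0


class TestAssembly:
    def test_no_fragmentation_keeps_genes_intact(self):
        bundle = simulate(SimulationConfig(seed=2, fragmentation=0.0))
        assert all(not t.is_split for t in bundle.truth.records)

    @pytest.mark.parametrize("frag", [0.0, 2.0, 8.0])
    def test_breakpoints_conserve_sequence(self, frag):
        # contigs of each chromosome tile it exactly, whatever the rate
        tree = simulate_species_tree(3, seed=5)
        hist = evolve_gene_family(tree, 0.0, 0.0, 3, seed=6)
        seqs = mutate_gene_sequences(hist, 0.2, seed=7)
        genome, _ = emit_fragmented_assembly(seqs.values(), frag, seed=8)
        by_chrom = {}
        for cid, seq in genome.contigs:
            taxon, chrom, (lo, hi) = genome.provenance[cid]
            assert hi - lo + 1 == len(seq)
            by_chrom.setdefault((taxon, chrom), []).append((lo, hi))
        for ivals in by_chrom.values():
            ivals.sort()
            assert ivals[0][0] == 1
            for (l1, h1), (l2, h2) in zip(ivals, ivals[1:]):
                assert l2 == h1 + 1

    def test_split_fraction_increases_with_fragmentation(self):
        # Monte-Carlo over seeds: fraction of genes on >=2 contigs grows
        tree = simulate_species_tree(2, seed=5)
        hist = evolve_gene_family(tree, 0.0, 0.0, 4, seed=6)
        seqs = mutate_gene_sequences(hist, 0.1, seed=7)
        levels = [0.0, 0.5, 2.0, 8.0]
        fractions = []
        for frag in levels:
            split = total = 0
            for s in range(500):
                _, truth = emit_fragmented_assembly(seqs.values(), frag, seed=s)
                split += sum(t.is_split for t in truth.records)
                total += len(truth.records)
            fractions.append(split / total)
        assert fractions[0] == 0.0
        assert all(a <= b for a, b in zip(fractions, fractions[1:]))
        assert fractions[-1] > fractions[0]

    def test_truth_exons_ordered_and_disjoint(self, default_bundle):
        for t in default_bundle.truth.records:
            per_contig = {}
            for ex in t.exons:
                per_contig.setdefault(ex.contig, []).append((ex.start, ex.end))
            for ivals in per_contig.values():
                ivals.sort()
                for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                    assert e1 < s2


class TestRoundTrip:
    def test_splice_translate_reproduces_recorded_peptides(self, default_bundle):
        contigs = default_bundle.genome.contig_dict()
        for t in default_bundle.truth.records:
            protein, peps = pio.truth_gene_peptides(contigs, t)
            g = default_bundle.sequences[t.gene_id]
            assert protein == g.protein
            assert peps == g.exon_peptides

    def test_full_determinism_of_bundle(self):
        cfg = SimulationConfig(seed=21, n_taxa=4, root_genes=2)
        b1, b2 = simulate(cfg), simulate(cfg)
        assert b1.genome.contigs == b2.genome.contigs
        assert [t.gene_id for t in b1.truth.records] == [
            t.gene_id for t in b2.truth.records
        ]
        assert b1.species_tree.as_string(schema="newick") == b2.species_tree.as_string(
            schema="newick"
        )

    def test_gff3_roundtrip(self, default_bundle, tmp_path):
        path = tmp_path / "truth.gff3"
        pio.write_truth_gff3(path, default_bundle.truth)
        back = pio.read_truth_gff3(path)
        key = lambda r: (r.gene_id, r.strand, tuple(r.phases), tuple(r.exons))
        assert sorted(map(key, back.records)) == sorted(
            map(key, default_bundle.truth.records)
        )

    def test_fasta_roundtrip_rewrap(self, tmp_path, default_bundle):
        path = tmp_path / "contigs.fasta"
        pio.write_fasta(path, default_bundle.genome.contigs)
        back = pio.read_fasta(path)
        assert back == default_bundle.genome.contigs
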