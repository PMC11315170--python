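"""Length filter, progressive aligner, NJ, bootstrap, clade classification."""

import numpy as np
import pytest

from paraloscope.classification import (
    MultipleAlignment,
    RecoveredSequence,
    bootstrap_support,
    classify_by_tree,
    dedup_near_identical,
    length_filter,
    neighbor_joining_tree,
    progressive_align,
    protein_distance_matrix,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _seq(i, taxon="t", peptide="M" * 50, nt=None):
    return RecoveredSequence(
        id=f"s{i}", taxon=taxon, peptide=peptide,
        nt_length=nt if nt is not None else 3 * len(peptide),
    )


class TestLengthFilter:
    def test_exactly_100_nt_removed_and_101_kept(self):
        seqs = [_seq(0, nt=100), _seq(1, nt=101)]
        kept = length_filter(seqs, 100)
        assert [s.id for s in kept] == ["s1"]

    def test_empty_input(self):
        assert length_filter([]) == []

    def test_aa_unit_option(self):
        seqs = [_seq(0, peptide="M" * 100, nt=1), _seq(1, peptide="M" * 101, nt=1)]
        kept = length_filter(seqs, 100, unit="aa")
        assert [s.id for s in kept] == ["s1"]

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        seqs = [_seq(i, nt=int(rng.integers(50, 200))) for i in range(20)]
        once = length_filter(seqs)
        twice = length_filter(once)
        assert once == twice


def _random_peptides(rng, n, lo=40, hi=80):
    return [
        (f"q{i}", "".join(rng.choice(list(AA), size=int(rng.integers(lo, hi)))))
        for i in range(n)
    ]


class TestProgressiveAlign:
    def test_identical_pair_gapless(self):
        msa = progressive_align([("a", "MKWLVR"), ("b", "MKWLVR")])
        assert msa.rows == ["MKWLVR", "MKWLVR"]

    @pytest.mark.parametrize("seed", range(10))
    def test_roundtrip_restores_inputs(self, seed):
        rng = np.random.default_rng(seed)
        seqs = _random_peptides(rng, int(rng.integers(2, 7)))
        msa = progressive_align(seqs)
        by_id = dict(seqs)
        for sid, row in zip(msa.ids, msa.rows):
            assert row.replace("-", "") == by_id[sid]

    def test_pairwise_matches_biopython_global_dp(self):
        # for 2 sequences the profile merge reduces to plain global alignment
        from Bio import Align

        from paraloscope._aln import blosum62_cached, encode_peptide, gotoh_align

        rng = np.random.default_rng(5)
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        from Bio.Align import substitution_matrices

        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        S = blosum62_cached()
        for _ in range(25):
            a = "".join(rng.choice(list(AA), size=int(rng.integers(20, 60))))
            b = "".join(rng.choice(list(AA), size=int(rng.integers(20, 60))))
            sim = S[np.ix_(encode_peptide(a), encode_peptide(b))]
            score, _, _ = gotoh_align(sim, -10.0, -0.5)
            assert score == pytest.approx(aligner.score(a, b))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = neighbor_joining_tree(D, ["a", "b", "c"])
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_additive_distances_recover_topology(self):
        import dendropy

        from paraloscope.synthetic_data import simulate_species_tree

        true = simulate_species_tree(8, seed=13)
        pdm = true.phylogenetic_distance_matrix()
        taxa = sorted(true.taxon_namespace, key=lambda t: t.label)
        labels = [t.label for t in taxa]
        n = len(labels)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
        nj = neighbor_joining_tree(D, labels)
        from paraloscope.classification import _bipartitions

        assert _bipartitions(nj) == _bipartitions(true)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(2)
        n = 7
        base = rng.uniform(1, 10, size=(n, n))
        D = (base + base.T) / 2
        np.fill_diagonal(D, 0)
        labels = [f"x{i}" for i in range(n)]
        t1 = neighbor_joining_tree(D, labels)
        perm = rng.permutation(n)
        t2 = neighbor_joining_tree(D[np.ix_(perm, perm)], [labels[i] for i in perm])
        from paraloscope.classification import _bipartitions

        assert _bipartitions(t1) == _bipartitions(t2)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError):
            neighbor_joining_tree(D, list("abc"))

    def test_skbio_cross_check(self):
        # independent NJ implementation agrees on the topology
        import dendropy
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(9)
        n = 6
        base = rng.uniform(1, 10, size=(n, n))
        D = (base + base.T) / 2
        np.fill_diagonal(D, 0)
        labels = [f"x{i}" for i in range(n)]
        mine = neighbor_joining_tree(D, labels)
        theirs = skbio_nj(DistanceMatrix(D, labels))
        ns = dendropy.TaxonNamespace(labels)
        t1 = dendropy.Tree.get(data=mine.as_string(schema="newick"),
                               schema="newick", taxon_namespace=ns)
        t2 = dendropy.Tree.get(data=str(theirs), schema="newick",
                               taxon_namespace=ns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0


class TestBootstrap:
    def _family_msa(self, seed=0):
        # two deeply separated subfamilies of near-identical members
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list(AA), size=60))
        b = "".join(rng.choice(list(AA), size=60))

        def mutate(s, k):
            s = list(s)
            for pos in rng.choice(len(s), size=k, replace=False):
                s[pos] = AA[rng.integers(20)]
            return "".join(s)

        seqs = [(f"a{i}", mutate(a, 3)) for i in range(3)]
        seqs += [(f"b{i}", mutate(b, 3)) for i in range(3)]
        return progressive_align(seqs)

    def test_no_reps_no_supports(self):
        msa = self._family_msa()
        tree, supports = bootstrap_support(msa, 0, seed=1)
        assert supports == {}
        assert {l.taxon.label for l in tree.leaf_node_iter()} == set(msa.ids)

    def test_supports_in_range_and_split_support(self):
        for seed in range(5):
            msa = self._family_msa(seed)
            tree, supports = bootstrap_support(msa, 200, seed=seed)
            assert all(0 <= v <= 100 for v in supports.values())
            split = frozenset({"a0", "a1", "a2"})
            assert supports.get(split, 0.0) >= 95.0


class TestClassify:
    def _tree(self, newick):
        import dendropy

        return dendropy.Tree.get(data=newick, schema="newick")

    def test_query_sister_to_single_reference(self):
        tree = self._tree("((q1:1,REFA:1):1,(REFB:1,REFC:1):1);")
        labels = classify_by_tree(
            tree, {"REFA": "A", "REFB": "B", "REFC": "C"}
        )
        assert labels["q1"] == "A"

    def test_query_between_blocks_unclassified(self):
        # q sits sister to a mixed (A,B) pair: no pure reference clade
        tree = self._tree("((q1:1,(REFA:1,REFB:1):1):1,(REFA2:1,REFB2:1):1);")
        labels = classify_by_tree(
            tree, {"REFA": "A", "REFB": "B", "REFA2": "A", "REFB2": "B"}
        )
        assert labels["q1"] == "unclassified"

    def test_leaf_order_permutation_invariance(self):
        newick = "((q1:1,REFA:1):1,((q2:1,REFB:1):1,(REFC:1,q3:1):1):1);"
        refs = {"REFA": "A", "REFB": "B", "REFC": "C"}
        t1 = self._tree(newick)
        l1 = classify_by_tree(t1, refs)
        newick2 = "(((REFC:1,q3:1):1,(REFB:1,q2:1):1):1,(REFA:1,q1:1):1);"
        l2 = classify_by_tree(self._tree(newick2), refs)
        assert l1 == l2 == {"q1": "A", "q2": "B", "q3": "C"}

    def test_no_references_rejected(self):
        tree = self._tree("((a:1,b:1):1,c:1);")
        with pytest.raises(ValueError):
            classify_by_tree(tree, {})


class TestDedup:
    def test_identical_pair_collapses(self):
        reps, cmap = dedup_near_identical([("a", "MKWLVR"), ("b", "MKWLVR")])
        assert len(reps) == 1
        assert cmap["a"] == cmap["b"]

    def test_threshold_one_keeps_distinct(self):
        reps, _ = dedup_near_identical(
            [("a", "MKWLVR"), ("b", "MKWLVA")], identity_threshold=1.0
        )
        assert len(reps) == 2

    def test_identity_arithmetic_at_threshold(self):
        # 199/200 identical columns -> identity 0.995 >= 0.99 -> merged
        rng = np.random.default_rng(8)
        base = "".join(rng.choice(list(AA), size=200))
        variant = "Q" + base[1:] if base[0] != "Q" else "W" + base[1:]
        reps, cmap = dedup_near_identical(
            [("long", base), ("var", variant)], identity_threshold=0.99
        )
        assert len(reps) == 1

    def test_longest_member_represents(self):
        reps, cmap = dedup_near_identical(
            [("short", "MKWLVR"), ("long", "MKWLVRS")], identity_threshold=0.8
        )
        assert reps == ["short"] or reps == ["long"]
        assert cmap["short"] == "long"
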