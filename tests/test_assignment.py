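"""Assignment solver vs enumeration oracle, conflicts, split-gene merging."""

import itertools

import numpy as np
import pytest

from paraloscope.assignment import (
    AssignmentInstance,
    Candidate,
    InstanceTooLargeError,
    build_assignment_instance,
    merge_split_genes,
    solve_assignment,
    validate_solution,
)
from paraloscope.genome_search import GeneModelCandidate
from tests.test_genome_search import _mk_hit


def _gm(paralog, contig, strand, exon_spans, score):
    hits = [
        _mk_hit(contig, strand, idx, s, e, score / len(exon_spans))
        for idx, (s, e) in exon_spans.items()
    ]
    for h in hits:
        object.__setattr__(h, "paralog", paralog)
    return GeneModelCandidate(
        paralog=paralog, hits=hits, total_score=score,
        completeness=len(exon_spans) / max(exon_spans),
    )


def _cand(paralog, locus, score, exons=frozenset({1}), interval=("c", "+", 1, 10)):
    return Candidate(
        paralog=paralog, locus=locus, score=score, exons=frozenset(exons),
        intervals=(interval,), exon_intervals=(interval,), n_query_exons=max(exons),
    )


class TestBuildInstance:
    def test_different_contigs_never_conflict(self):
        inst = build_assignment_instance(
            [_gm("A", "c1", "+", {1: (1, 100)}, 10.0),
             _gm("B", "c2", "+", {1: (1, 100)}, 10.0)]
        )
        assert inst.conflicts == set()

    def test_identical_intervals_conflict(self):
        inst = build_assignment_instance(
            [_gm("A", "c1", "+", {1: (1, 100)}, 10.0),
             _gm("B", "c1", "+", {1: (1, 100)}, 10.0)]
        )
        assert len(inst.conflicts) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_conflict_count_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        gms = []
        for k in range(10):
            start = int(rng.integers(1, 500))
            gms.append(
                _gm(f"P{rng.integers(3)}", f"c{rng.integers(2)}",
                    "+" if rng.random() < 0.7 else "-",
                    {1: (start, start + int(rng.integers(50, 200)))},
                    float(rng.uniform(1, 10)))
            )
        inst = build_assignment_instance(gms)
        expected = 0
        for i in range(len(inst.candidates)):
            for j in range(i + 1, len(inst.candidates)):
                a = inst.candidates[i].exon_intervals[0]
                b = inst.candidates[j].exon_intervals[0]
                if a[0] == b[0] and a[1] == b[1] and a[2] <= b[3] and b[2] <= a[3]:
                    expected += 1
        assert len(inst.conflicts) == expected


def _enumerate_optimum(inst: AssignmentInstance, max_copies=1):
    """Oracle: best conflict-free selection over all subsets."""
    import networkx as nx

    n = len(inst.candidates)
    graph = inst.conflict_graph()
    comp_of = {}
    for ci, comp in enumerate(nx.connected_components(graph)):
        for i in comp:
            comp_of[i] = ci
    best = 0.0
    for r in range(n + 1):
        for subset in itertools.combinations(range(n), r):
            ok = True
            for a, b in itertools.combinations(subset, 2):
                if (min(a, b), max(a, b)) in inst.conflicts:
                    ok = False
                    break
            if not ok:
                continue
            copies = {}
            for i in subset:
                key = (comp_of[i], inst.candidates[i].paralog)
                copies[key] = copies.get(key, 0) + 1
                if copies[key] > max_copies:
                    ok = False
                    break
            if ok:
                best = max(best, sum(inst.candidates[i].score for i in subset))
    return best


class TestSolve:
    def test_diagonal_dominant_identity_pairing(self):
        # 3 paralogs x 3 loci, all-pairs conflicts within each locus
        cands = []
        for li, locus in enumerate(("L1", "L2", "L3")):
            for pi, paralog in enumerate(("A", "B", "C")):
                score = 10.0 if li == pi else 1.0
                cands.append(
                    _cand(paralog, f"{locus}|{paralog}", score,
                          interval=(locus, "+", 1, 100))
                )
        conflicts = set()
        for i in range(len(cands)):
            for j in range(i + 1, len(cands)):
                if cands[i].intervals[0][0] == cands[j].intervals[0][0]:
                    conflicts.add((i, j))
        inst = AssignmentInstance(cands, conflicts)
        sol = solve_assignment(inst)
        chosen = {(c.paralog, c.intervals[0][0]) for c in
                  (inst.candidates[i] for i in sol.chosen_indices)}
        assert chosen == {("A", "L1"), ("B", "L2"), ("C", "L3")}
        assert sol.certificate == "optimal"

    def test_empty_instance(self):
        sol = solve_assignment(AssignmentInstance([], set()))
        assert sol.total_score == 0.0
        assert sol.genes == []

    def test_exact_limit_enforced(self):
        cands = [_cand("A", f"L{i}", 1.0) for i in range(30)]
        inst = AssignmentInstance(cands, set())
        with pytest.raises(InstanceTooLargeError):
            solve_assignment(inst, exact_limit=25)
        sol = solve_assignment(inst, exact_limit=25, fallback_to_greedy=True)
        assert sol.certificate == "heuristic"

    @pytest.mark.parametrize("max_copies", [1, 2])
    def test_exact_matches_enumeration_on_random_instances(self, max_copies):
        rng = np.random.default_rng(7)
        for trial in range(200):
            n_par = int(rng.integers(1, 6))
            n_loc = int(rng.integers(1, 6))
            cands = []
            for p in range(n_par):
                for l in range(n_loc):
                    if rng.random() < 0.6:
                        cands.append(
                            _cand(
                                f"P{p}", f"P{p}@L{l}",
                                float(rng.uniform(0.5, 10.0)),
                                interval=(f"L{l}", "+", 1, 100),
                            )
                        )
            conflicts = set()
            for i in range(len(cands)):
                for j in range(i + 1, len(cands)):
                    same_locus = (
                        cands[i].intervals[0][0] == cands[j].intervals[0][0]
                    )
                    if same_locus or rng.random() < 0.1:
                        conflicts.add((i, j))
            inst = AssignmentInstance(cands, conflicts)
            sol = solve_assignment(inst, max_copies=max_copies)
            oracle = _enumerate_optimum(inst, max_copies)
            assert sol.total_score == pytest.approx(oracle), f"trial {trial}"

    def test_greedy_never_beats_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            cands = [
                _cand(f"P{rng.integers(3)}", f"L{i}", float(rng.uniform(1, 10)),
                      interval=(f"c{rng.integers(3)}", "+",
                                int(s := rng.integers(1, 300)), int(s) + 50))
                for i in range(8)
            ]
            inst = build_assignment_instance([])  # rebuilt below
            conflicts = set()
            for i in range(len(cands)):
                for j in range(i + 1, len(cands)):
                    a, b = cands[i].intervals[0], cands[j].intervals[0]
                    if a[0] == b[0] and a[2] <= b[3] and b[2] <= a[3]:
                        conflicts.add((i, j))
            inst = AssignmentInstance(cands, conflicts)
            exact = solve_assignment(inst, mode="exact")
            greedy = solve_assignment(inst, mode="greedy")
            assert greedy.total_score <= exact.total_score + 1e-9
            validate_solution(exact, inst)
            validate_solution(greedy, inst)

    def test_greedy_equals_exact_on_conflict_free(self):
        cands = [_cand("A", f"L{i}", float(i + 1),
                       interval=(f"c{i}", "+", 1, 10)) for i in range(5)]
        inst = AssignmentInstance(cands, set())
        assert (
            solve_assignment(inst, mode="greedy").total_score
            == solve_assignment(inst, mode="exact").total_score
        )


class TestMergeSplit:
    def test_complementary_contigs_merge(self):
        gms = [
            _gm("A", "c1", "+", {1: (1, 90), 2: (200, 290)}, 20.0),
            _gm("A", "c2", "+", {3: (1, 90), 4: (200, 290)}, 18.0),
        ]
        inst = build_assignment_instance(gms)
        sol = merge_split_genes(solve_assignment(inst), inst)
        assert len(sol.genes) == 1
        g = sol.genes[0]
        assert g.merged and g.exons == frozenset({1, 2, 3, 4})
        assert g.completeness == pytest.approx(1.0)

    def test_overlapping_exon_sets_stay_copies(self):
        gms = [
            _gm("A", "c1", "+", {1: (1, 90), 2: (200, 290), 3: (400, 490)}, 20.0),
            _gm("A", "c2", "+", {3: (1, 90), 4: (200, 290)}, 18.0),
        ]
        inst = build_assignment_instance(gms)
        sol = merge_split_genes(solve_assignment(inst), inst)
        assert len(sol.genes) == 2
        assert all(not g.merged for g in sol.genes)

    def test_gap_in_union_prevents_merge(self):
        gms = [
            _gm("A", "c1", "+", {1: (1, 90)}, 10.0),
            _gm("A", "c2", "+", {3: (1, 90)}, 10.0),  # exon 2 missing
        ]
        inst = build_assignment_instance(gms)
        sol = merge_split_genes(solve_assignment(inst), inst)
        assert len(sol.genes) == 2
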