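"""Paralog-to-contig assignment: pick conflict-free gene models of maximal score.

Candidate gene models compete for genomic loci; two candidates conflict when
they overlap on the same contig and strand.  The solver selects a
conflict-free subset of maximal total bit score, with each paralog limited to
``max_copies`` loci per connected conflict component, either exactly (by
branch-and-bound over each component) or greedily.  Loci of one paralog that
jointly cover a gapless exon range on different contigs are merged afterwards
into a single reported (split) gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx

from .genome_search import GeneModelCandidate

__all__ = [
    "Candidate",
    "AssignmentInstance",
    "ReportedGene",
    "AssignmentSolution",
    "build_assignment_instance",
    "solve_assignment",
    "merge_split_genes",
    "validate_solution",
    "InstanceTooLargeError",
]

DEFAULT_EXACT_LIMIT = 25


class InstanceTooLargeError(ValueError):
    """Exact mode was requested beyond the configured candidate limit."""


@dataclass(frozen=True)
class Candidate:
    """One candidate gene model as seen by the solver."""

    paralog: str
    locus: str
    score: float
    exons: frozenset[int]
    #: per-(contig, strand) span of the model: (contig, strand, start, end)
    intervals: tuple[tuple[str, str, int, int], ...]
    #: the model's individual exon intervals; the conflict relation is
    #: exon-level so that interleaved gene copies do not block each other
    exon_intervals: tuple[tuple[str, str, int, int], ...] = ()
    n_query_exons: int = 0
    source: GeneModelCandidate | None = None

    @property
    def contigs(self) -> frozenset[str]:
        return frozenset(c for c, _, _, _ in self.intervals)


@dataclass
class AssignmentInstance:
    candidates: list[Candidate]
    conflicts: set[tuple[int, int]]  # index pairs, i < j

    @property
    def paralogs(self) -> list[str]:
        return sorted({c.paralog for c in self.candidates})

    def conflict_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.candidates)))
        g.add_edges_from(self.conflicts)
        return g


def _overlaps(a: Candidate, b: Candidate) -> bool:
    ia = a.exon_intervals or a.intervals
    ib = b.exon_intervals or b.intervals
    for ca, sa, lo_a, hi_a in ia:
        for cb, sb, lo_b, hi_b in ib:
            if ca == cb and sa == sb and lo_a <= hi_b and lo_b <= hi_a:
                return True
    return False


def build_assignment_instance(
    candidates: list[GeneModelCandidate],
) -> AssignmentInstance:
    """Wrap gene-model candidates and compute the pairwise conflict relation.

    Candidates are ordered canonically (paralog, first contig, start) and get
    locus ids ``L001..``; a conflict is >=1 nt of overlap on the same contig
    and strand.
    """
    wrapped = []
    for gm in candidates:
        spans = gm.contig_spans()
        wrapped.append((gm, spans))
    wrapped.sort(
        key=lambda t: (
            t[0].paralog,
            t[1][0][0] if t[1] else "",
            t[1][0][2] if t[1] else 0,
        )
    )
    cands = []
    for i, (gm, spans) in enumerate(wrapped):
        n_q = max(
            int(round(len(gm.exon_indices) / gm.completeness))
            if gm.completeness
            else 0,
            max(gm.exon_indices, default=0),
        )
        cands.append(
            Candidate(
                paralog=gm.paralog,
                locus=f"L{i + 1:03d}",
                score=gm.total_score,
                exons=gm.exon_indices,
                intervals=tuple(spans),
                exon_intervals=tuple(
                    (h.contig_id, h.strand, h.start, h.end) for h in gm.hits
                ),
                n_query_exons=n_q,
                source=gm,
            )
        )
    conflicts = set()
    for i in range(len(cands)):
        for j in range(i + 1, len(cands)):
            if _overlaps(cands[i], cands[j]):
                conflicts.add((i, j))
    return AssignmentInstance(cands, conflicts)


@dataclass(frozen=True)
class ReportedGene:
    """A reported gene: one locus, or several merged loci of a split gene."""

    paralog: str
    loci: tuple[str, ...]
    exons: frozenset[int]
    score: float
    completeness: float
    merged: bool = False
    candidates: tuple[Candidate, ...] = ()


@dataclass
class AssignmentSolution:
    chosen_indices: tuple[int, ...]
    instance: AssignmentInstance
    total_score: float
    certificate: str  # 'optimal' | 'heuristic'
    genes: list[ReportedGene] = field(default_factory=list)

    @property
    def chosen(self) -> dict[str, list[str]]:
        """Map paralog -> chosen loci (>1 entry: split gene or extra copy)."""
        out: dict[str, list[str]] = {}
        for g in self.genes:
            out.setdefault(g.paralog, []).extend(g.loci)
        return out


def _component_exact(
    cands: list[Candidate],
    idxs: list[int],
    conflicts: set[tuple[int, int]],
    max_copies: int,
) -> tuple[float, tuple[int, ...]]:
    """Branch-and-bound over one conflict component (canonical order)."""
    order = sorted(idxs, key=lambda i: (cands[i].paralog, cands[i].locus))
    suffix = [0.0] * (len(order) + 1)
    for k in range(len(order) - 1, -1, -1):
        suffix[k] = suffix[k + 1] + max(cands[order[k]].score, 0.0)
    conflict = lambda i, j: (min(i, j), max(i, j)) in conflicts
    best_score = 0.0
    best_set: tuple[int, ...] = ()

    def _dfs(k: int, chosen: list[int], score: float, copies: dict[str, int]):
        nonlocal best_score, best_set
        if score + suffix[k] <= best_score and k > 0:
            return  # cannot strictly improve
        if k == len(order):
            if score > best_score:
                best_score = score
                best_set = tuple(chosen)
            return
        i = order[k]
        c = cands[i]
        # include
        if copies.get(c.paralog, 0) < max_copies and all(
            not conflict(i, j) for j in chosen
        ):
            copies[c.paralog] = copies.get(c.paralog, 0) + 1
            chosen.append(i)
            _dfs(k + 1, chosen, score + c.score, copies)
            chosen.pop()
            copies[c.paralog] -= 1
        # exclude
        _dfs(k + 1, chosen, score, copies)

    _dfs(0, [], 0.0, {})
    return best_score, best_set


def solve_assignment(
    inst: AssignmentInstance,
    mode: str = "exact",
    max_copies: int = 1,
    exact_limit: int = DEFAULT_EXACT_LIMIT,
    fallback_to_greedy: bool = False,
) -> AssignmentSolution:
    """Select a conflict-free candidate subset of maximal total score.

    Exact mode solves each connected conflict component by branch-and-bound
    (guaranteed optimum); greedy mode takes candidates by descending score,
    skipping conflicts and exhausted per-component paralog budgets.
    """
    if mode not in ("exact", "greedy"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(inst.candidates)
    if mode == "exact" and n > exact_limit:
        if not fallback_to_greedy:
            raise InstanceTooLargeError(
                f"{n} candidates exceed the exact-mode limit {exact_limit}"
            )
        mode = "greedy"
    graph = inst.conflict_graph()
    comp_of = {}
    for ci, comp in enumerate(nx.connected_components(graph)):
        for i in comp:
            comp_of[i] = ci
    chosen: list[int] = []
    if mode == "exact":
        total = 0.0
        for comp in nx.connected_components(graph):
            s, picked = _component_exact(
                inst.candidates, sorted(comp), inst.conflicts, max_copies
            )
            total += s
            chosen.extend(picked)
        certificate = "optimal"
    else:
        order = sorted(
            range(n),
            key=lambda i: (
                -inst.candidates[i].score,
                inst.candidates[i].paralog,
                inst.candidates[i].locus,
            ),
        )
        copies: dict[tuple[int, str], int] = {}
        for i in order:
            c = inst.candidates[i]
            key = (comp_of[i], c.paralog)
            if copies.get(key, 0) >= max_copies:
                continue
            if any(
                (min(i, j), max(i, j)) in inst.conflicts for j in chosen
            ):
                continue
            chosen.append(i)
            copies[key] = copies.get(key, 0) + 1
        total = sum(inst.candidates[i].score for i in chosen)
        certificate = "heuristic"
    chosen.sort(
        key=lambda i: (inst.candidates[i].paralog, inst.candidates[i].locus)
    )
    genes = [
        ReportedGene(
            paralog=inst.candidates[i].paralog,
            loci=(inst.candidates[i].locus,),
            exons=inst.candidates[i].exons,
            score=inst.candidates[i].score,
            completeness=(
                len(inst.candidates[i].exons) / inst.candidates[i].n_query_exons
                if inst.candidates[i].n_query_exons
                else 0.0
            ),
            candidates=(inst.candidates[i],),
        )
        for i in chosen
    ]
    sol = AssignmentSolution(tuple(chosen), inst, float(total), certificate, genes)
    validate_solution(sol, inst)
    return sol


def validate_solution(sol: AssignmentSolution, inst: AssignmentInstance) -> None:
    """Machine-check feasibility: no conflicts, unique loci, consistent score."""
    chosen = sol.chosen_indices
    for a in range(len(chosen)):
        for b in range(a + 1, len(chosen)):
            i, j = min(chosen[a], chosen[b]), max(chosen[a], chosen[b])
            if (i, j) in inst.conflicts:
                raise AssertionError(f"chosen candidates {i} and {j} conflict")
    loci = [inst.candidates[i].locus for i in chosen]
    if len(loci) != len(set(loci)):
        raise AssertionError("a locus serves two candidates")
    total = sum(inst.candidates[i].score for i in chosen)
    if abs(total - sol.total_score) > 1e-9:
        raise AssertionError("total_score does not match chosen candidates")


def _gapless_union(groups: list[frozenset[int]]) -> bool:
    union: set[int] = set()
    for g in groups:
        if union & g:
            return False
        union |= g
    return union == set(range(min(union), max(union) + 1)) if union else False


def merge_split_genes(
    sol: AssignmentSolution, inst: AssignmentInstance
) -> AssignmentSolution:
    """Merge same-paralog loci that complement each other across contigs.

    Loci of one paralog on disjoint contig sets whose exon-index sets are
    disjoint and jointly gapless (their union is a consecutive run) are
    reported as a single merged gene; overlapping exon sets stay separate
    (extra copies).
    """
    by_paralog: dict[str, list[ReportedGene]] = {}
    for g in sol.genes:
        by_paralog.setdefault(g.paralog, []).append(g)
    merged_genes: list[ReportedGene] = []
    for paralog in sorted(by_paralog):
        genes = sorted(by_paralog[paralog], key=lambda g: min(g.exons, default=0))
        used = [False] * len(genes)
        for i, g in enumerate(genes):
            if used[i]:
                continue
            group = [g]
            used[i] = True
            for j in range(i + 1, len(genes)):
                if used[j]:
                    continue
                h = genes[j]
                cand_group = group + [h]
                contig_sets = [
                    frozenset(
                        c for cc in gg.candidates for c in cc.contigs
                    )
                    for gg in cand_group
                ]
                all_disjoint = all(
                    not (contig_sets[a] & contig_sets[b])
                    for a in range(len(cand_group))
                    for b in range(a + 1, len(cand_group))
                )
                exon_sets = [gg.exons for gg in cand_group]
                disjoint_exons = all(
                    not (exon_sets[a] & exon_sets[b])
                    for a in range(len(cand_group))
                    for b in range(a + 1, len(cand_group))
                )
                if all_disjoint and disjoint_exons:
                    group.append(h)
                    used[j] = True
            if len(group) > 1 and _gapless_union([g.exons for g in group]):
                exons = frozenset().union(*(g.exons for g in group))
                n_q = max(
                    (c.n_query_exons for g in group for c in g.candidates),
                    default=0,
                )
                merged_genes.append(
                    ReportedGene(
                        paralog=paralog,
                        loci=tuple(l for g in group for l in g.loci),
                        exons=exons,
                        score=sum(g.score for g in group),
                        completeness=len(exons) / n_q if n_q else 0.0,
                        merged=True,
                        candidates=tuple(c for g in group for c in g.candidates),
                    )
                )
            else:
                merged_genes.extend(group)
    merged_genes.sort(key=lambda g: (g.paralog, g.loci))
    return replace(sol, genes=merged_genes)
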