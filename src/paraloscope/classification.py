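"""Filter, align and classify recovered sequences with internal gene trees.

Recovered peptides pass a length filter, are aligned by an internal
progressive aligner (k-mer guide tree, profile-profile merges with affine
gaps), placed in a neighbor-joining tree with optional column-resampling
bootstrap, and classified into subfamilies by their position relative to
labelled reference leaves.  Near-identical copies can be collapsed for
copy-number statistics.  An externally computed Newick tree can be imported
in place of the internal one (:func:`read_gene_tree`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from ._aln import (
    N_AA,
    blosum62_cached,
    encode_peptide,
    gotoh_align,
    pairwise_identity,
)

__all__ = [
    "RecoveredSequence",
    "MultipleAlignment",
    "length_filter",
    "progressive_align",
    "protein_distance_matrix",
    "neighbor_joining_tree",
    "bootstrap_support",
    "classify_by_tree",
    "dedup_near_identical",
    "read_gene_tree",
]

#: distance assigned when the p-distance correction diverges (p >= 0.85)
MAX_PROTEIN_DISTANCE = 5.0


@dataclass(frozen=True)
class RecoveredSequence:
    """One recovered gene: identity, peptide and bookkeeping for filtering."""

    id: str
    taxon: str
    peptide: str
    nt_length: int
    paralog_guess: str = ""
    completeness: float = 0.0


def length_filter(
    seqs: list[RecoveredSequence], min_len: int = 100, unit: str = "nt"
) -> list[RecoveredSequence]:
    """Keep sequences strictly longer than ``min_len`` (default >100 nt).

    ``unit`` selects nucleotide length (default) or residue count ('aa').
    """
    if unit not in ("nt", "aa"):
        raise ValueError("unit must be 'nt' or 'aa'")
    if unit == "nt":
        return [s for s in seqs if s.nt_length > min_len]
    return [s for s in seqs if len(s.peptide) > min_len]


@dataclass
class MultipleAlignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("one id per row required")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows must have equal length")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def column_sample(self, cols: np.ndarray) -> "MultipleAlignment":
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return MultipleAlignment(list(self.ids), rows)


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if len(a) < k or len(b) < k:
        return 1.0
    ca = Counter(a[i: i + k] for i in range(len(a) - k + 1))
    cb = Counter(b[i: i + k] for i in range(len(b) - k + 1))
    common = sum((ca & cb).values())
    return 1.0 - common / (min(len(a), len(b)) - k + 1)


def _profile_freqs(rows: list[str]) -> np.ndarray:
    """(width, 20) residue frequency profile; gaps and X contribute nothing."""
    width = len(rows[0])
    F = np.zeros((width, N_AA))
    for r in rows:
        enc = encode_peptide(r)
        for i, ch in enumerate(r):
            if ch != "-" and enc[i] < N_AA:
                F[i, enc[i]] += 1
    return F / len(rows)


def _merge(
    A: MultipleAlignment,
    B: MultipleAlignment,
    gap_open: float,
    gap_extend: float,
) -> MultipleAlignment:
    S = blosum62_cached()[:N_AA, :N_AA]
    Fa = _profile_freqs(A.rows)
    Fb = _profile_freqs(B.rows)
    sim = Fa @ S @ Fb.T
    _, pi, pj = gotoh_align(sim, gap_open, gap_extend)
    rows = []
    for r in A.rows:
        rows.append("".join(r[i] if i >= 0 else "-" for i in pi))
    for r in B.rows:
        rows.append("".join(r[j] if j >= 0 else "-" for j in pj))
    return MultipleAlignment(A.ids + B.ids, rows)


def progressive_align(
    seqs: list[tuple[str, str]],
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> MultipleAlignment:
    """Progressive multiple alignment (k-mer guide tree, profile merges).

    Pairwise k-mer distances feed a UPGMA guide tree; alignments are merged
    bottom-up with affine-gap profile-profile dynamic programming.  Removing
    all gaps from any output row restores the corresponding input sequence.
    """
    if len(seqs) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    ids = [i for i, _ in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("sequence ids must be unique")
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _kmer_distance(seqs[i][1], seqs[j][1])
    Z = linkage(squareform(D, checks=False), method="average")
    nodes: dict[int, MultipleAlignment] = {
        i: MultipleAlignment([seqs[i][0]], [seqs[i][1]]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(Z):
        nodes[n + step] = _merge(
            nodes.pop(int(a)), nodes.pop(int(b)), gap_open, gap_extend
        )
    msa = nodes[2 * n - 2]
    order = {sid: k for k, sid in enumerate(ids)}
    pairs = sorted(zip(msa.ids, msa.rows), key=lambda t: order[t[0]])
    return MultipleAlignment([p[0] for p in pairs], [p[1] for p in pairs])


def protein_distance_matrix(
    msa: MultipleAlignment, max_distance: float = MAX_PROTEIN_DISTANCE
) -> np.ndarray:
    """Corrected pairwise distances ``-ln(1 - p - p^2/5)`` from an alignment.

    p is the proportion of differing residues over columns where both rows
    are ungapped; p >= 0.85 (or no shared columns) maps to ``max_distance``.
    """
    n = len(msa.rows)
    enc = [encode_peptide(r.replace("-", "?")) for r in msa.rows]
    gap = [np.array([c == "-" for c in r]) for r in msa.rows]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gap[i] & ~gap[j]
            m = int(both.sum())
            if m == 0:
                d = max_distance
            else:
                p = float((enc[i][both] != enc[j][both]).sum()) / m
                arg = 1.0 - p - p * p / 5.0
                d = max_distance if p >= 0.85 or arg <= 0 else -np.log(arg)
            D[i, j] = D[j, i] = min(d, max_distance)
    return D


def neighbor_joining_tree(
    distances: np.ndarray, labels: list[str]
) -> dendropy.Tree:
    """Classic neighbor joining; returns an unrooted dendropy tree.

    Negative branch lengths are clamped to 0 with the deficit moved to the
    sister branch.
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or not np.allclose(
        np.diag(D), 0
    ):
        raise ValueError("distance matrix must be square, symmetric, zero-diagonal")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if len(labels) != n:
        raise ValueError("one label per row required")
    taxa = dendropy.TaxonNamespace(labels)
    nodes = []
    for lbl in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lbl))
        nodes.append(node)
    active = list(range(n))
    D = D.copy()
    next_nodes = {i: nodes[i] for i in range(n)}
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for bj in range(ai + 1, m):
                i, j = active[ai], active[bj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        ni, nj = next_nodes[i], next_nodes[j]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = max(li, 0.0)
        nj.edge.length = max(lj, 0.0)
        # distances to the new node
        new_row = {}
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        active.remove(i)
        active.remove(j)
        u = i  # reuse slot i for the new node
        for k, d in new_row.items():
            D[u, k] = D[k, u] = d
        active.append(u)
        next_nodes[u] = parent
    # join the final three nodes at an unresolved root
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = dendropy.Node()
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        node = next_nodes[idx]
        root.add_child(node)
        node.edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def _bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as the canonical (smaller/lexicographic) side."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(
            (side, other), key=lambda s: (len(s), tuple(sorted(s)))
        )
        out.add(canon)
    return out


def bootstrap_support(
    msa: MultipleAlignment,
    n_reps: int,
    seed: int,
    max_distance: float = MAX_PROTEIN_DISTANCE,
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """NJ tree from ``msa`` with column-resampling bootstrap supports (%).

    With ``n_reps == 0`` the tree is returned without supports.  Supports are
    attached to internal nodes as labels and returned as a bipartition map.
    """
    if n_reps < 0:
        raise ValueError("n_reps must be >= 0")
    tree = neighbor_joining_tree(protein_distance_matrix(msa, max_distance), msa.ids)
    if n_reps == 0:
        return tree, {}
    rng = np.random.default_rng(seed)
    counts: Counter = Counter()
    for _ in range(n_reps):
        cols = rng.integers(0, msa.width, size=msa.width)
        rep = msa.column_sample(cols)
        rep_tree = neighbor_joining_tree(
            protein_distance_matrix(rep, max_distance), rep.ids
        )
        counts.update(_bipartitions(rep_tree))
    leaves = frozenset(msa.ids)
    supports: dict[frozenset[str], float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min((side, other), key=lambda s: (len(s), tuple(sorted(s))))
        pct = 100.0 * counts[canon] / n_reps
        supports[canon] = pct
        node.label = f"{pct:.0f}"
    return tree, supports


def _walk_up_label(
    work: dendropy.Tree, references: dict[str, str]
) -> dict[str, str]:
    out: dict[str, str] = {}
    for leaf in work.leaf_node_iter():
        lbl = leaf.taxon.label
        if lbl in references:
            continue
        node = leaf.parent_node
        label = "unclassified"
        while node is not None:
            clade_refs = {
                references[l.taxon.label]
                for l in node.leaf_iter()
                if l.taxon.label in references
            }
            if clade_refs:
                label = clade_refs.pop() if len(clade_refs) == 1 else "unclassified"
                break
            node = node.parent_node
        out[lbl] = label
    return out


def classify_by_tree(
    tree: dendropy.Tree,
    references: dict[str, str],
    outgroup: str | None = None,
) -> dict[str, str]:
    """Label each query leaf by the smallest clade with pure reference content.

    ``references`` maps reference leaf labels to subfamily names.  The
    (unrooted) tree is rooted on a reference outgroup edge and every query
    leaf gets the subfamily of the references in its smallest
    reference-containing ancestral clade, or 'unclassified' if that clade
    mixes subfamilies.  Because the reference chosen as outgroup cannot vote
    for its own subfamily under its rooting, every reference edge is tried in
    turn (or just ``outgroup`` when given) and a leaf is labelled only if all
    rootings that resolve it agree.
    """
    if not references:
        raise ValueError("at least one reference leaf required")
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    missing = set(references) - labels
    if missing:
        raise ValueError(f"reference leaves not in tree: {sorted(missing)}")
    outgroups = [outgroup] if outgroup else sorted(references)
    votes: dict[str, set[str]] = {}
    for og in outgroups:
        work = tree.clone(depth=1)
        og_node = next(
            l for l in work.leaf_node_iter() if l.taxon.label == og
        )
        if og_node.edge.length is None:
            og_node.edge.length = 0.0
        work.reroot_at_edge(og_node.edge, update_bipartitions=False)
        for lbl, lab in _walk_up_label(work, references).items():
            votes.setdefault(lbl, set()).add(lab)
    out: dict[str, str] = {}
    for lbl, labs in votes.items():
        resolved = labs - {"unclassified"}
        out[lbl] = resolved.pop() if len(resolved) == 1 else "unclassified"
    return out


def dedup_near_identical(
    seqs: list[tuple[str, str]], identity_threshold: float = 0.99
) -> tuple[list[str], dict[str, str]]:
    """Collapse near-identical sequences by single-linkage identity clustering.

    Identity is matches over alignment columns of a global alignment; the
    longest member (ties: lexicographically smallest id) represents each
    cluster.  Returns (representative ids, id -> representative map).
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(i for i, _ in seqs)
    by_id = dict(seqs)
    ids = [i for i, _ in seqs]
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            if (
                pairwise_identity(by_id[ids[a]], by_id[ids[b]])
                >= identity_threshold
            ):
                g.add_edge(ids[a], ids[b])
    reps: list[str] = []
    cluster_map: dict[str, str] = {}
    for comp in nx.connected_components(g):
        rep = sorted(comp, key=lambda i: (-len(by_id[i]), i))[0]
        reps.append(rep)
        for i in comp:
            cluster_map[i] = rep
    reps.sort(key=lambda r: ids.index(r))
    return reps, cluster_map


def read_gene_tree(path: str) -> dendropy.Tree:
    """Import an externally computed Newick gene tree (ML hook)."""
    return dendropy.Tree.get(path=path, schema="newick")
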