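"""Synthetic gene-family benchmarks with complete ground truth.

Emulates the study conditions of a multi-genome receptor-family survey:
a species sample (ultrametric Yule tree), a gene family evolving on it by
duplication and loss, multi-exon gene structure with canonical GT..AG splice
sites whose positions and phases are conserved within each subfamily, sequence
divergence growing with tree distance, and assembly fragmentation that can
split a gene across contigs.  Every emitted genome carries a truth annotation
so that downstream search, assignment and classification can be scored
exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

import dendropy
import numpy as np

from ._aln import AMINO_ACIDS, BACKGROUND, blosum62_cached, encode_peptide

__all__ = [
    "SimulationConfig",
    "GeneNode",
    "GeneFamilyHistory",
    "GeneSequence",
    "SyntheticGenome",
    "TruthExon",
    "TruthGene",
    "TruthAnnotation",
    "SimBundle",
    "simulate_species_tree",
    "evolve_gene_family",
    "mutate_gene_sequences",
    "emit_fragmented_assembly",
    "simulate",
    "taxa_by_patristic_distance",
]

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    Rates are events per gene lineage per unit of tree time (the species tree
    has unit height); ``subst_scale`` converts tree time into expected amino
    acid substitutions per site; ``fragmentation`` is the expected number of
    assembly breakpoints per 100 kb.
    """

    n_taxa: int = 8
    root_genes: int = 6
    dup_rate: float = 0.2
    loss_rate: float = 0.1
    subst_scale: float = 0.3
    exon_count_range: tuple[int, int] = (3, 6)
    fragmentation: float = 2.0
    seed: int = 0
    protein_length_range: tuple[int, int] = (150, 250)
    intron_length_range: tuple[int, int] = (60, 2000)
    spacer_length_range: tuple[int, int] = (300, 900)

    def validate(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if self.root_genes < 1:
            raise ValueError("root_genes must be >= 1")
        for name in ("dup_rate", "loss_rate", "subst_scale", "fragmentation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.exon_count_range[0] < 1:
            raise ValueError("exon_count_range minimum must be >= 1")


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Derive per-stage integer seeds (< 2**31) from one master seed."""
    state = np.random.SeedSequence(int(seed)).generate_state(n)
    return [int(s % (2**31)) for s in state]


# ---------------------------------------------------------------------------
# species tree


def simulate_species_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Simulate a rooted ultrametric pure-birth (Yule) tree of unit height.

    Leaves are labelled ``T01 .. Tnn`` deterministically from the seed.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    rng = np.random.default_rng(seed)
    labels = [f"T{i + 1:02d}" for i in range(n_taxa)]
    if n_taxa == 1:
        newick = f"({labels[0]}:1.0):0.0;"
        return dendropy.Tree.get(data=newick, schema="newick")

    # forward Yule: split a random active lineage at exponential waiting times
    class _N:
        __slots__ = ("t", "children", "label")

        def __init__(self, t):
            self.t = t
            self.children: list[_N] = []
            self.label = None

    root = _N(0.0)
    active = [root]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(int(rng.integers(len(active))))
        # the root splits at time 0; later nodes split at their event time
        node.t = 0.0 if node is root else t
        for _ in range(2):
            child = _N(t)
            node.children.append(child)
            active.append(child)
    height = t + rng.exponential(1.0 / n_taxa)
    order = iter(labels)

    def _newick(node: _N, parent_t: float) -> str:
        if not node.children:
            bl = (height - parent_t) / height
            return f"{next(order)}:{bl:.10f}"
        split_t = node.t
        inner = ",".join(_newick(c, split_t) for c in node.children)
        bl = (split_t - parent_t) / height
        return f"({inner}):{bl:.10f}"

    newick = _newick(root, root.t) + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return tree


def tree_height(tree: dendropy.Tree) -> float:
    return max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())


def taxa_by_patristic_distance(tree: dendropy.Tree, from_taxon: str) -> list[str]:
    """Taxon labels ordered by patristic distance from ``from_taxon``.

    Ties are broken lexicographically; ``from_taxon`` itself comes first.
    """
    pdm = tree.phylogenetic_distance_matrix()
    ns = {t.label: t for t in tree.taxon_namespace}
    if from_taxon not in ns:
        raise KeyError(f"unknown taxon {from_taxon!r}")
    src = ns[from_taxon]
    pairs = []
    for label, tax in ns.items():
        d = 0.0 if tax is src else pdm.patristic_distance(src, tax)
        pairs.append((d, label))
    pairs.sort()
    return [label for _, label in pairs]


# ---------------------------------------------------------------------------
# gene family evolution


@dataclass
class GeneNode:
    """Node of a gene tree embedded in the species tree."""

    kind: str  # root | speciation | duplication | loss | leaf
    time: float  # depth in species-tree time units
    subfamily: str
    taxon: str | None = None
    gene_id: str | None = None
    children: list["GeneNode"] = field(default_factory=list)

    def leaf_iter(self):
        stack = [self]
        while stack:
            node = stack.pop()
            if node.kind == "leaf":
                yield node
            stack.extend(reversed(node.children))


@dataclass
class GeneFamilyHistory:
    species_tree: dendropy.Tree
    roots: list[GeneNode]
    events: list[tuple[str, str, float]]  # (species branch label, type, time)
    leaf_genes: dict[str, list[tuple[str, str]]]  # taxon -> [(gene_id, subfamily)]

    @property
    def subfamilies(self) -> list[str]:
        return [r.subfamily for r in self.roots]


def _branch_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label or f"internal@{id(node)}"


def _label_internal(tree: dendropy.Tree) -> None:
    i = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and not node.label:
            i += 1
            node.label = f"N{i}"


def evolve_gene_family(
    tree: dendropy.Tree,
    dup_rate: float,
    loss_rate: float,
    root_genes: int,
    seed: int,
) -> GeneFamilyHistory:
    """Evolve ``root_genes`` gene lineages along the species tree.

    Each lineage experiences a linear birth-death process (duplication rate
    ``dup_rate``, loss rate ``loss_rate``) on every species-tree branch and is
    copied into both daughter lineages at speciations.  Each surviving leaf
    gene is labelled with its subfamily of origin (its root gene).
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    if root_genes < 1:
        raise ValueError("root_genes must be >= 1")
    rng = np.random.default_rng(seed)
    _label_internal(tree)
    total = dup_rate + loss_rate
    events: list[tuple[str, str, float]] = []
    leaf_genes: dict[str, list[tuple[str, str]]] = {
        leaf.taxon.label: [] for leaf in tree.leaf_node_iter()
    }
    counters: dict[tuple[str, str], int] = {}

    def _at_species_node(parent_gene: GeneNode, sp_node: dendropy.Node, t: float):
        if sp_node.is_leaf():
            taxon = sp_node.taxon.label
            key = (taxon, parent_gene.subfamily)
            counters[key] = counters.get(key, 0) + 1
            gid = f"{parent_gene.subfamily}|{taxon}|{counters[key]}"
            node = GeneNode("leaf", t, parent_gene.subfamily, taxon=taxon, gene_id=gid)
            parent_gene.children.append(node)
            leaf_genes[taxon].append((gid, parent_gene.subfamily))
        else:
            node = GeneNode("speciation", t, parent_gene.subfamily)
            parent_gene.children.append(node)
            for child in sp_node.child_nodes():
                _along_edge(node, child, t)

    def _along_edge(parent_gene: GeneNode, sp_node: dendropy.Node, t0: float):
        """One gene lineage traversing the edge that leads to ``sp_node``."""
        t_edge = sp_node.edge.length or 0.0
        elapsed = 0.0
        holder = parent_gene
        while True:
            wait = rng.exponential(1.0 / total) if total > 0 else np.inf
            if wait >= t_edge - elapsed:
                _at_species_node(holder, sp_node, t0 + t_edge)
                return
            elapsed += wait
            now = t0 + elapsed
            if rng.random() < (dup_rate / total if total else 0.0):
                events.append((_branch_label(sp_node), "duplication", now))
                node = GeneNode("duplication", now, holder.subfamily)
                holder.children.append(node)
                # one of the two daughters continues in this loop, the other
                # recursively
                _along_edge_from(node, sp_node, now, t_edge - elapsed)
                holder = node
            else:
                events.append((_branch_label(sp_node), "loss", now))
                holder.children.append(GeneNode("loss", now, holder.subfamily))
                return

    def _along_edge_from(
        parent_gene: GeneNode, sp_node: dendropy.Node, t0: float, t_remaining: float
    ):
        elapsed = 0.0
        holder = parent_gene
        while True:
            wait = rng.exponential(1.0 / total) if total > 0 else np.inf
            if wait >= t_remaining - elapsed:
                _at_species_node(holder, sp_node, t0 + (t_remaining - 0.0))
                return
            elapsed += wait
            now = t0 + elapsed
            if rng.random() < (dup_rate / total if total else 0.0):
                events.append((_branch_label(sp_node), "duplication", now))
                node = GeneNode("duplication", now, holder.subfamily)
                holder.children.append(node)
                _along_edge_from(node, sp_node, now, t_remaining - elapsed)
                holder = node
            else:
                events.append((_branch_label(sp_node), "loss", now))
                holder.children.append(GeneNode("loss", now, holder.subfamily))
                return

    roots = []
    for g in range(root_genes):
        sf = f"SF{g + 1}"
        root = GeneNode("root", 0.0, sf)
        sp_root = tree.seed_node
        if sp_root.is_leaf():
            _at_species_node(root, sp_root, 0.0)
        else:
            for child in sp_root.child_nodes():
                _along_edge(root, child, 0.0)
        roots.append(root)
    return GeneFamilyHistory(tree, roots, events, leaf_genes)


# ---------------------------------------------------------------------------
# sequences


@dataclass
class GeneSequence:
    """A realised leaf gene: peptide, exon decomposition and nucleotide parts."""

    gene_id: str
    taxon: str
    subfamily: str
    protein: str
    exon_peptides: list[str]
    exon_nt: list[str]
    introns: list[str]  # intron i sits after exon i; len = n_exons - 1
    phases: list[int]  # phase of intron i (0/1/2)

    @property
    def cds(self) -> str:
        return "".join(self.exon_nt)

    @property
    def pre_mrna(self) -> str:
        parts = []
        for i, ex in enumerate(self.exon_nt):
            parts.append(ex)
            if i < len(self.introns):
                parts.append(self.introns[i])
        return "".join(parts)

    @property
    def exon_count(self) -> int:
        return len(self.exon_nt)


def _substitution_kernel() -> np.ndarray:
    """Per-event replacement distribution: P(a->b) ∝ q_b * 2**S62(a,b), b != a."""
    S = blosum62_cached()[:20, :20]
    P = BACKGROUND[None, :] * np.exp2(S)
    np.fill_diagonal(P, 0.0)
    P /= P.sum(axis=1, keepdims=True)
    return P


def _mutate_peptide(
    pep: np.ndarray, branch_len: float, rng: np.random.Generator, kernel: np.ndarray
) -> np.ndarray:
    out = pep.copy()
    n_events = rng.poisson(branch_len, size=out.size)
    for site in np.nonzero(n_events)[0]:
        for _ in range(n_events[site]):
            out[site] = rng.choice(20, p=kernel[out[site]])
    return out


def _split_peptide_by_cuts(protein: str, cuts_nt: list[int]) -> list[str]:
    """Assign each residue to the exon in which its codon starts."""
    bounds = [0] + list(cuts_nt) + [3 * len(protein)]
    peps = []
    for e in range(len(bounds) - 1):
        lo, hi = bounds[e], bounds[e + 1]
        residues = [protein[r] for r in range(len(protein)) if lo <= 3 * r < hi]
        peps.append("".join(residues))
    return peps


def mutate_gene_sequences(
    history: GeneFamilyHistory,
    subst_scale: float,
    seed: int,
    exon_count_range: tuple[int, int] = (3, 6),
    protein_length_range: tuple[int, int] = (150, 250),
    intron_length_range: tuple[int, int] = (60, 2000),
) -> dict[str, GeneSequence]:
    """Realise sequences for every surviving leaf gene of ``history``.

    A root peptide and a conserved exon-intron blueprint (nucleotide cut
    points, hence intron phases) are drawn per subfamily; peptides then evolve
    along the gene tree under a BLOSUM62-derived replacement kernel with
    ``subst_scale * branch_length`` expected substitutions per site.  There is
    no indel process, so exon counts and lengths are conserved exactly within
    a subfamily.  Leaf peptides are back-translated with uniform codon choice
    and introns (GT .. polypyrimidine AG) are inserted at the blueprint cuts.
    """
    if not history.roots:
        raise ValueError("empty gene family history")
    rng = np.random.default_rng(seed)
    kernel = _substitution_kernel()
    min_exon_nt = 45
    out: dict[str, GeneSequence] = {}
    for root in history.roots:
        # subfamily blueprint
        length = int(rng.integers(*protein_length_range))
        aa_idx = rng.choice(20, size=length, p=BACKGROUND)
        aa_idx[0] = AMINO_ACIDS.index("M")
        k = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
        n_cuts = k - 1
        cds_len = 3 * length
        cuts: list[int] = []
        if n_cuts > 0:
            for _ in range(200):
                cand = sorted(rng.integers(min_exon_nt, cds_len - min_exon_nt, n_cuts))
                gaps = np.diff([0] + list(cand) + [cds_len])
                if (gaps >= min_exon_nt).all() and len(set(cand)) == n_cuts:
                    cuts = [int(c) for c in cand]
                    break
            else:  # evenly spaced fallback
                cuts = [round(cds_len * (i + 1) / k) for i in range(n_cuts)]
        phases = [c % 3 for c in cuts]

        # evolve peptides down the gene tree
        def _walk(gnode: GeneNode, pep: np.ndarray, t_parent: float):
            for child in gnode.children:
                bl = max(child.time - t_parent, 0.0) * subst_scale
                cp = _mutate_peptide(pep, bl, rng, kernel)
                if child.kind == "leaf":
                    protein = "".join(AMINO_ACIDS[i] for i in cp)
                    exon_nt = _backtranslate(protein, cuts, rng)
                    introns = [
                        _make_intron(rng, intron_length_range, phase)
                        for phase in phases
                    ]
                    out[child.gene_id] = GeneSequence(
                        gene_id=child.gene_id,
                        taxon=child.taxon,
                        subfamily=child.subfamily,
                        protein=protein,
                        exon_peptides=_split_peptide_by_cuts(protein, cuts),
                        exon_nt=exon_nt,
                        introns=introns,
                        phases=list(phases),
                    )
                elif child.kind != "loss":
                    _walk(child, cp, child.time)

        _walk(root, aa_idx, 0.0)
    return out


def _backtranslate(protein: str, cuts_nt: list[int], rng: np.random.Generator) -> list[str]:
    cds = "".join(
        _CODONS[a][int(rng.integers(len(_CODONS[a])))] for a in protein
    )
    bounds = [0] + list(cuts_nt) + [len(cds)]
    return [cds[bounds[i]: bounds[i + 1]] for i in range(len(bounds) - 1)]


def _make_intron(
    rng: np.random.Generator, length_range: tuple[int, int], phase: int
) -> str:
    lo, hi = length_range
    length = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    length = max(length, lo)
    # GT .. random .. 15 nt polypyrimidine tract .. AG; the pyrimidine tract
    # keeps chance AG dinucleotides away from the acceptor, as in real introns
    mid_len = max(length - 4 - 15, 0)
    mid = "".join(rng.choice(list("ACGT"), size=mid_len))
    tract = "".join(rng.choice(list("CT"), size=min(15, length - 4)))
    return "GT" + mid + tract + "AG"


# ---------------------------------------------------------------------------
# assembly


@dataclass
class SyntheticGenome:
    contigs: list[tuple[str, str]]
    provenance: dict[str, tuple[str, str, tuple[int, int]]]

    def contig_dict(self) -> dict[str, str]:
        return dict(self.contigs)


@dataclass(frozen=True)
class TruthExon:
    contig: str
    start: int  # 1-based inclusive, forward strand
    end: int
    exon_number: int


@dataclass
class TruthGene:
    taxon: str
    gene_id: str
    subfamily: str
    strand: str
    phases: list[int]
    exons: list[TruthExon]

    @property
    def contigs(self) -> list[str]:
        seen: list[str] = []
        for e in self.exons:
            if e.contig not in seen:
                seen.append(e.contig)
        return seen

    @property
    def is_split(self) -> bool:
        return len(self.contigs) > 1


@dataclass
class TruthAnnotation:
    records: list[TruthGene]

    def by_taxon(self, taxon: str) -> list[TruthGene]:
        return [r for r in self.records if r.taxon == taxon]


def _gene_exon_intervals_local(gene: GeneSequence) -> list[tuple[int, int]]:
    """Exon intervals within the pre-mRNA, 1-based inclusive."""
    ivals = []
    pos = 0
    for i, ex in enumerate(gene.exon_nt):
        ivals.append((pos + 1, pos + len(ex)))
        pos += len(ex)
        if i < len(gene.introns):
            pos += len(gene.introns[i])
    return ivals


def emit_fragmented_assembly(
    genes: Iterable[GeneSequence],
    fragmentation: float,
    seed: int,
    spacer_length_range: tuple[int, int] = (300, 900),
) -> tuple[SyntheticGenome, TruthAnnotation]:
    """Place genes on per-taxon chromosomes and apply Poisson fragmentation.

    Genes are separated by random intergenic spacers and placed on either
    strand.  Breakpoints are drawn uniformly at a rate of ``fragmentation``
    expected breaks per 100 kb but are never placed inside an exon (nor within
    3 nt of its ends), so truth phases and exon intervals stay well defined.
    Truth records are rewritten to post-fragmentation contig coordinates.
    """
    if fragmentation < 0:
        raise ValueError("fragmentation must be >= 0")
    rng = np.random.default_rng(seed)
    by_taxon: dict[str, list[GeneSequence]] = {}
    for g in genes:
        by_taxon.setdefault(g.taxon, []).append(g)
    contigs: list[tuple[str, str]] = []
    provenance: dict[str, tuple[str, str, tuple[int, int]]] = {}
    records: list[TruthGene] = []
    for taxon in sorted(by_taxon):
        glist = sorted(by_taxon[taxon], key=lambda g: g.gene_id)
        chrom_parts: list[str] = []
        pos = 0
        placed: list[TruthGene] = []
        for gene in glist:
            spacer_len = int(rng.integers(*spacer_length_range))
            chrom_parts.append("".join(rng.choice(list("ACGT"), size=spacer_len)))
            pos += spacer_len
            strand = "+" if rng.random() < 0.5 else "-"
            pre = gene.pre_mrna
            local = _gene_exon_intervals_local(gene)
            L = len(pre)
            if strand == "+":
                seq = pre
                exons = [
                    TruthExon("", pos + s, pos + e, i + 1)
                    for i, (s, e) in enumerate(local)
                ]
            else:
                seq = revcomp(pre)
                exons = [
                    TruthExon("", pos + (L - e + 1), pos + (L - s + 1), i + 1)
                    for i, (s, e) in enumerate(local)
                ]
            chrom_parts.append(seq)
            pos += L
            placed.append(
                TruthGene(taxon, gene.gene_id, gene.subfamily, strand,
                          list(gene.phases), exons)
            )
        tail = int(rng.integers(*spacer_length_range))
        chrom_parts.append("".join(rng.choice(list("ACGT"), size=tail)))
        pos += tail
        chrom = "".join(chrom_parts)
        chrom_name = f"{taxon}_chr1"

        # breakpoints: cut between p and p+1 (1-based p in [1, L-1])
        L = len(chrom)
        n_break = rng.poisson(fragmentation * L / 1e5)
        forbidden = []
        for tg in placed:
            for ex in tg.exons:
                forbidden.append((ex.start - 3, ex.end + 3))
        breaks: set[int] = set()
        for _ in range(n_break):
            for _attempt in range(50):
                p = int(rng.integers(1, L))
                ok = all(not (lo - 1 <= p <= hi) for lo, hi in forbidden)
                if ok and p not in breaks:
                    breaks.add(p)
                    break
        bounds = [0] + sorted(breaks) + [L]
        for ci in range(len(bounds) - 1):
            lo, hi = bounds[ci], bounds[ci + 1]
            name = f"{taxon}_ctg{ci + 1}"
            contigs.append((name, chrom[lo:hi]))
            provenance[name] = (taxon, chrom_name, (lo + 1, hi))
        # rewrite truth coordinates to contigs
        starts = bounds[:-1]
        for tg in placed:
            new_exons = []
            for ex in tg.exons:
                ci = int(np.searchsorted(starts, ex.start - 1, side="right")) - 1
                lo = starts[ci]
                new_exons.append(
                    TruthExon(f"{taxon}_ctg{ci + 1}", ex.start - lo, ex.end - lo,
                              ex.exon_number)
                )
            tg.exons = new_exons
            records.append(tg)
    return SyntheticGenome(contigs, provenance), TruthAnnotation(records)


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SimBundle:
    config: SimulationConfig
    species_tree: dendropy.Tree
    history: GeneFamilyHistory
    sequences: dict[str, GeneSequence]
    genome: SyntheticGenome
    truth: TruthAnnotation


def simulate(config: SimulationConfig) -> SimBundle:
    """Run the full generator: tree -> family -> sequences -> assembly."""
    config.validate()
    s_tree, s_fam, s_seq, s_asm = _stage_seeds(config.seed, 4)
    tree = simulate_species_tree(config.n_taxa, s_tree)
    history = evolve_gene_family(
        tree, config.dup_rate, config.loss_rate, config.root_genes, s_fam
    )
    sequences = mutate_gene_sequences(
        history,
        config.subst_scale,
        s_seq,
        exon_count_range=config.exon_count_range,
        protein_length_range=config.protein_length_range,
        intron_length_range=config.intron_length_range,
    )
    genome, truth = emit_fragmented_assembly(
        sequences.values(),
        config.fragmentation,
        s_asm,
        spacer_length_range=config.spacer_length_range,
    )
    return SimBundle(config, tree, history, sequences, genome, truth)
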