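"""Copy-number matrices, Dollo gain/loss reconstruction and summary statistics.

Classified genes are tabulated into a taxon-or-genus x subfamily copy-number
matrix (the heat-map input), each subfamily's phylogenetic profile is
explained under Dollo parsimony (a single gain at the MRCA of the carriers
plus a minimal set of subtree losses), and per-class copy-number and
genomes-per-genus statistics are summarised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PresenceMatrix",
    "EventReconstruction",
    "build_presence_matrix",
    "dollo_gain_loss",
    "copy_number_stats",
    "genome_count_stats",
    "plot_heatmap",
]


@dataclass
class PresenceMatrix:
    """Rows: taxa or genera; columns: subfamilies; cells: copy counts."""

    table: pd.DataFrame  # integer copy counts
    genomes_per_row: dict[str, int] = field(default_factory=dict)
    collapse: str = "taxon"

    def __post_init__(self):
        if (self.table.values < 0).any():
            raise ValueError("copy counts must be >= 0")
        if self.table.index.has_duplicates or self.table.columns.has_duplicates:
            raise ValueError("row/column labels must be unique")

    @property
    def total(self) -> int:
        return int(self.table.values.sum())


def build_presence_matrix(
    classified: pd.DataFrame,
    taxonomy: dict[str, str] | None = None,
    collapse: str = "taxon",
    genus_mode: str = "sum",
) -> PresenceMatrix:
    """Tabulate classified genes into a copy-number matrix.

    ``classified`` needs columns ``taxon`` and ``subfamily`` (one row per
    classified, deduplicated gene).  With ``collapse='genus'`` member taxa of
    a genus are combined by ``genus_mode`` ('sum' of copies, or 'max' over
    member genomes — both readings of a multi-genome genus cell are
    supported).
    """
    if collapse not in ("taxon", "genus"):
        raise ValueError("collapse must be 'taxon' or 'genus'")
    if genus_mode not in ("sum", "max"):
        raise ValueError("genus_mode must be 'sum' or 'max'")
    df = classified[["taxon", "subfamily"]].copy()
    per_taxon = (
        df.groupby(["taxon", "subfamily"]).size().unstack(fill_value=0).astype(int)
    )
    per_taxon = per_taxon.sort_index(axis=0).sort_index(axis=1)
    if collapse == "taxon":
        return PresenceMatrix(
            per_taxon, {t: 1 for t in per_taxon.index}, collapse="taxon"
        )
    if taxonomy is None:
        raise ValueError("taxonomy required for genus collapse")
    unmapped = set(per_taxon.index) - set(taxonomy)
    if unmapped:
        raise KeyError(f"taxa missing from taxonomy: {sorted(unmapped)}")
    genus = per_taxon.index.map(taxonomy)
    grouped = per_taxon.groupby(genus)
    table = (grouped.sum() if genus_mode == "sum" else grouped.max()).astype(int)
    table = table.sort_index(axis=0)
    genomes = {g: int(n) for g, n in per_taxon.groupby(genus).size().items()}
    return PresenceMatrix(table, genomes, collapse="genus")


@dataclass
class EventReconstruction:
    """Dollo explanation of one subfamily's phylogenetic profile."""

    subfamily: str
    gain_branch: str | None  # label of the node whose stem carries the gain
    loss_branches: list[str]
    n_losses: int
    all_absent: bool = False

    @property
    def n_gains(self) -> int:
        return 0 if self.all_absent else 1


def _node_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label or "root"


def _ensure_internal_labels(tree: dendropy.Tree) -> None:
    """Give unlabeled internal nodes stable preorder labels (in place)."""
    i = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and not node.label:
            i += 1
            node.label = f"N{i}"


def dollo_gain_loss(
    tree: dendropy.Tree, present: set[str], subfamily: str = ""
) -> EventReconstruction:
    """Single-gain / minimum-loss reconstruction of a presence pattern.

    The gain is placed on the stem of the MRCA of all presence leaves; the
    losses are the maximal subtrees below the gain containing no presence
    leaf.  An all-absent pattern is returned flagged, with zero events.
    """
    _ensure_internal_labels(tree)
    leaf_labels = {l.taxon.label for l in tree.leaf_node_iter()}
    unknown = present - leaf_labels
    if unknown:
        raise ValueError(f"presence taxa not in tree: {sorted(unknown)}")
    if not present:
        return EventReconstruction(subfamily, None, [], 0, all_absent=True)
    taxa = [
        t for t in tree.taxon_namespace if t.label in present
    ]
    if len(present) == 1:
        gain = next(
            l for l in tree.leaf_node_iter() if l.taxon.label in present
        )
    else:
        gain = tree.mrca(taxa=taxa)
    losses: list[str] = []

    def _has_present(node) -> bool:
        return any(l.taxon.label in present for l in node.leaf_iter())

    def _walk(node):
        for child in node.child_nodes():
            if _has_present(child):
                _walk(child)
            else:
                losses.append(_node_label(child))

    _walk(gain)
    return EventReconstruction(
        subfamily, _node_label(gain), sorted(losses), len(losses)
    )


def replay_events(
    tree: dendropy.Tree, rec: EventReconstruction
) -> set[str]:
    """Re-simulate a reconstruction into the leaf presence pattern it implies."""
    if rec.all_absent:
        return set()
    gain_node = None
    for node in tree.preorder_node_iter():
        if _node_label(node) == rec.gain_branch:
            gain_node = node
            break
    if gain_node is None:
        raise ValueError(f"gain branch {rec.gain_branch!r} not found")
    lost = set(rec.loss_branches)
    present: set[str] = set()

    def _walk(node):
        if _node_label(node) in lost:
            return
        if node.is_leaf():
            present.add(node.taxon.label)
        for child in node.child_nodes():
            _walk(child)

    _walk(gain_node)
    return present


def copy_number_stats(
    matrix: PresenceMatrix, class_grouping: dict[str, str] | None = None
) -> pd.DataFrame:
    """Mean copies per genome for each receptor class, to one decimal.

    ``class_grouping`` maps subfamily -> class (default: each subfamily its
    own class).  The mean is the arithmetic mean over genomes (matrix rows
    weighted by genomes per row) of the summed class columns.
    """
    if matrix.table.empty:
        raise ValueError("empty presence matrix")
    grouping = class_grouping or {c: c for c in matrix.table.columns}
    n_genomes = sum(matrix.genomes_per_row.get(r, 1) for r in matrix.table.index)
    rows = []
    for cls in sorted(set(grouping.values())):
        cols = [c for c in matrix.table.columns if grouping.get(c) == cls]
        total = float(matrix.table[cols].values.sum())
        rows.append(
            {
                "class": cls,
                "total_copies": int(total),
                "mean_per_genome": round(total / n_genomes, 1),
            }
        )
    return pd.DataFrame(rows).set_index("class")


def genome_count_stats(counts: dict[str, int]) -> dict[str, float]:
    """Range / median / mean of genomes per genus from a genus -> count map."""
    if not counts:
        raise ValueError("no genus counts")
    values = np.array(sorted(counts.values()))
    return {
        "n_genera": int(values.size),
        "n_genomes": int(values.sum()),
        "min": int(values.min()),
        "max": int(values.max()),
        "median": float(np.median(values)),
        "mean": round(float(values.mean()), 1),
    }


def plot_heatmap(matrix: PresenceMatrix, path: str) -> None:
    """Write the copy-number heat map to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(
            max(4.0, 0.5 * matrix.table.shape[1] + 2),
            max(3.0, 0.3 * matrix.table.shape[0] + 1.5),
        )
    )
    im = ax.imshow(matrix.table.values, cmap="viridis", aspect="auto")
    ax.set_xticks(range(matrix.table.shape[1]), matrix.table.columns, rotation=90)
    ax.set_yticks(range(matrix.table.shape[0]), matrix.table.index)
    fig.colorbar(im, ax=ax, label="copies")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
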