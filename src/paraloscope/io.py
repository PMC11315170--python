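"""File formats: FASTA, GFF3 (1-based inclusive), Newick, TSV, YAML, JSON.

Thin wrappers over Biopython / dendropy / pandas plus the package's own GFF3
conventions (`gene_id`, `subfamily`, `exon_number`, `phase_after`
attributes).  Parse -> write -> parse is a fixed point for every format.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_search import revcomp, translate_cds
from .synthetic_data import TruthAnnotation, TruthExon, TruthGene

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "write_truth_gff3",
    "read_truth_gff3",
    "read_tsv",
    "write_tsv",
    "read_yaml",
    "write_yaml",
    "read_json",
    "write_json",
    "splice_truth_gene",
    "truth_gene_peptides",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file as (id, sequence) pairs, in file order."""
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(path: str | Path, tree: dendropy.Tree) -> None:
    tree.write(path=str(path), schema="newick")


def _fmt_attrs(**attrs) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items() if v is not None)


def write_truth_gff3(path: str | Path, truth: TruthAnnotation) -> None:
    """Write a truth annotation as GFF3 exon features (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for tg in truth.records:
        for i, ex in enumerate(tg.exons):
            phase_after = (
                tg.phases[ex.exon_number - 1]
                if ex.exon_number - 1 < len(tg.phases)
                else None
            )
            attrs = _fmt_attrs(
                gene_id=tg.gene_id,
                subfamily=tg.subfamily,
                exon_number=ex.exon_number,
                taxon=tg.taxon,
                phase_after=phase_after,
            )
            lines.append(
                "\t".join(
                    [
                        ex.contig,
                        "paraloscope",
                        "exon",
                        str(ex.start),
                        str(ex.end),
                        ".",
                        tg.strand,
                        ".",
                        attrs,
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_truth_gff3(path: str | Path) -> TruthAnnotation:
    genes: dict[str, dict] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
        contig, _, ftype, start, end, _, strand, _, attr_text = fields
        if ftype != "exon":
            continue
        attrs = _parse_attrs(attr_text)
        try:
            gid = attrs["gene_id"]
            exon_number = int(attrs["exon_number"])
        except KeyError as exc:
            raise ValueError(f"{path}:{lineno}: missing attribute {exc}")
        rec = genes.setdefault(
            gid,
            {
                "taxon": attrs.get("taxon", ""),
                "subfamily": attrs.get("subfamily", ""),
                "strand": strand,
                "exons": [],
                "phases": {},
            },
        )
        rec["exons"].append(TruthExon(contig, int(start), int(end), exon_number))
        if "phase_after" in attrs:
            rec["phases"][exon_number] = int(attrs["phase_after"])
    records = []
    for gid in sorted(genes):
        rec = genes[gid]
        exons = sorted(rec["exons"], key=lambda e: e.exon_number)
        phases = [rec["phases"][i] for i in sorted(rec["phases"])]
        records.append(
            TruthGene(rec["taxon"], gid, rec["subfamily"], rec["strand"], phases, exons)
        )
    return TruthAnnotation(records)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(path: str | Path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_yaml(path: str | Path):
    return yaml.safe_load(Path(path).read_text())


def write_yaml(path: str | Path, obj) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def splice_truth_gene(contigs: dict[str, str], tg: TruthGene) -> str:
    """Extract and splice the coding sequence of a truth gene.

    Exons are taken in gene order (``exon_number``); minus-strand exons are
    reverse-complemented from their forward-strand truth intervals.
    """
    parts = []
    for ex in sorted(tg.exons, key=lambda e: e.exon_number):
        seq = contigs[ex.contig][ex.start - 1: ex.end]
        parts.append(seq if tg.strand == "+" else revcomp(seq))
    return "".join(parts)


def truth_gene_peptides(
    contigs: dict[str, str], tg: TruthGene
) -> tuple[str, list[str]]:
    """Translate a truth gene and split the protein into exon peptides.

    A residue whose codon straddles an intron belongs to the upstream exon
    (the codon-start rule used throughout the package).
    """
    cds = splice_truth_gene(contigs, tg)
    protein = translate_cds(cds)
    exons = sorted(tg.exons, key=lambda e: e.exon_number)
    lengths = [e.end - e.start + 1 for e in exons]
    bounds = [0]
    for ln in lengths:
        bounds.append(bounds[-1] + ln)
    peps = []
    for e in range(len(exons)):
        lo, hi = bounds[e], bounds[e + 1]
        peps.append(
            "".join(
                protein[r] for r in range(len(protein)) if lo <= 3 * r < hi
            )
        )
    return protein, peps
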