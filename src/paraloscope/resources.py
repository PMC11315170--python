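"""Packaged reference data: published survey totals and the genome inventory.

The receptor-family totals reported for the 159-genome nematode survey (1100
NPR, 375 FRPR and 82 C09F12.3 sequences, 1557 in total) are carried as
constants; :func:`synthetic_supplement_fasta` expands them into a synthetic
stand-in for the survey's supplementary multi-FASTA (random peptides, real
per-family record counts) for exercising FASTA handling at scale.  The
per-genus genome inventory is likewise a synthetic reconstruction consistent
with the published summary statistics (66 genera, 159 genomes, range 1-22,
median 1, mean 2.4).
"""

from __future__ import annotations

from importlib import resources as _ir

import numpy as np
import pandas as pd

from ._aln import AMINO_ACIDS, BACKGROUND

__all__ = [
    "FAMILY_TOTALS",
    "TOTAL_SEQUENCES",
    "load_genome_inventory",
    "synthetic_supplement_fasta",
]

#: published number of detected receptor sequences per family
FAMILY_TOTALS: dict[str, int] = {"NPR": 1100, "FRPR": 375, "C09F12.3": 82}
TOTAL_SEQUENCES: int = sum(FAMILY_TOTALS.values())


def load_genome_inventory() -> dict[str, int]:
    """Per-genus genome counts of the survey's genome list (synthetic copy)."""
    path = _ir.files("paraloscope.data") / "genome_inventory_synthetic.tsv"
    with _ir.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    return dict(zip(df["genus"], df["n_genomes"].astype(int)))


def synthetic_supplement_fasta(seed: int = 0, length: int = 120) -> list[tuple[str, str]]:
    """Synthetic stand-in for the survey's supplementary receptor multi-FASTA.

    One random peptide record per detected receptor, named
    ``<FAMILY>_<n>|taxon<k>``; per-family record counts equal the published
    totals.  Sequences are synthetic and carry no biological signal.
    """
    rng = np.random.default_rng(seed)
    records = []
    for family in sorted(FAMILY_TOTALS):
        for i in range(FAMILY_TOTALS[family]):
            pep = "".join(
                AMINO_ACIDS[j] for j in rng.choice(20, size=length, p=BACKGROUND)
            )
            records.append((f"{family}_{i + 1}|taxon{i % 159 + 1}", pep))
    return records
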