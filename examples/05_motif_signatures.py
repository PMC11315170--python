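"""Microswitch motif diagnostics for receptor proteins.

Scans class-A GPCR activation motifs (CWxP, NPxxY, DRY), the NPY-receptor
positions D/E6.59, E45.52 and Q3.32 and the TM3/ECL2 cysteine pair, then
classifies the signature pattern.
"""

from paraloscope.motif_scan import receptor_signature_report, signature_classify
from paraloscope.reference_gpcr_synthetic import (
    REFERENCE_POSITIONS,
    REFERENCE_SEQUENCE,
)


def edit(protein, bw, new):
    pos = REFERENCE_POSITIONS[bw]
    return protein[: pos - 1] + new + protein[pos:]


# an NPR-like receptor: the canonical reference itself
npr = REFERENCE_SEQUENCE
# an FRPR-like receptor: TM7 proline lost (N->T too), TM6 W->H, no cys pair
frpr = REFERENCE_SEQUENCE
for bw, aa in (("7.49", "T"), ("7.50", "I"), ("6.48", "H"),
               ("3.25", "A"), ("45.50", "S")):
    frpr = edit(frpr, bw, aa)

for name, protein in (("NPR-like carrier", npr), ("FRPR-like carrier", frpr)):
    rep = receptor_signature_report(protein)
    print(f"{name}:")
    for motif, match in rep.motifs.items():
        print(f"  {motif:<6} {match.status:<10} observed {match.residues!r}")
    print(f"  cys pair TM3/ECL2: {rep.cys_pair}")
    print(f"  D/E6.59 {rep.npy_positions['D/E6.59']}, "
          f"E45.52 {rep.npy_positions['E45.52']}, "
          f"Q3.32 {rep.npy_positions['Q3.32']}")
    print(f"  signature class -> {signature_classify(rep)}\n")
# FRPR-type receptors lack the TM7 proline and TM6 tryptophan microswitches
# and the extracellular disulfide cysteines, which is what the rule detects.
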