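"""Synthetic annotated rhodopsin-family receptor reference.

This is a constructed (synthetic) reference protein, not a database entry:
an idealised class-A GPCR built segment by segment so that every landmark
needed for Ballesteros-Weinstein-style position transfer sits at a known
offset — the seven transmembrane helices, the ECL2 loop, the TM3 cysteine
(3.25) and ECL2 cysteine (45.50) of the conserved disulfide, the DRY (TM3),
CWxP (TM6) and NPxxY (TM7) microswitch motifs, and the ligand-binding
positions Q3.32, E45.52 and D6.59.  Spans and positions are computed from the
segment layout at import time, so sequence and annotation cannot drift apart.
"""

from __future__ import annotations

# (segment name, sequence) in N->C order.  Offsets of annotated positions
# within their segment are given alongside in _POSITIONS.
_SEGMENTS: list[tuple[str, str]] = [
    ("Nterm", "MDNATNLTEFP"),
    ("TM1", "LVILGVVFGLIGNGLVILTYIFY"),
    ("ICL1", "KRKSLR"),
    ("TM2", "NSFILSLAVADLLVGLLVMPFSL"),
    ("ECL1", "ANELMG"),
    #       C(3.25) ...... Q(3.32) ................ D R Y (3.49-3.51)
    ("TM3", "CIVTLSVQISLMGWAITHPLSFKEDRY"),
    ("ICL2", "RSPKRAK"),
    ("TM4", "AVIAVVLAVFIVSSGPLLFMND"),
    #        offset 6 = C(45.50), offset 8 = E(45.52)
    ("ECL2", "NQWPFGCMETLPGS"),
    ("TM5", "FVAYFVPLTVISVLYGAMLARL"),
    ("ICL3", "RGRERVGGSKASSRE"),
    #        offsets 17-20 = CWLP (6.47-6.50), offset 29 = D(6.59)
    ("TM6", "RTLKMTFVIVAVFIVSFCWLPFFITNIMQDV"),
    ("ECL3", "FGTF"),
    #        offsets 19-23 = NPIIY (7.49-7.53)
    ("TM7", "ELLSTVSSLAMDFLDTLAMNPIIYT"),
    ("Cterm", "GRSFRQKFKRMLS"),
]

_POSITIONS: dict[str, tuple[str, int]] = {
    "3.25": ("TM3", 0),
    "3.32": ("TM3", 7),
    "3.49": ("TM3", 24),
    "3.50": ("TM3", 25),
    "3.51": ("TM3", 26),
    "45.50": ("ECL2", 6),
    "45.52": ("ECL2", 8),
    "6.47": ("TM6", 17),
    "6.48": ("TM6", 18),
    "6.50": ("TM6", 20),
    "6.59": ("TM6", 29),
    "7.49": ("TM7", 19),
    "7.50": ("TM7", 20),
    "7.53": ("TM7", 23),
}


def _build() -> tuple[str, dict[str, tuple[int, int]], dict[str, int]]:
    seq_parts = []
    spans: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, seg in _SEGMENTS:
        spans[name] = (pos + 1, pos + len(seg))  # 1-based inclusive
        seq_parts.append(seg)
        pos += len(seg)
    sequence = "".join(seq_parts)
    positions = {}
    for bw, (seg, off) in _POSITIONS.items():
        positions[bw] = spans[seg][0] + off  # 1-based
    return sequence, spans, positions


REFERENCE_SEQUENCE, REFERENCE_SPANS, REFERENCE_POSITIONS = _build()

# sanity anchors of the layout (fail fast on accidental edits)
assert REFERENCE_SEQUENCE[REFERENCE_POSITIONS["3.50"] - 1] == "R"
assert REFERENCE_SEQUENCE[REFERENCE_POSITIONS["6.48"] - 1] == "W"
assert REFERENCE_SEQUENCE[REFERENCE_POSITIONS["7.50"] - 1] == "P"
assert REFERENCE_SEQUENCE[REFERENCE_POSITIONS["45.50"] - 1] == "C"
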