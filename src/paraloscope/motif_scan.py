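"""Rhodopsin-family microswitch motif diagnostics for receptor proteins.

Scans receptor proteins for the class-A GPCR activation motifs — CWxP (TM6),
NPxxY (TM7) and DRY/ERY (TM3) — plus the NPY-receptor-specific positions
D/E6.59, E45.52 and Q3.32 and the TM3/ECL2 cysteine pair, and classifies the
resulting signature as NPR-like, FRPR-like, hybrid or indeterminate.
Ballesteros-Weinstein positions are resolved by global alignment against a
packaged annotated (synthetic) reference receptor; if the protein cannot be
anchored, motifs are sought over the whole sequence and the report is
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._aln import pairwise_align
from .reference_gpcr_synthetic import (
    REFERENCE_POSITIONS,
    REFERENCE_SEQUENCE,
    REFERENCE_SPANS,
)

__all__ = [
    "MotifDefinition",
    "MotifMatch",
    "AnchorResult",
    "AnchoringError",
    "MotifReport",
    "DEFAULT_MOTIFS",
    "anchor_to_reference",
    "find_motif",
    "receptor_signature_report",
    "signature_classify",
]


@dataclass(frozen=True)
class MotifDefinition:
    """An ordered-residue-class motif; 'x' matches anything.

    ``known_variants`` are named alternate forms reported in the literature
    for particular paralogs (matched exactly, e.g. S/CWxW for the CWxP slot).
    """

    name: str
    pattern: tuple[str, ...]
    region: str
    known_variants: tuple[tuple[str, tuple[str, ...]], ...] = ()

    def __post_init__(self):
        if len(self.pattern) < 3:
            raise ValueError("motif patterns must have length >= 3")


DEFAULT_MOTIFS: dict[str, MotifDefinition] = {
    "CWxP": MotifDefinition(
        "CWxP",
        ("C", "W", "x", "P"),
        "TM6",
        known_variants=(("S/CWxW", ("CS", "W", "x", "W")),),
    ),
    "NPxxY": MotifDefinition("NPxxY", ("N", "P", "x", "x", "Y"), "TM7"),
    "DRY": MotifDefinition("DRY", ("DE", "R", "Y"), "TM3"),
}


@dataclass(frozen=True)
class MotifMatch:
    status: str  # canonical | variant | absent
    residues: str  # observed residues at the best candidate position
    position: int | None  # 1-based start on the protein, None if no window
    mismatches: int
    matched_positions: frozenset[int]  # pattern indices that matched
    variant_name: str | None = None


class AnchoringError(ValueError):
    """The protein could not be aligned to the reference confidently."""


@dataclass
class AnchorResult:
    windows: dict[str, tuple[int, int] | None]
    positions: dict[str, int | None]
    identity: float
    n_columns: int


def anchor_to_reference(
    protein: str,
    reference: str = REFERENCE_SEQUENCE,
    spans: dict[str, tuple[int, int]] | None = None,
    positions: dict[str, int] | None = None,
    min_identity: float = 0.30,
    min_columns: int = 100,
) -> AnchorResult:
    """Transfer reference TM windows and named positions onto ``protein``.

    A global alignment against the annotated reference maps each reference
    column to a protein position; annotated windows and Ballesteros-Weinstein
    positions are carried through the alignment.  Raises
    :class:`AnchoringError` if identity over aligned (ungapped) columns falls
    below ``min_identity`` or fewer than ``min_columns`` columns align.
    """
    spans = REFERENCE_SPANS if spans is None else spans
    positions = REFERENCE_POSITIONS if positions is None else positions
    _, ra, rp = pairwise_align(reference, protein)
    ref_to_prot: dict[int, int | None] = {}
    ri = pi = 0
    aligned = matches = 0
    for ca, cp in zip(ra, rp):
        if ca != "-" and cp != "-":
            ref_to_prot[ri] = pi
            aligned += 1
            if ca == cp:
                matches += 1
        elif ca != "-":
            ref_to_prot[ri] = None
        if ca != "-":
            ri += 1
        if cp != "-":
            pi += 1
    identity = matches / aligned if aligned else 0.0
    if aligned < min_columns or identity < min_identity:
        raise AnchoringError(
            f"anchoring failed: identity {identity:.2f} over {aligned} columns"
        )
    windows: dict[str, tuple[int, int] | None] = {}
    for region, (s, e) in spans.items():
        mapped = [
            ref_to_prot[i] for i in range(s - 1, e) if ref_to_prot.get(i) is not None
        ]
        windows[region] = (min(mapped) + 1, max(mapped) + 1) if mapped else None
    out_pos: dict[str, int | None] = {}
    for name, refpos in positions.items():
        m = ref_to_prot.get(refpos - 1)
        out_pos[name] = None if m is None else m + 1
    return AnchorResult(windows, out_pos, identity, aligned)


def _class_match(ch: str, cls: str) -> bool:
    return cls == "x" or ch in cls


def _candidates(window_seq: str, pattern: tuple[str, ...]):
    k = len(pattern)
    for start in range(len(window_seq) - k + 1):
        sub = window_seq[start: start + k]
        matched = frozenset(
            i for i, cls in enumerate(pattern) if _class_match(sub[i], cls)
        )
        mism = sum(
            1 for i, cls in enumerate(pattern)
            if cls != "x" and i not in matched
        )
        yield start, sub, matched, mism


def find_motif(
    protein: str, m: MotifDefinition, window: tuple[int, int] | None
) -> MotifMatch:
    """Locate a motif inside a window (1-based inclusive; None = no window).

    canonical: exact class match; variant: a named literature variant, or at
    most one substitution at a non-'x' position; absent otherwise.  The
    leftmost qualifying candidate wins; absent reports the best (fewest
    mismatches, leftmost) candidate so that retained residues can still be
    inspected.
    """
    if window is None:
        return MotifMatch("absent", "", None, len(m.pattern), frozenset())
    lo, hi = window
    if lo < 1 or hi > len(protein) or hi < lo:
        raise ValueError(f"window {window} outside protein of length {len(protein)}")
    seq = protein[lo - 1: hi]
    if len(seq) < len(m.pattern):
        return MotifMatch("absent", seq, lo, len(m.pattern), frozenset())
    best = None  # (mismatches, start, sub, matched)
    for start, sub, matched, mism in _candidates(seq, m.pattern):
        if mism == 0:
            return MotifMatch("canonical", sub, lo + start, 0, matched)
        if best is None or mism < best[0]:
            best = (mism, start, sub, matched)
    for vname, vpattern in m.known_variants:
        for start, sub, matched, mism in _candidates(seq, vpattern):
            if mism == 0:
                return MotifMatch(
                    "variant", sub, lo + start, 1, matched, variant_name=vname
                )
    for start, sub, matched, mism in _candidates(seq, m.pattern):
        if mism == 1:
            return MotifMatch("variant", sub, lo + start, 1, matched)
    mism, start, sub, matched = best
    return MotifMatch("absent", sub, lo + start, mism, matched)


@dataclass
class MotifReport:
    """Per-protein motif and signature summary."""

    motifs: dict[str, MotifMatch]
    position_residues: dict[str, str | None]
    npy_positions: dict[str, bool]
    cys_pair: bool
    tm6_w_residue: str | None
    tm6_p_retained: bool
    tm7_p_retained: bool
    tm7_y_retained: bool
    anchored: bool
    notes: list[str] = field(default_factory=list)


def receptor_signature_report(
    protein: str,
    motifs: dict[str, MotifDefinition] | None = None,
) -> MotifReport:
    """Evaluate all microswitch motifs and NPY-specific positions.

    Uses reference anchoring when possible; otherwise scans the whole
    sequence and flags the report as unanchored.
    """
    motifs = DEFAULT_MOTIFS if motifs is None else motifs
    notes: list[str] = []
    try:
        anchor = anchor_to_reference(protein)
        anchored = True
    except AnchoringError as exc:
        anchor = AnchorResult(
            {region: (1, len(protein)) for region in REFERENCE_SPANS},
            {name: None for name in REFERENCE_POSITIONS},
            0.0,
            0,
        )
        anchored = False
        notes.append(f"fallback to whole-sequence scan ({exc})")
    matches = {
        name: find_motif(protein, m, anchor.windows.get(m.region))
        for name, m in motifs.items()
    }

    def _residue(bw: str) -> str | None:
        pos = anchor.positions.get(bw)
        return protein[pos - 1] if pos else None

    pos_res = {bw: _residue(bw) for bw in ("6.59", "45.52", "3.32", "6.48", "6.50",
                                           "7.50", "7.53", "3.25", "45.50")}
    npy = {
        "D/E6.59": pos_res["6.59"] in ("D", "E"),
        "E45.52": pos_res["45.52"] == "E",
        "Q3.32": pos_res["3.32"] == "Q",
    }
    tm3_win = anchor.windows.get("TM3")
    ecl2_win = anchor.windows.get("ECL2")

    def _has_cys(win):
        if win is None:
            return False
        return "C" in protein[win[0] - 1: win[1]]

    cys_pair = _has_cys(tm3_win) and _has_cys(ecl2_win)
    tm6 = matches.get("CWxP")
    tm7 = matches.get("NPxxY")
    tm6_w = pos_res["6.48"]
    if tm6_w is None and tm6 and len(tm6.residues) >= 2 and tm6.position:
        tm6_w = tm6.residues[1]
    tm6_p = (
        pos_res["6.50"] == "P"
        if pos_res["6.50"] is not None
        else bool(tm6 and len(tm6.residues) >= 4 and tm6.residues[3] == "P")
    )
    tm7_p = (
        pos_res["7.50"] == "P"
        if pos_res["7.50"] is not None
        else bool(tm7 and len(tm7.residues) >= 2 and tm7.residues[1] == "P")
    )
    tm7_win = anchor.windows.get("TM7")
    tm7_y = (
        pos_res["7.53"] == "Y"
        if pos_res["7.53"] is not None
        else bool(tm7_win and "Y" in protein[tm7_win[0] - 1: tm7_win[1]])
    )
    if tm7 and tm7.status != "canonical" and tm7_y and not tm7_p:
        notes.append("FRPR-type TM7: proline lost, tyrosine retained")
    if tm6_w in ("H", "N", "Y"):
        notes.append("FRPR-type TM6: toggle tryptophan replaced by hydrophilic residue")
    return MotifReport(
        motifs=matches,
        position_residues=pos_res,
        npy_positions=npy,
        cys_pair=cys_pair,
        tm6_w_residue=tm6_w,
        tm6_p_retained=tm6_p,
        tm7_p_retained=tm7_p,
        tm7_y_retained=tm7_y,
        anchored=anchored,
        notes=notes,
    )


def signature_classify(r: MotifReport) -> str:
    """Rule-based signature class from a motif report (sequence-free).

    NPR-like: TM6 and TM7 motifs intact (canonical or conservative variant
    with the TM7 proline retained) plus the TM3/ECL2 cysteine pair.
    FRPR-like: TM7 proline lost, TM6 toggle tryptophan replaced by H/N/Y and
    no cysteine pair.  Hybrid: canonical TM7 and cysteine pair but a TM6
    motif reduced to its proline.  Anything else: indeterminate.
    """
    tm6 = r.motifs.get("CWxP")
    tm7 = r.motifs.get("NPxxY")
    if tm6 is None or tm7 is None:
        return "indeterminate"
    tm6_ok = tm6.status in ("canonical", "variant")
    tm7_ok = tm7.status == "canonical" or (
        tm7.status == "variant" and r.tm7_p_retained
    )
    if tm6_ok and tm7_ok and r.cys_pair:
        return "NPR-like"
    if (
        not r.tm7_p_retained
        and r.tm6_w_residue in ("H", "N", "Y")
        and not r.cys_pair
    ):
        return "FRPR-like"
    if (
        tm7.status == "canonical"
        and not tm6_ok
        and r.tm6_p_retained
        and r.cys_pair
    ):
        return "hybrid"
    return "indeterminate"
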