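"""Locate exon hits in contigs and chain them into gene-model candidates.

Contigs are translated in all six reading frames; every per-exon profile is
slid over every frame, windows above threshold become exon hits, hit
boundaries are snapped to canonical splice signals (AG acceptor upstream,
GT donor downstream), and collinear hits are chained by dynamic programming
into maximum-score gene-model candidates, optionally across contigs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from ._aln import AA_INDEX, N_AA
from .exon_profiles import ExonProfile, STOP_SCORE

__all__ = [
    "ContigRecord",
    "FrameTranslation",
    "ExonHit",
    "GeneModelCandidate",
    "six_frame_translate",
    "scan_for_exon_hits",
    "chain_hits_to_gene_models",
    "translate_cds",
    "DEFAULT_INTRON_BOUNDS",
    "DEFAULT_SNAP_RADIUS",
    "DEFAULT_THRESHOLD_FACTOR",
]

DEFAULT_INTRON_BOUNDS = (40, 20000)
DEFAULT_SNAP_RADIUS = 15
#: default hit threshold as a fraction of the profile's maximum score
DEFAULT_THRESHOLD_FACTOR = 0.6

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str) -> str:
    """Translate a nucleotide string codon by codon; unknown codons -> X."""
    return "".join(
        _CODON_TABLE.get(cds[i: i + 3], "X") for i in range(0, len(cds) - 2, 3)
    )


@dataclass(frozen=True)
class ContigRecord:
    id: str
    sequence: str
    taxon: str = ""

    def __post_init__(self):
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"contig {self.id}: invalid characters {bad}")


@dataclass(frozen=True)
class FrameTranslation:
    """One reading frame of a contig with its coordinate map.

    ``frame`` is 1..3; ``strand`` '+' or '-'.  Peptide position ``j``
    (0-based) maps back to a forward-strand codon interval via
    :meth:`codon_interval` (1-based inclusive).
    """

    contig_id: str
    strand: str
    frame: int
    peptide: str
    contig_length: int

    def codon_interval(self, j: int) -> tuple[int, int]:
        if self.strand == "+":
            start = self.frame + 3 * j
            return start, start + 2
        # reverse strand: positions counted on the reverse complement
        start_rc = self.frame + 3 * j
        end_rc = start_rc + 2
        return self.contig_length - end_rc + 1, self.contig_length - start_rc + 1

    def window_interval(self, offset: int, length: int) -> tuple[int, int]:
        """Forward-strand interval of a peptide window [offset, offset+length)."""
        a = self.codon_interval(offset)
        b = self.codon_interval(offset + length - 1)
        lo = min(a[0], b[0])
        hi = max(a[1], b[1])
        return lo, hi


def six_frame_translate(c: ContigRecord) -> list[FrameTranslation]:
    """All six reading frames under the standard genetic code.

    Stops render as '*', codons containing N as 'X'.
    """
    out = []
    rc = revcomp(c.sequence)
    for strand, seq in (("+", c.sequence), ("-", rc)):
        for frame in (1, 2, 3):
            pep = translate_cds(seq[frame - 1:])
            out.append(
                FrameTranslation(c.id, strand, frame, pep, len(c.sequence))
            )
    return out


@dataclass(frozen=True)
class ExonHit:
    """A profile window on a contig, with splice-aware boundaries.

    ``start``/``end`` are 1-based inclusive forward-strand coordinates after
    snapping.  ``acceptor_status``/``donor_status`` refer to the gene-oriented
    upstream/downstream boundary and are one of ``splice-snapped``,
    ``contig-end``, ``unsnapped``.
    """

    contig_id: str
    strand: str
    frame: int
    start: int
    end: int
    peptide: str
    paralog: str
    exon_index: int
    score: float
    acceptor_status: str
    donor_status: str

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


def _encode_frame_peptide(peptide: str) -> np.ndarray:
    enc = np.empty(len(peptide), dtype=np.int64)
    for j, ch in enumerate(peptide):
        enc[j] = N_AA + 1 if ch == "*" else AA_INDEX.get(ch, N_AA)
    return enc


@lru_cache(maxsize=256)
def _translated_frames(
    contig_id: str, sequence: str
) -> tuple[tuple[FrameTranslation, np.ndarray], ...]:
    """Cached six-frame translation + encoded peptides for one contig."""
    frames = six_frame_translate(ContigRecord(contig_id, sequence))
    return tuple((ft, _encode_frame_peptide(ft.peptide)) for ft in frames)


def _window_scores_encoded(profile: ExonProfile, enc: np.ndarray) -> np.ndarray:
    """Score of every profile placement along an encoded frame peptide."""
    L = profile.length
    n = enc.size
    if n < L:
        return np.empty(0)
    ext = np.concatenate(
        [profile.matrix, np.full((L, 1), STOP_SCORE)], axis=1
    )
    n_off = n - L + 1
    scores = np.zeros(n_off)
    for i in range(L):
        scores += ext[i][enc[i: i + n_off]]
    return scores


def _window_scores(profile: ExonProfile, peptide: str) -> np.ndarray:
    """Score of every profile placement along ``peptide`` (may be empty)."""
    return _window_scores_encoded(profile, _encode_frame_peptide(peptide))


def _find_signal(
    seq: str, predicted: int, lo: int, hi: int, check, radius: int
) -> tuple[int | None, bool]:
    """Locate a splice signal near a boundary (coordinates are 1-based local).

    ``predicted`` is tried first (conserved intron phase makes it the expected
    position); otherwise the nearest signal within ``radius`` wins, extension
    preferred over trimming at equal distance.  ``check(pos)`` tests the
    signal at candidate boundary ``pos``.  Returns (position or None,
    search_crossed_contig_end).
    """
    crossed = False

    def _try(pos: int) -> bool:
        nonlocal crossed
        if pos < lo or pos > hi:
            crossed = True
            return False
        return check(pos)

    if _try(predicted):
        return predicted, crossed
    for dist in range(radius + 1):
        for pos in (predicted - dist, predicted + dist):
            if pos == predicted:
                continue
            if _try(pos):
                return pos, crossed
    return None, crossed


def scan_for_exon_hits(
    profile: ExonProfile,
    contig: ContigRecord,
    min_bits: float | None = None,
    snap_radius: int = DEFAULT_SNAP_RADIUS,
    threshold_factor: float = DEFAULT_THRESHOLD_FACTOR,
) -> list[ExonHit]:
    """All above-threshold profile windows on both strands, splice-snapped.

    ``min_bits`` defaults to ``threshold_factor * profile.max_score``.
    Overlapping same-frame windows are merged to the best-scoring one.  Hit
    boundaries that correspond to an intron side of the exon are snapped to
    the phase-predicted AG/GT position (falling back to the nearest signal
    within ``snap_radius``); outer boundaries of first/last exons are left
    unsnapped.
    """
    if min_bits is None:
        min_bits = threshold_factor * profile.max_score
    if not np.isfinite(min_bits):
        raise ValueError("min_bits must be finite")
    L = profile.length
    hits: list[ExonHit] = []
    rc = revcomp(contig.sequence)
    for ft, enc in _translated_frames(contig.id, contig.sequence):
        scores = _window_scores_encoded(profile, enc)
        cand = np.nonzero(scores >= min_bits)[0]
        if cand.size == 0:
            continue
        # non-maximum suppression among overlapping windows of this frame
        order = cand[np.lexsort((cand, -scores[cand]))]
        kept: list[int] = []
        for off in order:
            if all(abs(off - k) >= L for k in kept):
                kept.append(int(off))
        local_seq = contig.sequence if ft.strand == "+" else rc
        Lc = len(local_seq)
        for off in sorted(kept):
            # strand-local 1-based interval of the codon-aligned window
            s_local = ft.frame + 3 * off
            e_local = s_local + 3 * L - 1
            acc_status = don_status = "unsnapped"
            s_new, e_new = s_local, e_local
            if profile.phase_before is not None:
                delta = (3 - profile.phase_before) % 3
                pos, crossed = _find_signal(
                    local_seq,
                    s_local - delta,
                    3,
                    Lc,
                    lambda p: local_seq[p - 3: p - 1] == "AG",
                    snap_radius,
                )
                if pos is not None:
                    s_new = pos
                    acc_status = "splice-snapped"
                else:
                    acc_status = "contig-end" if crossed else "unsnapped"
            elif s_local - snap_radius < 1:
                acc_status = "contig-end"
            if profile.phase_after is not None:
                delta = profile.phase_after
                pos, crossed = _find_signal(
                    local_seq,
                    e_local + delta,
                    1,
                    Lc - 2,
                    lambda p: local_seq[p: p + 2] == "GT",
                    snap_radius,
                )
                if pos is not None:
                    e_new = pos
                    don_status = "splice-snapped"
                else:
                    don_status = "contig-end" if crossed else "unsnapped"
            elif e_local + snap_radius > Lc:
                don_status = "contig-end"
            if ft.strand == "+":
                start, end = s_new, e_new
            else:
                start, end = Lc - e_new + 1, Lc - s_new + 1
            hits.append(
                ExonHit(
                    contig_id=contig.id,
                    strand=ft.strand,
                    frame=ft.frame,
                    start=start,
                    end=end,
                    peptide=ft.peptide[off: off + L],
                    paralog=profile.paralog,
                    exon_index=profile.exon_index,
                    score=float(scores[off]),
                    acceptor_status=acc_status,
                    donor_status=don_status,
                )
            )
    hits.sort(key=lambda h: (h.contig_id, h.start, h.end, h.strand, h.frame))
    return hits


@dataclass
class GeneModelCandidate:
    """An ordered chain of exon hits, possibly spanning several contigs."""

    paralog: str
    hits: list[ExonHit]
    total_score: float
    completeness: float

    @property
    def exon_indices(self) -> frozenset[int]:
        return frozenset(h.exon_index for h in self.hits)

    @property
    def contigs(self) -> tuple[str, ...]:
        seen: list[str] = []
        for h in self.hits:
            if h.contig_id not in seen:
                seen.append(h.contig_id)
        return tuple(seen)

    def contig_spans(self) -> list[tuple[str, str, int, int]]:
        spans: dict[tuple[str, str], list[int]] = {}
        for h in self.hits:
            spans.setdefault((h.contig_id, h.strand), []).extend([h.start, h.end])
        return [
            (c, s, min(v), max(v)) for (c, s), v in sorted(spans.items())
        ]


def _chain_gap(a: ExonHit, b: ExonHit) -> int | None:
    """Genomic gap between consecutive chain members, None across contigs."""
    if a.contig_id != b.contig_id:
        return None
    if a.strand == "+":
        return b.start - a.end - 1
    return a.start - b.end - 1


def _compatible(
    a: ExonHit, b: ExonHit, intron_bounds: tuple[int, int], allow_split: bool
) -> bool:
    """May hit ``b`` directly follow hit ``a`` in a chain (a.exon < b.exon)?"""
    if a.exon_index >= b.exon_index:
        return False
    if a.contig_id != b.contig_id:
        return allow_split
    if a.strand != b.strand:
        return False
    lo, hi = intron_bounds
    gap = _chain_gap(a, b)
    return lo <= gap <= hi


def chain_hits_to_gene_models(
    hits: list[ExonHit],
    intron_bounds: tuple[int, int] = DEFAULT_INTRON_BOUNDS,
    allow_split: bool = True,
    n_query_exons: int | None = None,
    gap_penalty: float = 0.0,
) -> list[GeneModelCandidate]:
    """Partition hits into maximum-score collinear chains (gene candidates).

    Chains are found by dynamic programming over hits ordered by exon index;
    consecutive chain members must be compatible (increasing exon index, same
    strand and an intron-length gap within bounds on one contig; different
    contigs allowed only when ``allow_split``).  Candidates are extracted
    greedily by total score; each hit serves in at most one candidate.

    ``gap_penalty`` (bits per gap nucleotide, default 0) is a weak
    compactness prior on the chain objective: with tandem gene copies, the
    exons of one copy and those of its neighbour can both satisfy the intron
    bounds, and near-ties are then resolved toward the compact (single-copy)
    chain.  Reported ``total_score`` remains the plain sum of hit scores.
    """
    if not hits:
        return []
    paralogs = {h.paralog for h in hits}
    if len(paralogs) > 1:
        raise ValueError(f"hits must share one paralog, got {sorted(paralogs)}")
    seen: dict[tuple, float] = {}
    for h in hits:
        key = (h.contig_id, h.strand, h.start, h.end, h.exon_index)
        if key in seen and seen[key] != h.score:
            raise ValueError(f"conflicting duplicate hits at {key}")
        seen[key] = h.score
    if n_query_exons is None:
        n_query_exons = max(h.exon_index for h in hits)
    pool = sorted(hits, key=lambda h: (h.exon_index, h.contig_id, h.start, h.end))
    candidates: list[GeneModelCandidate] = []
    while pool:
        n = len(pool)
        best = [h.score for h in pool]
        prev = [-1] * n
        for i in range(n):
            for j in range(i):
                if _compatible(pool[j], pool[i], intron_bounds, allow_split):
                    gap = _chain_gap(pool[j], pool[i])
                    pen = gap_penalty * gap if gap is not None else 0.0
                    cand = best[j] + pool[i].score - pen
                    if cand > best[i]:
                        best[i] = cand
                        prev[i] = j
        top = int(np.argmax(best))
        chain = []
        k = top
        while k != -1:
            chain.append(pool[k])
            k = prev[k]
        chain.reverse()
        candidates.append(
            GeneModelCandidate(
                paralog=chain[0].paralog,
                hits=chain,
                total_score=float(sum(h.score for h in chain)),
                completeness=len({h.exon_index for h in chain}) / n_query_exons,
            )
        )
        used = set(id(h) for h in chain)
        pool = [h for h in pool if id(h) not in used]
    candidates.sort(key=lambda c: -c.total_score)
    return candidates
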