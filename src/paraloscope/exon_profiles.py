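"""Per-exon position-specific scoring profiles and their iterative update.

Each query paralog is decomposed into its exons; every exon gets its own
ungapped position-specific log-odds matrix (bits).  Searches accept orthologous
exons, whose peptides are folded back into the training alignment so that the
profile tracks the family as the search proceeds from close to distant
species — the engine behind subclass-specific iterative homology search.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ._aln import AA_INDEX, AMINO_ACIDS, BACKGROUND, N_AA

__all__ = [
    "QueryParalog",
    "ExonProfile",
    "ProfileSet",
    "AcceptedExon",
    "split_query_into_exons",
    "build_exon_profile",
    "score_peptide",
    "iterative_update",
    "build_profile_set",
]

#: score of a stop codon ('*') against any profile column, in bits
STOP_SCORE = -10.0
_GAP = "-"


@dataclass(frozen=True)
class QueryParalog:
    """A query protein with its exon decomposition.

    ``exon_boundaries`` are 1-based inclusive residue intervals partitioning
    the protein, in gene order; a residue whose codon is split by an intron
    belongs to the upstream exon.  ``phases`` holds the phase (0/1/2) of the
    intron following each exon (length ``n_exons - 1``).
    """

    name: str
    protein: str
    exon_boundaries: tuple[tuple[int, int], ...]
    phases: tuple[int, ...]
    group: int = 1

    def __post_init__(self):
        bounds = self.exon_boundaries
        if not bounds:
            raise ValueError("at least one exon required")
        if len(self.phases) != len(bounds) - 1:
            raise ValueError("need one phase per intron")
        prev_end = 0
        for s, e in bounds:
            if s != prev_end + 1 or e < s:
                raise ValueError(
                    f"exon boundaries must partition the protein, got {bounds}"
                )
            prev_end = e
        if prev_end != len(self.protein):
            raise ValueError("exon boundaries must cover the whole protein")

    @property
    def n_exons(self) -> int:
        return len(self.exon_boundaries)


def split_query_into_exons(q: QueryParalog) -> list[str]:
    """Exon peptides in gene order (concatenation equals the protein)."""
    return [q.protein[s - 1: e] for s, e in q.exon_boundaries]


@dataclass
class ExonProfile:
    """Ungapped log-odds profile (bits) for one exon of one paralog."""

    paralog: str
    exon_index: int  # 1-based ordinal within the query gene
    n_exons: int
    matrix: np.ndarray  # (L, 21): 20 residues + neutral X column
    background: np.ndarray
    pseudocount: float
    n_sequences: int
    training: list[str] = field(default_factory=list)  # aligned training rows
    #: indices of the matrix columns within the training alignment (columns
    #: exceeding the gap limit are dropped from the matrix but kept here)
    columns: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    phase_before: int | None = None  # phase of the upstream intron
    phase_after: int | None = None  # phase of the downstream intron

    def __post_init__(self):
        if self.matrix.shape[0] < 1:
            raise ValueError("profile needs at least one column")
        if not np.isfinite(self.matrix).all():
            raise ValueError("profile scores must be finite")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def max_score(self) -> float:
        """Maximum attainable window score (sum of column maxima)."""
        return float(self.matrix[:, :N_AA].max(axis=1).sum())

    @property
    def min_column_scores(self) -> np.ndarray:
        return self.matrix[:, :N_AA].min(axis=1)

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.matrix[:, :N_AA].argmax(axis=1))

    @property
    def is_first(self) -> bool:
        return self.exon_index == 1

    @property
    def is_last(self) -> bool:
        return self.exon_index == self.n_exons


def build_exon_profile(
    aligned_peptides: list[str],
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
    *,
    paralog: str = "",
    exon_index: int = 1,
    n_exons: int = 1,
    phase_before: int | None = None,
    phase_after: int | None = None,
    max_gap_fraction: float = 0.5,
) -> ExonProfile:
    """Build a log-odds profile from equal-length (gap-containing) peptides.

    Column scores are ``log2((count(a) + pc*bg(a)) / ((n + pc) * bg(a)))``;
    columns with more than ``max_gap_fraction`` gaps are dropped.  The X
    column scores 0 bits (background expectation).
    """
    if not aligned_peptides:
        raise ValueError("at least one training peptide required")
    widths = {len(p) for p in aligned_peptides}
    if len(widths) != 1:
        raise ValueError("training peptides must have equal aligned length")
    bg = BACKGROUND if background is None else np.asarray(background, dtype=float)
    if bg.shape != (N_AA,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be a 20-vector summing to 1")
    n = len(aligned_peptides)
    width = widths.pop()
    counts = np.zeros((width, N_AA))
    gaps = np.zeros(width)
    for pep in aligned_peptides:
        for i, ch in enumerate(pep):
            if ch == _GAP:
                gaps[i] += 1
            else:
                idx = AA_INDEX.get(ch)
                if idx is not None:
                    counts[i, idx] += 1
    keep = gaps <= max_gap_fraction * n
    if not keep.any():
        raise ValueError("all columns exceeded the gap fraction limit")
    counts = counts[keep]
    scores = np.log2((counts + pseudocount * bg) / ((n + pseudocount) * bg))
    matrix = np.zeros((scores.shape[0], N_AA + 1))
    matrix[:, :N_AA] = scores
    return ExonProfile(
        paralog=paralog,
        exon_index=exon_index,
        n_exons=n_exons,
        matrix=matrix,
        background=bg,
        pseudocount=pseudocount,
        n_sequences=n,
        training=list(aligned_peptides),
        columns=np.nonzero(keep)[0],
        phase_before=phase_before,
        phase_after=phase_after,
    )


def _lookup(profile: ExonProfile, peptide: str) -> np.ndarray:
    """Per (column, peptide position) score table, honouring X and stops."""
    L = profile.length
    tab = np.empty((L, len(peptide)))
    m = profile.matrix
    for j, ch in enumerate(peptide):
        if ch == "*":
            tab[:, j] = STOP_SCORE
        else:
            tab[:, j] = m[:, AA_INDEX.get(ch, N_AA)]
    return tab


def score_peptide(profile: ExonProfile, peptide: str) -> tuple[float, int]:
    """Best ungapped placement of the profile against ``peptide``.

    Returns ``(score_bits, offset)``.  For peptides at least as long as the
    profile, ``offset`` is the 0-based peptide position where the profile
    starts.  Shorter peptides are slid inside the profile, uncovered columns
    are charged their minimum column score, and the (negative or zero) offset
    is the position of the peptide within the profile, negated.
    """
    if len(peptide) < 1:
        raise ValueError("peptide must be non-empty")
    L = profile.length
    tab = _lookup(profile, peptide)
    n = len(peptide)
    if n >= L:
        n_off = n - L + 1
        scores = np.zeros(n_off)
        for i in range(L):
            scores += tab[i, i: i + n_off]
        best = int(scores.argmax())
        return float(scores[best]), best
    mins = profile.min_column_scores
    best_score, best_shift = -np.inf, 0
    for shift in range(L - n + 1):
        covered = float(sum(tab[shift + j, j] for j in range(n)))
        pad = float(mins.sum() - mins[shift: shift + n].sum())
        s = covered + pad
        if s > best_score:
            best_score, best_shift = s, shift
    return best_score, -best_shift


@dataclass(frozen=True)
class AcceptedExon:
    """A classified exon hit fed back into the profiles."""

    species: str
    paralog: str
    exon_index: int
    peptide: str


@dataclass
class ProfileSet:
    """All per-exon profiles of a query set, plus the update history."""

    profiles: dict[tuple[str, int], ExonProfile]
    training_log: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        by_paralog: dict[str, set[int]] = {}
        for (paralog, idx) in self.profiles:
            by_paralog.setdefault(paralog, set()).add(idx)
        for paralog, idxs in by_paralog.items():
            if idxs != set(range(1, max(idxs) + 1)):
                raise ValueError(f"exon indices of {paralog} are not 1..k: {idxs}")

    @property
    def paralogs(self) -> list[str]:
        return sorted({p for p, _ in self.profiles})

    def exons_of(self, paralog: str) -> list[ExonProfile]:
        idxs = sorted(i for p, i in self.profiles if p == paralog)
        return [self.profiles[(paralog, i)] for i in idxs]


def build_profile_set(
    queries: list[QueryParalog],
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
) -> ProfileSet:
    """Initial single-sequence profiles: one per exon of each query paralog."""
    profiles: dict[tuple[str, int], ExonProfile] = {}
    for q in queries:
        peps = split_query_into_exons(q)
        for i, pep in enumerate(peps, start=1):
            profiles[(q.name, i)] = build_exon_profile(
                [pep],
                background=background,
                pseudocount=pseudocount,
                paralog=q.name,
                exon_index=i,
                n_exons=q.n_exons,
                phase_before=q.phases[i - 2] if i > 1 else None,
                phase_after=q.phases[i - 1] if i < q.n_exons else None,
            )
    return ProfileSet(profiles)


def _align_into(profile: ExonProfile, peptide: str) -> str:
    """Place ``peptide`` into the training alignment frame as a new row."""
    L = profile.length
    width = len(profile.training[0]) if profile.training else L
    _, offset = score_peptide(profile, peptide)
    row = [_GAP] * width
    if len(peptide) >= L:
        for i in range(L):
            row[profile.columns[i]] = peptide[offset + i]
    else:
        shift = -offset
        for j, ch in enumerate(peptide):
            row[profile.columns[shift + j]] = ch
    return "".join(row)


def iterative_update(
    ps: ProfileSet,
    accepted: list[AcceptedExon],
    species_order: list[str],
) -> ProfileSet:
    """Fold accepted exon peptides into their profiles, species by species.

    Processing strictly follows ``species_order`` (taxa sorted by patristic
    distance from the query taxon); within a species, hits are applied in a
    deterministic (paralog, exon, peptide) order.  Returns a new ProfileSet;
    the input is not modified.
    """
    known = set(ps.profiles)
    for hit in accepted:
        if (hit.paralog, hit.exon_index) not in known:
            raise KeyError(
                f"accepted hit references unknown profile "
                f"({hit.paralog}, exon {hit.exon_index})"
            )
        if hit.species not in species_order:
            raise KeyError(f"accepted hit from unknown species {hit.species!r}")
    new = ProfileSet(copy.deepcopy(ps.profiles), list(ps.training_log))
    for species in species_order:
        batch = sorted(
            (h for h in accepted if h.species == species),
            key=lambda h: (h.paralog, h.exon_index, h.peptide),
        )
        for hit in batch:
            prof = new.profiles[(hit.paralog, hit.exon_index)]
            row = _align_into(prof, hit.peptide)
            new.profiles[(hit.paralog, hit.exon_index)] = build_exon_profile(
                prof.training + [row],
                background=prof.background,
                pseudocount=prof.pseudocount,
                paralog=prof.paralog,
                exon_index=prof.exon_index,
                n_exons=prof.n_exons,
                phase_before=prof.phase_before,
                phase_after=prof.phase_after,
            )
        new.training_log.append((species, len(batch)))
    return new
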