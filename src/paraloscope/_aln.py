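"""Shared alignment machinery: residue encoding, BLOSUM62, and a Gotoh kernel.

The affine-gap global aligner is used by the progressive aligner, the
near-identity deduplicator and the motif-scan anchoring step.  Gap cost
convention: a gap of length L costs ``open + (L-1) * extend`` (the opening
position carries the full open penalty), and terminal gaps are penalized like
internal ones — the same convention as Biopython's ``PairwiseAligner`` in
global mode, which serves as an independent oracle in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_AA = 20
#: index used for X / ambiguous residues; scores 0 against everything
X_INDEX = 20

# Typical amino-acid background frequencies (Robinson & Robinson style),
# normalised to sum to 1.  Used as the default profile background and for
# sampling synthetic root sequences.
BACKGROUND = np.array(
    [
        0.0786, 0.0151, 0.0535, 0.0661, 0.0405, 0.0684, 0.0229, 0.0591,
        0.0595, 0.0962, 0.0238, 0.0443, 0.0484, 0.0397, 0.0540, 0.0683,
        0.0541, 0.0673, 0.0108, 0.0294,
    ]
)
BACKGROUND = BACKGROUND / BACKGROUND.sum()

_DEFAULT_GAP_OPEN = -10.0
_DEFAULT_GAP_EXTEND = -0.5


def blosum62() -> np.ndarray:
    """Return BLOSUM62 as a 21x21 float array in AMINO_ACIDS order.

    Row/column 20 is the neutral X class (score 0 against everything).
    """
    from Bio.Align import substitution_matrices

    raw = substitution_matrices.load("BLOSUM62")
    mat = np.zeros((N_AA + 1, N_AA + 1))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            mat[i, j] = raw[a, b]
    return mat


_BLOSUM62: np.ndarray | None = None


def blosum62_cached() -> np.ndarray:
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = blosum62()
    return _BLOSUM62


def encode_peptide(peptide: str) -> np.ndarray:
    """Encode a peptide as int8 indices into AMINO_ACIDS; unknowns -> X_INDEX."""
    out = np.empty(len(peptide), dtype=np.int8)
    for i, ch in enumerate(peptide):
        out[i] = AA_INDEX.get(ch, X_INDEX)
    return out


@njit(cache=True)
def _gotoh_fill(sim, gap_open, gap_extend):  # pragma: no cover - numba
    n, m = sim.shape
    NEG = -1e30
    H = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in second sequence (i advances)
    Y = np.full((n + 1, m + 1), NEG)  # gap in first sequence (j advances)
    # traceback: 0=H,1=X,2=Y predecessor state
    tH = np.zeros((n + 1, m + 1), dtype=np.int8)
    tX = np.zeros((n + 1, m + 1), dtype=np.int8)
    tY = np.zeros((n + 1, m + 1), dtype=np.int8)
    H[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
        tX[i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
        tY[0, j] = 2 if j > 1 else 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sim[i - 1, j - 1]
            # H
            best = H[i - 1, j - 1]
            arg = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                arg = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                arg = 2
            H[i, j] = best + s
            tH[i, j] = arg
            # X: consume i
            best = H[i - 1, j] + gap_open
            arg = 0
            if X[i - 1, j] + gap_extend > best:
                best = X[i - 1, j] + gap_extend
                arg = 1
            if Y[i - 1, j] + gap_open > best:
                best = Y[i - 1, j] + gap_open
                arg = 2
            X[i, j] = best
            tX[i, j] = arg
            # Y: consume j
            best = H[i, j - 1] + gap_open
            arg = 0
            if Y[i, j - 1] + gap_extend > best:
                best = Y[i, j - 1] + gap_extend
                arg = 2
            if X[i, j - 1] + gap_open > best:
                best = X[i, j - 1] + gap_open
                arg = 1
            Y[i, j] = best
            tY[i, j] = arg
    # traceback
    score = H[n, m]
    state = 0
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2
    path_i = np.empty(n + m, dtype=np.int64)
    path_j = np.empty(n + m, dtype=np.int64)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            prev = tH[i, j]
            i -= 1
            j -= 1
            path_i[k] = i
            path_j[k] = j
        elif state == 1:
            prev = tX[i, j]
            i -= 1
            path_i[k] = i
            path_j[k] = -1
        else:
            prev = tY[i, j]
            j -= 1
            path_i[k] = -1
            path_j[k] = j
        state = prev
        k += 1
    return score, path_i[:k][::-1].copy(), path_j[:k][::-1].copy()


def gotoh_align(
    sim: np.ndarray,
    gap_open: float = _DEFAULT_GAP_OPEN,
    gap_extend: float = _DEFAULT_GAP_EXTEND,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Global affine-gap alignment over a precomputed similarity matrix.

    Returns (score, path_i, path_j) where the paths give, column by column,
    the consumed row/column index or -1 for a gap.
    """
    sim = np.ascontiguousarray(sim, dtype=np.float64)
    return _gotoh_fill(sim, float(gap_open), float(gap_extend))


def pairwise_align(
    a: str,
    b: str,
    gap_open: float = _DEFAULT_GAP_OPEN,
    gap_extend: float = _DEFAULT_GAP_EXTEND,
) -> tuple[float, str, str]:
    """Global BLOSUM62 alignment of two peptides; returns (score, alnA, alnB)."""
    S = blosum62_cached()
    ea, eb = encode_peptide(a), encode_peptide(b)
    sim = S[np.ix_(ea, eb)]
    score, pi, pj = gotoh_align(sim, gap_open, gap_extend)
    ra = "".join(a[i] if i >= 0 else "-" for i in pi)
    rb = "".join(b[j] if j >= 0 else "-" for j in pj)
    return float(score), ra, rb


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical residues over all alignment columns (global)."""
    if not a and not b:
        return 1.0
    _, ra, rb = pairwise_align(a, b)
    matches = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
    return matches / len(ra)
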