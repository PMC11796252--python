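"""Scoring schemes and pairwise local alignment.

Bit scores follow the Karlin-Altschul conversion ``bits = (lambda*S - ln K) / ln 2``
with the published gapped BLOSUM62/11/1 constants by default. A gap of length L
costs ``gap_open + L * gap_extend`` (NCBI convention), so opening into a gap from
an aligned pair costs ``gap_open + gap_extend``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .io import HitTableRow, ProteinRecord

#: Canonical residue order used for all internal matrices and vectors.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: BLOSUM62 background residue frequencies (20 canonical residues, normalized).
BLOSUM62_BACKGROUND = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}


def _load_matrix(name: str) -> np.ndarray:
    """Return the named substitution matrix re-indexed over :data:`ALPHABET`."""
    mat = substitution_matrices.load(name)
    out = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.int64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = int(mat[a][b])
    return out


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and bit-conversion constants."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float = 0.267
    k: float = 0.041
    matrix: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lambda_ <= 0:
            raise ValueError("lambda must be positive")
        if self.matrix is None:
            object.__setattr__(self, "matrix", _load_matrix(self.matrix_name))
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")

    @property
    def ln_k(self) -> float:
        return math.log(self.k)

    def raw_to_bits(self, raw: float) -> float:
        return (self.lambda_ * raw - self.ln_k) / math.log(2.0)

    def evalue(self, raw: float, m: int, n: int) -> float:
        """Pairwise-search-space E-value proxy ``K*m*n*exp(-lambda*S)``."""
        return self.k * m * n * math.exp(-self.lambda_ * raw)


def encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_INDEX[c] for c in sequence], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"residue {exc} outside alphabet {ALPHABET!r}") from None


# --- Smith-Waterman kernel -------------------------------------------------
#
# Gotoh three-state recurrence.  H = best local alignment ending at (i, j);
# E = ending with a gap in the query (consuming subject); F = gap in subject.
# The optimal cell is the highest score at the lexicographically smallest
# (end_q, end_s); traceback prefers diagonal > up > left and closes gaps as
# early as possible, so outputs are bit-reproducible.

def _sw_fill_py(qa, sa, sub, gap_first, gap_ext, H, E, F):
    n, m = qa.shape[0], sa.shape[0]
    best = 0.0
    bi = bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = max(H[i, j - 1] - gap_first, E[i, j - 1] - gap_ext)
            f = max(H[i - 1, j] - gap_first, F[i - 1, j] - gap_ext)
            h = H[i - 1, j - 1] + sub[qa[i - 1], sa[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
            if h > best:
                best = h
                bi, bj = i, j
    return best, bi, bj


try:  # numba accelerates the inner loop when available; behaviour is identical
    from numba import njit

    _sw_fill = njit(cache=True, fastmath=False)(_sw_fill_py)
except ImportError:  # pragma: no cover - exercised only without numba
    _sw_fill = _sw_fill_py


@dataclass(frozen=True)
class LocalAlignment:
    """Raw result of one Smith-Waterman alignment (1-based inclusive spans)."""

    raw_score: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    alignment_length: int
    identities: int
    mismatches: int
    gap_opens: int


def smith_waterman(query: str, subject: str, scheme: ScoringScheme) -> LocalAlignment:
    """Optimal local alignment of two residue strings with affine gaps.

    Returns a zero-score, empty-span alignment when no positive-scoring pair
    exists.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    qa, sa = encode(query), encode(subject)
    n, m = len(qa), len(sa)
    neg = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)
    F = np.full((n + 1, m + 1), neg)
    gap_first = float(scheme.gap_open + scheme.gap_extend)
    sub = scheme.matrix.astype(np.float64)
    best, bi, bj = _sw_fill(qa, sa, sub, gap_first, float(scheme.gap_extend), H, E, F)
    if best <= 0.0:
        return LocalAlignment(0.0, 0, 0, 0, 0, 0, 0, 0, 0)

    # traceback: state 'H' at (bi, bj)
    i, j = bi, bj
    state = "H"
    aln_len = ident = mismatch = gap_opens = 0
    ge = float(scheme.gap_extend)
    while True:
        if state == "H":
            if H[i, j] <= 0.0:
                break
            diag = H[i - 1, j - 1] + sub[qa[i - 1], sa[j - 1]]
            if H[i, j] == diag:
                aln_len += 1
                if qa[i - 1] == sa[j - 1]:
                    ident += 1
                else:
                    mismatch += 1
                i, j = i - 1, j - 1
            elif H[i, j] == F[i, j]:  # up: gap in subject
                state = "F"
            else:  # left: gap in query
                state = "E"
        elif state == "F":
            aln_len += 1
            if F[i, j] == H[i - 1, j] - gap_first:
                gap_opens += 1
                state = "H"
            i -= 1
        else:  # E
            aln_len += 1
            if E[i, j] == H[i, j - 1] - gap_first:
                gap_opens += 1
                state = "H"
            j -= 1
    return LocalAlignment(
        raw_score=float(best),
        q_start=i + 1,
        q_end=bi,
        s_start=j + 1,
        s_end=bj,
        alignment_length=aln_len,
        identities=ident,
        mismatches=mismatch,
        gap_opens=gap_opens,
    )


def local_align(a: ProteinRecord, b: ProteinRecord, scheme: ScoringScheme) -> HitTableRow:
    """Align two proteins and package the result as a hit-table row."""
    aln = smith_waterman(a.sequence, b.sequence, scheme)
    pid = 100.0 * aln.identities / aln.alignment_length if aln.alignment_length else 0.0
    return HitTableRow(
        query_id=a.id,
        subject_id=b.id,
        percent_identity=pid,
        alignment_length=aln.alignment_length,
        mismatches=aln.mismatches,
        gap_opens=aln.gap_opens,
        q_start=aln.q_start,
        q_end=aln.q_end,
        s_start=aln.s_start,
        s_end=aln.s_end,
        e_value=scheme.evalue(aln.raw_score, len(a.sequence), len(b.sequence)),
        bit_score=scheme.raw_to_bits(aln.raw_score),
        q_len=len(a.sequence),
        s_len=len(b.sequence),
    )


def needleman_wunsch(query: str, subject: str, scheme: ScoringScheme) -> tuple[str, str]:
    """Global alignment with affine gaps; returns the two gapped rows.

    Used to stitch family members onto the center sequence of a center-star
    multiple alignment.  Tie-breaking mirrors the local aligner: diagonal >
    up (gap in subject) > left (gap in query), gaps closed as early as
    possible.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    qa, sa = encode(query), encode(subject)
    n, m = len(qa), len(sa)
    neg = -1e12
    go, ge = float(scheme.gap_open), float(scheme.gap_extend)
    gap_first = go + ge
    sub = scheme.matrix.astype(np.float64)
    H = np.full((n + 1, m + 1), neg)
    E = np.full((n + 1, m + 1), neg)  # gap in query (consumes subject, "left")
    F = np.full((n + 1, m + 1), neg)  # gap in subject (consumes query, "up")
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = -(go + j * ge)
        H[0, j] = E[0, j]
    for i in range(1, n + 1):
        F[i, 0] = -(go + i * ge)
        H[i, 0] = F[i, 0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_first, E[i, j - 1] - ge)
            F[i, j] = max(H[i - 1, j] - gap_first, F[i - 1, j] - ge)
            H[i, j] = max(H[i - 1, j - 1] + sub[qa[i - 1], sa[j - 1]], E[i, j], F[i, j])
    # traceback
    out_q: list[str] = []
    out_s: list[str] = []
    i, j = n, m
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub[qa[i - 1], sa[j - 1]]:
                out_q.append(query[i - 1])
                out_s.append(subject[j - 1])
                i, j = i - 1, j - 1
            elif i > 0 and H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            out_q.append(query[i - 1])
            out_s.append("-")
            if H[i - 1, j] > neg / 2 and F[i, j] == H[i - 1, j] - gap_first:
                state = "H"
            i -= 1
        else:  # E
            out_q.append("-")
            out_s.append(subject[j - 1])
            if H[i, j - 1] > neg / 2 and E[i, j] == H[i, j - 1] - gap_first:
                state = "H"
            j -= 1
    return "".join(reversed(out_q)), "".join(reversed(out_s))


def self_raw_score(sequence: str, scheme: ScoringScheme) -> float:
    """Raw self-alignment score: the diagonal substitution sum.

    For any matrix with positive diagonal and positive gap penalties the
    ungapped full-length self alignment is optimal.
    """
    qa = encode(sequence)
    return float(scheme.matrix[qa, qa].sum())
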