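"""Global protein alignment with identity and coverage statistics.

The aligner is a Needleman–Wunsch/Gotoh dynamic program under BLOSUM62 with
affine gap costs (a gap of length k costs open + k·extend, BLAST-style
open=11, extend=1) and end gaps penalized. Traceback is deterministic with
tie order diagonal > up > left, so identical inputs always yield the same
alignment string.

Identity is matches / alignment columns × 100 (BLAST-like). Coverage of a
sequence is the fraction of its residues aligned residue-to-residue (not
against a gap), ×100; for a fragment aligned globally to a full-length
protein this is the fragment's span on the full protein.

The inner DP loops are JIT-compiled with numba when it is importable; the
pure-Python path computes identical results.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from .errors import FgiTyperError

NEG_INF = np.int32(-(10 ** 8))

#: canonical residue order used for the score matrix; X absorbs unknowns
ALPHABET = "ARNDCQEGHILKMFPSTWYVX"
_CHAR_TO_IDX = np.full(128, ALPHABET.index("X"), dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _CHAR_TO_IDX[ord(_c)] = _i
    _CHAR_TO_IDX[ord(_c.lower())] = _i


@lru_cache(maxsize=None)
def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as an int32 array over ALPHABET; X scores 0 against everything."""
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(ALPHABET)
    mat = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            if a == "X" or b == "X":
                mat[i, j] = 0
            else:
                mat[i, j] = int(blosum[a][b])
    return mat


@dataclass(frozen=True)
class ScoringConfig:
    """Affine-gap scoring parameters (BLAST protein defaults)."""

    gap_open: int = 11
    gap_extend: int = 1


DEFAULT_SCORING = ScoringConfig()


@dataclass
class AlignmentResult:
    """A global pairwise alignment and its summary statistics."""

    aligned_a: str
    aligned_b: str
    score: int
    identity_pct: float
    coverage_a_pct: float
    coverage_b_pct: float
    n_matches: int
    n_columns: int

    @property
    def min_coverage_pct(self) -> float:
        return min(self.coverage_a_pct, self.coverage_b_pct)


def _fill_and_traceback(ia, ib, submat, gap_open, gap_extend):
    """Gotoh fill plus deterministic traceback.

    Returns (score, moves) where moves[k] in {0: diagonal, 1: up (gap in b),
    2: left (gap in a)} reading the alignment left to right.

    State matrices: M (a_i~b_j), X (gap in b, vertical), Y (gap in a,
    horizontal). Ties prefer M, then X, then Y — i.e. diagonal > up > left.
    """
    n, m = len(ia), len(ib)
    open_cost = gap_open + gap_extend
    M = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    X = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    Y = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    # pointer codes: for M cells, predecessor state 0/1/2; for X, 0 (from M)
    # or 1 (extend); for Y, 0 (from M) or 2 (extend)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)

    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + i * gap_extend)
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + j * gap_extend)
        pY[0, j] = 0 if j == 1 else 2

    for i in range(1, n + 1):
        ai = ia[i - 1]
        for j in range(1, m + 1):
            # M: best predecessor with diagonal>up>left preference on ties
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + submat[ai, ib[j - 1]]
            pM[i, j] = ptr

            vo = M[i - 1, j] - open_cost
            ve = X[i - 1, j] - gap_extend
            if vo >= ve:
                X[i, j] = vo
                pX[i, j] = 0
            else:
                X[i, j] = ve
                pX[i, j] = 1

            ho = M[i, j - 1] - open_cost
            he = Y[i, j - 1] - gap_extend
            if ho >= he:
                Y[i, j] = ho
                pY[i, j] = 0
            else:
                Y[i, j] = he
                pY[i, j] = 2

    # final state choice, same preference order
    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2

    moves = np.empty(n + m, dtype=np.int8)
    k = n + m
    i, j = n, m
    while i > 0 or j > 0:
        k -= 1
        if state == 0:
            moves[k] = 0
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            moves[k] = 1
            state = pX[i, j]
            i -= 1
        else:
            moves[k] = 2
            state = pY[i, j]
            j -= 1
    return np.int64(score), moves[k:]


try:  # optional JIT; the pure-Python path is the reference semantics
    from numba import njit

    _fill_and_traceback = njit(cache=True)(_fill_and_traceback)
except ImportError:  # pragma: no cover - numba is normally available
    pass


def encode(seq: str) -> np.ndarray:
    """Map a protein string to score-matrix indices (unknowns become X)."""
    arr = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    return _CHAR_TO_IDX[np.minimum(arr, 127)].astype(np.int8)


def align_global(a: str, b: str, scoring: ScoringConfig = DEFAULT_SCORING) -> AlignmentResult:
    """Optimal global alignment of two protein sequences.

    Raises :class:`FgiTyperError` on empty input. See the module docstring
    for scoring, tie-breaking, identity and coverage definitions.
    """
    if not a or not b:
        raise FgiTyperError("align_global requires two non-empty sequences")
    ia, ib = encode(a), encode(b)
    score, moves = _fill_and_traceback(
        ia, ib, blosum62_matrix(), scoring.gap_open, scoring.gap_extend
    )
    out_a = []
    out_b = []
    i = j = 0
    matches = 0
    aligned_cols = 0
    for mv in moves:
        if mv == 0:
            ca, cb = a[i], b[j]
            out_a.append(ca)
            out_b.append(cb)
            aligned_cols += 1
            if ca.upper() == cb.upper():
                matches += 1
            i += 1
            j += 1
        elif mv == 1:
            out_a.append(a[i])
            out_b.append("-")
            i += 1
        else:
            out_a.append("-")
            out_b.append(b[j])
            j += 1
    n_cols = len(moves)
    return AlignmentResult(
        aligned_a="".join(out_a),
        aligned_b="".join(out_b),
        score=int(score),
        identity_pct=100.0 * matches / n_cols,
        coverage_a_pct=100.0 * aligned_cols / len(a),
        coverage_b_pct=100.0 * aligned_cols / len(b),
        n_matches=matches,
        n_columns=n_cols,
    )


def qualifies(result: AlignmentResult, id_thresh: float, cov_thresh: float) -> bool:
    """Orthology criterion: identity strictly above id_thresh and both
    coverages at least cov_thresh (all in percent)."""
    return result.identity_pct > id_thresh and result.min_coverage_pct >= cov_thresh


def kmer_set(seq: str, k: int = 4) -> frozenset:
    """Distinct k-mers of a sequence (prescreen support)."""
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def shared_kmer_count(a: str, b: str, k: int = 4) -> int:
    """Number of distinct k-mers shared between two sequences."""
    return len(kmer_set(a, k) & kmer_set(b, k))


def may_share_identity(
    a: str,
    b: str,
    a_kmers: frozenset | None = None,
    b_kmers: frozenset | None = None,
    min_len_screen: int = 40,
) -> bool:
    """Cheap prescreen: could this pair plausibly clear a 50%+ identity bar?

    Sequences related at or above ~50% identity (with random substitutions)
    share many 4-mers, while unrelated proteins share almost none. Pairs
    shorter than ``min_len_screen`` are always passed through to the full
    aligner. Precomputed k-mer sets may be supplied to avoid rebuilding them
    in all-vs-all searches. This is a heuristic speed filter only — callers
    may disable it via the prescreen flag in Thresholds.
    """
    shorter = min(len(a), len(b))
    if shorter < min_len_screen:
        return True
    if a_kmers is None:
        a_kmers = kmer_set(a)
    if b_kmers is None:
        b_kmers = kmer_set(b)
    threshold = max(2, int(0.01 * shorter))
    return len(a_kmers & b_kmers) >= threshold


def warm_up() -> None:
    """Trigger JIT compilation once so timings downstream are flat."""
    align_global("MKLV", "MKLV")
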