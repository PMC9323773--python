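"""Reference Smith-Waterman dynamic programming (quadratic space).

A deliberately plain affine-gap local-alignment implementation, independent
of the production engine in :mod:`hervtrace.alignment`, kept as the ground
truth for validating alignment scores and identities.  The gap convention
matches the engine: a gap of length L costs ``gap_open + (L-1)*gap_extend``.

Among co-optimal local alignments the one with the most identities is
reported (same tie-break as the engine), implemented by running the DP with
identical-residue scores nudged up by an epsilon far below the score
granularity; the reported raw score is recomputed under the true scoring
and cross-checked against an unperturbed DP fill.

The inner loops are numba-jitted; the traceback is plain Python over the
returned matrices.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NT_ORDER = "ACGTN"
_AA_ORDER = "ACDEFGHIKLMNPQRSTVWYXBZJUO*"

_NEG = -1e18
_TIE_EPS = 1e-7


@njit(cache=True)
def _sw_fill(q, s, sub, gap_open, gap_extend):
    m, n = q.shape[0], s.shape[0]
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), _NEG)  # gap in query (consumes subject)
    F = np.full((m + 1, n + 1), _NEG)  # gap in subject (consumes query)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            diag = H[i - 1, j - 1] + sub[q[i - 1], s[j - 1]]
            H[i, j] = max(0.0, diag, E[i, j], F[i, j])
    return H, E, F


def _encode(seq: str, order: str) -> np.ndarray:
    lut = {c: i for i, c in enumerate(order)}
    return np.array([lut[c] for c in seq.upper()], dtype=np.int64)


def _nt_matrix(match: float, mismatch: float) -> np.ndarray:
    sub = np.full((5, 5), mismatch)
    for i in range(4):
        sub[i, i] = match
    return sub


def _aa_matrix(matrix_id: str = "BLOSUM62") -> np.ndarray:
    from Bio.Align import substitution_matrices
    base = substitution_matrices.load(matrix_id)
    k = len(_AA_ORDER)
    sub = np.full((k, k), -1e4)
    for i, a in enumerate(_AA_ORDER):
        for j, b in enumerate(_AA_ORDER):
            if a != "*" and b != "*" and a in base.alphabet and b in base.alphabet:
                sub[i, j] = base[a, b]
    return sub


def sw_best(query: str, subject: str, match: float = 1.0, mismatch: float = -2.0,
            gap_open: float = 2.5, gap_extend: float = 2.5,
            protein: bool = False, matrix_id: str = "BLOSUM62"):
    """Optimal local alignment by full DP.

    Returns ``(score, q_start, q_end, s_start, s_end, aligned_cols,
    identities)``; all-zero coordinates when no positive-scoring alignment
    exists.
    """
    order = _AA_ORDER if protein else _NT_ORDER
    true_sub = _aa_matrix(matrix_id) if protein else _nt_matrix(match, mismatch)
    q = _encode(query, order)
    s = _encode(subject, order)
    # perturbed matrix: favour identities among co-optimal paths
    sub = true_sub.copy()
    for i, c in enumerate(order):
        if c not in "N*":
            sub[i, i] += _TIE_EPS
    H, E, F = _sw_fill(q, s, sub, gap_open, gap_extend)
    if H.max() <= 0:
        return 0.0, 0, 0, 0, 0, 0, 0
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    i, j = int(i), int(j)
    q_end, s_end = i, j
    cols = 0
    idents = 0
    true_score = 0.0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + sub[q[i - 1], s[j - 1]]
            if H[i, j] == diag:
                cols += 1
                true_score += true_sub[q[i - 1], s[j - 1]]
                if query[i - 1].upper() == subject[j - 1].upper() and \
                        (protein or query[i - 1].upper() != "N"):
                    idents += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols += 1
            if E[i, j] == H[i, j - 1] - gap_open:
                true_score -= gap_open
                j -= 1
                state = "H"
            else:
                true_score -= gap_extend
                j -= 1
        else:
            cols += 1
            if F[i, j] == H[i - 1, j] - gap_open:
                true_score -= gap_open
                i -= 1
                state = "H"
            else:
                true_score -= gap_extend
                i -= 1
    # sanity: the tie-broken path must still be optimal under true scoring
    Ht, _, _ = _sw_fill(q, s, true_sub, gap_open, gap_extend)
    best_true = float(Ht.max())
    if abs(true_score - best_true) > 1e-6:
        raise AssertionError(
            f"tie-break changed optimality: {true_score} vs {best_true}")
    return best_true, i, q_end, j, s_end, cols, idents


def sw_score(query: str, subject: str, **kw) -> float:
    """Optimal local alignment score only."""
    return sw_best(query, subject, **kw)[0]
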