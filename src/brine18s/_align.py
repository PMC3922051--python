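"""Shared global-alignment engine.

One Needleman-Wunsch core serves both pairwise sequence alignment (OTU
clustering) and profile-profile alignment (progressive multiple alignment).
The substitution score for every cell is precomputed as a matrix, and the
row recurrence for linear gaps is vectorised with a prefix-max scan:

    H[i, j] = max(A[j], H[i, j-1] + g)
            = g*j + cummax_j (A'[j] - g*j),   A'[0] = H[i, 0]

so each DP row is a handful of numpy operations.  ``free_ends=True`` makes
terminal gaps cost-free (semi-global alignment), which keeps truncated
reads aligned as contiguous blocks against full-length sequences instead of
scattering their tails.  Traceback prefers diagonal, then up (gap in the
second input), then left — a fixed rule that makes every alignment
deterministic.
"""

from __future__ import annotations

import numpy as np

GAP = "-"


def nw_matrix(S: np.ndarray, gap: float, free_ends: bool = False) -> np.ndarray:
    """Fill the (n+1)x(m+1) alignment DP matrix for cell scores ``S``.

    ``S[i, j]`` is the score of aligning item i of the first input against
    item j of the second; ``gap`` is the linear gap penalty (negative).
    With ``free_ends`` leading gaps are free (first row/column zero).
    """
    n, m = S.shape
    H = np.empty((n + 1, m + 1), dtype=np.float64)
    gj = gap * np.arange(m + 1)
    H[0] = 0.0 if free_ends else gj
    for i in range(1, n + 1):
        prev = H[i - 1]
        a = np.empty(m + 1)
        a[0] = 0.0 if free_ends else gap * i
        # candidate scores entering column j from diagonal or from above
        a[1:] = np.maximum(prev[:-1] + S[i - 1], prev[1:] + gap)
        H[i] = gj + np.maximum.accumulate(a - gj)
    return H


def nw_align(S: np.ndarray, gap: float, free_ends: bool = False) -> tuple[float, list[tuple[int, int]]]:
    """Optimal alignment for cell scores ``S``; returns (score, ops).

    Ops ``(1, 1)`` consume one item from each input, ``(1, 0)`` gap the
    second input, ``(0, 1)`` gap the first.  Ties: diagonal, then up, then
    left.  With ``free_ends`` the score maximises over the last row/column
    (preferring the bottom-right corner, then later rows, then later
    columns) and terminal gaps are appended cost-free.
    """
    n, m = S.shape
    H = nw_matrix(S, gap, free_ends)
    eps = 1e-9
    suffix: list[tuple[int, int]] = []
    i, j = n, m
    if free_ends:
        best_i, best_val = n, H[n, m]
        for r in range(n, -1, -1):  # prefer bottom-most row on ties
            if H[r, m] > best_val + eps:
                best_i, best_val = r, H[r, m]
        best_j = m
        for c in range(m, -1, -1):
            if H[n, c] > best_val + eps:
                best_j, best_val = c, H[n, c]
                best_i = None
        if best_i is None:
            i, j = n, best_j
            suffix = [(0, 1)] * (m - best_j)
        else:
            i, j = best_i, m
            suffix = [(1, 0)] * (n - best_i)
    score = float(best_val) if free_ends else float(H[n, m])
    ops: list[tuple[int, int]] = []
    while i > 0 or j > 0:
        if free_ends and (i == 0 or j == 0):
            ops.extend([(1, 0)] * i + [(0, 1)] * j)
            break
        h = H[i, j]
        if i > 0 and j > 0 and abs(h - (H[i - 1, j - 1] + S[i - 1, j - 1])) < eps:
            ops.append((1, 1))
            i -= 1
            j -= 1
        elif i > 0 and abs(h - (H[i - 1, j] + gap)) < eps:
            ops.append((1, 0))
            i -= 1
        else:
            ops.append((0, 1))
            j -= 1
    ops.reverse()
    return score, ops + suffix


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode_onehot(seq: str) -> np.ndarray:
    """4 x L one-hot base matrix; ambiguous bases get an all-zero column."""
    arr = np.zeros((4, len(seq)), dtype=np.float64)
    for i, c in enumerate(seq):
        k = _BASE_INDEX.get(c)
        if k is not None:
            arr[k, i] = 1.0
    return arr


def substitution_matrix(match: float, mismatch: float) -> np.ndarray:
    M = np.full((4, 4), mismatch, dtype=np.float64)
    np.fill_diagonal(M, match)
    return M
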