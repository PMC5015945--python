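"""Affine-gap alignment kernels.

A gap of length L costs ``gap_open + gap_extend * L`` (BLASTN cost
convention). A base code >= 4 (N or other ambiguity) always scores as a
mismatch and never as a match. The dynamic programs are JIT-compiled
with numba; the first call in a process pays a one-off compilation
cost.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .config import ScoringScheme

NEG = -(2**30)


@njit(cache=True)
def _sw_kernel(q, s, match, mismatch, open_, ext):
    n, m = len(q), len(s)
    H_prev = np.zeros(m + 1, dtype=np.int64)
    F_prev = np.full(m + 1, NEG, dtype=np.int64)
    H_cur = np.zeros(m + 1, dtype=np.int64)
    F_cur = np.full(m + 1, NEG, dtype=np.int64)
    best = 0
    best_i = 0
    best_j = 0
    for i in range(1, n + 1):
        qc = q[i - 1]
        H_cur[0] = 0
        e = NEG
        for j in range(1, m + 1):
            sub = match if (qc < 4 and qc == s[j - 1]) else mismatch
            f = F_prev[j] - ext
            t = H_prev[j] - open_ - ext
            if t > f:
                f = t
            F_cur[j] = f
            e -= ext
            t = H_cur[j - 1] - open_ - ext
            if t > e:
                e = t
            h = H_prev[j - 1] + sub
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0:
                h = 0
            H_cur[j] = h
            if h > best:
                best = h
                best_i = i
                best_j = j
        H_prev, H_cur = H_cur, H_prev
        F_prev, F_cur = F_cur, F_prev
    return best, best_i, best_j


@njit(cache=True)
def _glocal_kernel(q, s, match, mismatch, open_, ext, H, E, F):
    n, m = len(q), len(s)
    for j in range(m + 1):
        H[0, j] = 0
        E[0, j] = NEG
        F[0, j] = NEG
    for i in range(1, n + 1):
        H[i, 0] = 0
        E[i, 0] = NEG
        F[i, 0] = NEG
        qc = q[i - 1]
        for j in range(1, m + 1):
            sub = match if (qc < 4 and qc == s[j - 1]) else mismatch
            f = F[i - 1, j] - ext
            t = H[i - 1, j] - open_ - ext
            if t > f:
                f = t
            F[i, j] = f
            e = E[i, j - 1] - ext
            t = H[i, j - 1] - open_ - ext
            if t > e:
                e = t
            E[i, j] = e
            h = H[i - 1, j - 1] + sub
            if f > h:
                h = f
            if e > h:
                h = e
            H[i, j] = h


@njit(cache=True)
def _sw_banded_kernel(q, s, dlo, dhi, match, mismatch, open_, ext):
    """Smith-Waterman restricted to diagonals j - i in [dlo, dhi]."""
    n, m = len(q), len(s)
    H_prev = np.zeros(m + 1, dtype=np.int64)
    F_prev = np.full(m + 1, NEG, dtype=np.int64)
    H_cur = np.zeros(m + 1, dtype=np.int64)
    F_cur = np.full(m + 1, NEG, dtype=np.int64)
    best = 0
    best_i = 0
    best_j = 0
    for i in range(1, n + 1):
        qc = q[i - 1]
        jstart = i + dlo
        if jstart < 1:
            jstart = 1
        jend = i + dhi
        if jend > m:
            jend = m
        if jstart > jend:  # band outside the matrix on this row
            H_prev, H_cur = H_cur, H_prev
            F_prev, F_cur = F_cur, F_prev
            continue
        if jstart > 1:
            H_cur[jstart - 1] = 0
            F_cur[jstart - 1] = NEG
        e = NEG
        for j in range(jstart, jend + 1):
            sub = match if (qc < 4 and qc == s[j - 1]) else mismatch
            f = F_prev[j] - ext
            t = H_prev[j] - open_ - ext
            if t > f:
                f = t
            F_cur[j] = f
            e -= ext
            t = H_cur[j - 1] - open_ - ext
            if t > e:
                e = t
            h = H_prev[j - 1] + sub
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0:
                h = 0
            H_cur[j] = h
            if h > best:
                best = h
                best_i = i
                best_j = j
        if jend + 1 <= m:
            H_cur[jend + 1] = 0
            F_cur[jend + 1] = NEG
        H_prev, H_cur = H_cur, H_prev
        F_prev, F_cur = F_cur, F_prev
    return best, best_i, best_j


def local_align_banded(q: np.ndarray, s: np.ndarray, dlo: int, dhi: int,
                       scheme: ScoringScheme,
                       pad: int = 24) -> tuple[int, int, int, int, int]:
    """Local alignment within a diagonal band (j - i in [dlo-pad, dhi+pad]).

    Same return convention as :func:`local_align`. Alignments whose
    optimal path leaves the band are not found — callers pass a band
    derived from the seed cluster, which realistic alignments stay in.
    """
    q = np.ascontiguousarray(q)
    s = np.ascontiguousarray(s)
    lo, hi = dlo - pad, dhi + pad
    best, q_end, s_end = _sw_banded_kernel(
        q, s, lo, hi, scheme.match, scheme.mismatch,
        scheme.gap_open, scheme.gap_extend)
    if best <= 0:
        return 0, 0, 0, 0, 0
    # reversed prefixes: diagonal d maps to (s_end - q_end) - d
    rlo = (s_end - q_end) - hi
    rhi = (s_end - q_end) - lo
    best2, qr, sr = _sw_banded_kernel(
        np.ascontiguousarray(q[:q_end][::-1]),
        np.ascontiguousarray(s[:s_end][::-1]),
        rlo, rhi, scheme.match, scheme.mismatch,
        scheme.gap_open, scheme.gap_extend)
    return max(best, best2), q_end - qr, q_end, s_end - sr, s_end


def local_score_end(q: np.ndarray, s: np.ndarray,
                    scheme: ScoringScheme) -> tuple[int, int, int]:
    """Best Smith-Waterman score and its end coordinates.

    Returns ``(score, q_end, s_end)`` with exclusive 0-based ends.
    """
    best, bi, bj = _sw_kernel(
        np.ascontiguousarray(q), np.ascontiguousarray(s),
        scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend)
    return int(best), int(bi), int(bj)


def local_align(q: np.ndarray, s: np.ndarray,
                scheme: ScoringScheme) -> tuple[int, int, int, int, int]:
    """Optimal local alignment: ``(score, q_start, q_end, s_start, s_end)``.

    End coordinates from a forward pass; start coordinates from the same
    pass on the reversed prefixes.
    """
    score, q_end, s_end = local_score_end(q, s, scheme)
    if score <= 0:
        return 0, 0, 0, 0, 0
    score2, qr, sr = local_score_end(q[:q_end][::-1], s[:s_end][::-1], scheme)
    q_start, s_start = q_end - qr, s_end - sr
    return max(score, score2), q_start, q_end, s_start, s_end


def glocal_project(q: np.ndarray, s: np.ndarray,
                   scheme: ScoringScheme) -> tuple[int, np.ndarray]:
    """Global alignment with free end gaps, projected onto query columns.

    Returns ``(score, proj)`` where ``proj[i]`` is the subject base code
    aligned to query position i, or -1 where the subject has a gap.
    Subject insertions relative to the query are dropped: the projection
    is what "stacking members on query coordinates" means for the
    family alignments.
    """
    n, m = len(q), len(s)
    open_, ext = scheme.gap_open, scheme.gap_extend
    match, mismatch = scheme.match, scheme.mismatch
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    E = np.empty((n + 1, m + 1), dtype=np.int64)
    F = np.empty((n + 1, m + 1), dtype=np.int64)
    _glocal_kernel(np.ascontiguousarray(q), np.ascontiguousarray(s),
                   match, mismatch, open_, ext, H, E, F)
    # free trailing gaps: best cell on the last row or column
    last_row_j = int(np.argmax(H[n, :]))
    last_col_i = int(np.argmax(H[:, m]))
    if H[n, last_row_j] >= H[last_col_i, m]:
        i, j = n, last_row_j
    else:
        i, j = last_col_i, m
    score = int(H[i, j])

    proj = np.full(n, -1, dtype=np.int16)
    while i > 0 and j > 0:
        h = H[i, j]
        sub = match if (q[i - 1] < 4 and q[i - 1] == s[j - 1]) else mismatch
        if h == H[i - 1, j - 1] + sub:
            proj[i - 1] = s[j - 1]
            i, j = i - 1, j - 1
        elif h == F[i, j]:
            while True:  # vertical gap: subject gap at query columns
                exit_here = F[i, j] == H[i - 1, j] - open_ - ext
                i -= 1
                if i == 0 or exit_here:
                    break
        elif h == E[i, j]:
            while True:  # horizontal gap: subject insertion, dropped
                exit_here = E[i, j] == H[i, j - 1] - open_ - ext
                j -= 1
                if j == 0 or exit_here:
                    break
        else:  # free boundary
            break
    return score, proj
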