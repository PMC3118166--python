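"""Numba-compiled inner loops: FM-index rank/search/locate and banded Gotoh DP.

Everything here operates on plain numpy arrays so the kernels stay free of
Python object overhead; the object-level API lives in :mod:`pyromap.fmindex`
and :mod:`pyromap.extension`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: cost larger than any reachable alignment cost, small enough that
#: adding a gap penalty cannot overflow int32
BIG = np.int32(1 << 28)


@njit(cache=True, inline="always")
def rank_k(bwt, ck, stride, c, i):
    """Occurrences of symbol ``c`` in ``bwt[:i]`` via checkpoint + scan."""
    blk = i // stride
    r = ck[c, blk]
    for k in range(blk * stride, i):
        if bwt[k] == c:
            r += 1
    return r


@njit(cache=True)
def backward_search_k(bwt, ck, stride, cumcounts, pattern):
    """Suffix-array interval of ``pattern``; ``(0, 0)`` if absent.

    Processes the pattern right-to-left, one symbol per step.  Symbols
    outside the base alphabet (codes 2..5) yield the empty interval.
    """
    lo = np.int64(0)
    hi = np.int64(bwt.shape[0])
    for idx in range(pattern.shape[0] - 1, -1, -1):
        c = pattern[idx]
        if c < 2 or c > 5:
            return np.int64(0), np.int64(0)
        lo = cumcounts[c] + rank_k(bwt, ck, stride, c, lo)
        hi = cumcounts[c] + rank_k(bwt, ck, stride, c, hi)
        if lo >= hi:
            return np.int64(0), np.int64(0)
    return lo, hi


@njit(cache=True)
def extend_right_k(bwt, ck, stride, cumcounts, query, start, rare_cap, min_len):
    """Longest prefix of ``query[start:]`` present in the indexed text.

    Intended to run against the index of the *reversed* text: appending a
    symbol on the right of the forward pattern is one backward-search step
    on the reversed text.  Returns ``(length, lo, hi, rare_len, rare_lo,
    rare_hi)`` where ``[lo, hi)`` is the interval of the longest non-empty
    match and ``rare_len`` is the smallest prefix length of at least
    ``min_len`` symbols whose interval holds at most ``rare_cap`` rows
    (0 when no prefix qualifies).  All-zero when even the first symbol is
    absent.
    """
    lo = np.int64(0)
    hi = np.int64(bwt.shape[0])
    length = 0
    best_lo = np.int64(0)
    best_hi = np.int64(0)
    rare_len = 0
    rare_lo = np.int64(0)
    rare_hi = np.int64(0)
    for pos in range(start, query.shape[0]):
        c = query[pos]
        if c < 2 or c > 5:
            break
        nlo = cumcounts[c] + rank_k(bwt, ck, stride, c, lo)
        nhi = cumcounts[c] + rank_k(bwt, ck, stride, c, hi)
        if nlo >= nhi:
            break
        lo, hi = nlo, nhi
        best_lo, best_hi = lo, hi
        length += 1
        if rare_len == 0 and hi - lo <= rare_cap and length >= min_len:
            rare_len = length
            rare_lo, rare_hi = lo, hi
    return length, best_lo, best_hi, rare_len, rare_lo, rare_hi


@njit(cache=True)
def locate_k(bwt, ck, stride, cumcounts, sa_marked, sa_values, lo, hi):
    """Suffix-array values for rows ``[lo, hi)`` by LF-walking to a sample."""
    out = np.empty(hi - lo, np.int64)
    for r in range(lo, hi):
        i = r
        steps = 0
        while sa_marked[i] == 0:
            c = bwt[i]
            i = cumcounts[c] + rank_k(bwt, ck, stride, c, i)
            steps += 1
        out[r - lo] = sa_values[i] + steps
    return out


@njit(cache=True, inline="always")
def _coherent_k(pos, seed_idx, occ_len, read_start, segment, a, b, eps_min, rho):
    """Coherence of occurrence ``b`` following chain member ``a``."""
    if seed_idx[b] <= seed_idx[a]:
        return False
    if segment[b] != segment[a]:
        return False
    if pos[b] < pos[a]:
        return False
    read_gap = read_start[b] - (read_start[a] + occ_len[a])
    genome_gap = pos[b] - (pos[a] + occ_len[a])
    eps = int(np.ceil(rho * read_gap))
    if eps < eps_min:
        eps = eps_min
    d = genome_gap - read_gap
    return -eps <= d <= eps


@njit(cache=True)
def chain_build_k(pos, seed_idx, occ_len, read_start, segment, eps_min, rho, lookback):
    """Greedy left-to-right coherence chaining with bounded lookback.

    Occurrences (sorted by position) are appended to the most recently
    active chain whose tail they are coherent with, searching at most
    ``lookback`` recent chains; otherwise they start a new chain.  With
    ``lookback == 1`` this is the strict partition into maximal runs of
    consecutive coherent matches; a small lookback keeps an isolated
    interloper occurrence from cutting the chain it landed inside.

    Returns ``(chain_id per occurrence, n_chains, spans, first_occ)``
    where ``spans[c]`` counts the distinct read bases covered by chain
    ``c``'s anchors (anchors may overlap on the read) and ``first_occ[c]``
    is the index of the chain's first occurrence.
    """
    n = pos.shape[0]
    chain_id = np.empty(n, np.int64)
    spans = np.zeros(n, np.int64)
    first_occ = np.empty(n, np.int64)
    tails = np.empty(n, np.int64)  # last occurrence of each chain
    covered = np.empty(n, np.int64)  # read-side covered end of each chain
    ring = np.empty(lookback, np.int64)  # recently active chain ids
    nring = 0
    nch = 0
    for i in range(n):
        assigned = -1
        for r in range(nring):
            c = ring[r]
            if _coherent_k(pos, seed_idx, occ_len, read_start, segment, tails[c], i, eps_min, rho):
                assigned = c
                break
        if assigned == -1:
            assigned = nch
            nch += 1
            first_occ[assigned] = i
            covered[assigned] = read_start[i]
        c = assigned
        chain_id[i] = c
        tails[c] = i
        end = read_start[i] + occ_len[i]
        if end > covered[c]:
            start = read_start[i]
            if start < covered[c]:
                start = covered[c]
            spans[c] += end - start
            covered[c] = end
        # move chain c to the front of the recency ring
        found = -1
        for r in range(nring):
            if ring[r] == c:
                found = r
                break
        if found == -1:
            if nring < lookback:
                nring += 1
            found = nring - 1
        for r in range(found, 0, -1):
            ring[r] = ring[r - 1]
        ring[0] = c
    return chain_id, nch, spans, first_occ


@njit(cache=True)
def rare_matches_k(bwt, ck, stride, cumcounts, query, starts, rare_cap, min_len):
    """Shortest informative match from each cursor in ``starts``.

    For every cursor, extends a backward search on the reversed text until
    the interval holds at most ``rare_cap`` rows, then stops.  Returns
    parallel arrays ``(length, lo, hi)`` with zeros where no prefix of
    length >= ``min_len`` reaches the cap before the match dies out.
    """
    m = starts.shape[0]
    out_len = np.zeros(m, np.int64)
    out_lo = np.zeros(m, np.int64)
    out_hi = np.zeros(m, np.int64)
    nq = query.shape[0]
    for s in range(m):
        lo = np.int64(0)
        hi = np.int64(bwt.shape[0])
        length = 0
        for p in range(starts[s], nq):
            c = query[p]
            if c < 2 or c > 5:
                break
            nlo = cumcounts[c] + rank_k(bwt, ck, stride, c, lo)
            nhi = cumcounts[c] + rank_k(bwt, ck, stride, c, hi)
            if nlo >= nhi:
                break
            lo, hi = nlo, nhi
            length += 1
            if hi - lo <= rare_cap and length >= min_len:
                out_len[s] = length
                out_lo[s] = lo
                out_hi[s] = hi
                break
    return out_len, out_lo, out_hi


@njit(cache=True)
def gotoh_band_k(a, b, mismatch, gap_open, gap_ext, band_lo, band_hi):
    """Banded affine-gap (Gotoh) cost matrices for ``a`` vs ``b``.

    Minimisation over three states: ``M`` ends in match/mismatch, ``X``
    ends in a gap in ``b`` (consumes ``a`` only; an insertion relative to
    the reference), ``Y`` ends in a gap in ``a`` (consumes ``b`` only; a
    deletion).  A gap of length k costs ``gap_open + k * gap_ext``.  Cells
    with ``j - i`` outside ``[band_lo, band_hi]`` stay at :data:`BIG`.
    """
    la = a.shape[0]
    lb = b.shape[0]
    M = np.full((la + 1, lb + 1), BIG, np.int32)
    X = np.full((la + 1, lb + 1), BIG, np.int32)
    Y = np.full((la + 1, lb + 1), BIG, np.int32)
    M[0, 0] = 0
    for j in range(1, min(lb, band_hi) + 1):
        Y[0, j] = gap_open + j * gap_ext
    for i in range(1, la + 1):
        if i + band_lo <= 0:
            X[i, 0] = gap_open + i * gap_ext
        jlo = max(1, i + band_lo)
        jhi = min(lb, i + band_hi)
        for j in range(jlo, jhi + 1):
            p = M[i - 1, j - 1]
            if X[i - 1, j - 1] < p:
                p = X[i - 1, j - 1]
            if Y[i - 1, j - 1] < p:
                p = Y[i - 1, j - 1]
            if p < BIG:
                if a[i - 1] == b[j - 1]:
                    M[i, j] = p
                else:
                    M[i, j] = p + mismatch
            o = M[i - 1, j]
            if Y[i - 1, j] < o:
                o = Y[i - 1, j]
            v = BIG
            if o < BIG:
                v = o + gap_open + gap_ext
            if X[i - 1, j] < BIG and X[i - 1, j] + gap_ext < v:
                v = X[i - 1, j] + gap_ext
            if v < BIG:
                X[i, j] = v
            o = M[i, j - 1]
            if X[i, j - 1] < o:
                o = X[i, j - 1]
            w = BIG
            if o < BIG:
                w = o + gap_open + gap_ext
            if Y[i, j - 1] < BIG and Y[i, j - 1] + gap_ext < w:
                w = Y[i, j - 1] + gap_ext
            if w < BIG:
                Y[i, j] = w
    return M, X, Y
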