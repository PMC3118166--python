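"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (quadratic scans, full unbanded DP,
exhaustive enumeration) and shares no code with the package's own
algorithms.
"""

from __future__ import annotations

import numpy as np


def naive_suffix_array(codes) -> list[int]:
    """Sort all suffixes explicitly."""
    s = [int(c) for c in codes]
    return sorted(range(len(s)), key=lambda i: s[i:])


def bwt_by_rotation(codes) -> list[int]:
    """Last column of the sorted rotations of the terminated text."""
    s = [int(c) for c in codes]
    n = len(s)
    rotations = sorted(s[i:] + s[:i] for i in range(n))
    return [r[-1] for r in rotations]


def naive_occurrences(text_codes, pattern_codes) -> list[int]:
    """All exact occurrence start positions by direct comparison."""
    t = [int(c) for c in text_codes]
    p = [int(c) for c in pattern_codes]
    if not p:
        return list(range(len(t)))
    out = []
    for i in range(len(t) - len(p) + 1):
        if t[i : i + len(p)] == p:
            out.append(i)
    return out


def naive_longest_match(text_codes, query_codes, start: int) -> int:
    """Largest l such that query[start:start+l] occurs in the text."""
    l = 0
    while start + l < len(query_codes):
        if not naive_occurrences(text_codes, query_codes[start : start + l + 1]):
            break
        l += 1
    return l


def inverse_bwt_by_lf(bwt) -> list[int]:
    """Reconstruct the text from its BWT with an explicit LF table."""
    b = [int(c) for c in bwt]
    n = len(b)
    order = sorted(range(n), key=lambda i: (b[i], i))  # stable first-column order
    lf = [0] * n
    for first_row, i in enumerate(order):
        lf[i] = first_row
    out = [0] * n
    i = b.index(0)
    for pos in range(n - 1, -1, -1):
        out[pos] = b[i]
        i = lf[i]
    return out


def gotoh_full(a, b, mismatch=1, gap_open=1, gap_extend=1, free_b_ends=False):
    """Unbanded affine-gap DP with traceback.

    Returns ``(cost, ops)`` with ops over {=, X, I, D} (I consumes ``a``
    only).  With ``free_b_ends`` the alignment is semi-global in ``b``:
    leading and trailing unaligned stretches of ``b`` are free.
    """
    a = [int(c) for c in a]
    b = [int(c) for c in b]
    la, lb = len(a), len(b)
    INF = 10**9
    M = [[INF] * (lb + 1) for _ in range(la + 1)]
    X = [[INF] * (lb + 1) for _ in range(la + 1)]
    Y = [[INF] * (lb + 1) for _ in range(la + 1)]
    M[0][0] = 0
    for j in range(1, lb + 1):
        Y[0][j] = 0 if free_b_ends else gap_open + j * gap_extend
    for i in range(1, la + 1):
        X[i][0] = gap_open + i * gap_extend
        for j in range(1, lb + 1):
            diag = min(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            if diag < INF:
                M[i][j] = diag + (0 if a[i - 1] == b[j - 1] else mismatch)
            up = min(M[i - 1][j] + gap_open + gap_extend,
                     X[i - 1][j] + gap_extend,
                     Y[i - 1][j] + gap_open + gap_extend)
            X[i][j] = min(INF, up)
            left = min(M[i][j - 1] + gap_open + gap_extend,
                       X[i][j - 1] + gap_open + gap_extend,
                       Y[i][j - 1] + gap_extend)
            Y[i][j] = min(INF, left)
    if free_b_ends:
        end_j = min(range(lb + 1), key=lambda j: min(M[la][j], X[la][j], Y[la][j]))
    else:
        end_j = lb
    cell = min(M[la][end_j], X[la][end_j], Y[la][end_j])
    # traceback
    i, j = la, end_j
    state = "M" if M[i][j] == cell else ("X" if X[i][j] == cell else "Y")
    ops = []
    while i > 0 or j > 0:
        if free_b_ends and i == 0:
            break  # leading b overhang is free
        if state == "M":
            sub = 0 if a[i - 1] == b[j - 1] else mismatch
            ops.append("=" if sub == 0 else "X")
            target = M[i][j] - sub
            i, j = i - 1, j - 1
            state = "M" if M[i][j] == target else ("X" if X[i][j] == target else "Y")
        elif state == "X":
            ops.append("I")
            target = X[i][j]
            i -= 1
            if M[i][j] + gap_open + gap_extend == target:
                state = "M"
            elif X[i][j] + gap_extend == target:
                state = "X"
            else:
                state = "Y"
        else:
            ops.append("D")
            target = Y[i][j]
            j -= 1
            if j == 0 and free_b_ends and i == 0:
                break
            if M[i][j] + gap_open + gap_extend == target:
                state = "M"
            elif X[i][j] + gap_open + gap_extend == target:
                state = "X"
            else:
                state = "Y"
    ops.reverse()
    return int(cell), ops


def error_bases(ops) -> int:
    return sum(1 for op in ops if op in "XID")


def exhaustive_partitions(n: int):
    """All ways to split range(n) into consecutive non-empty blocks."""
    if n == 0:
        yield []
        return
    for mask in range(1 << (n - 1)):
        blocks, start = [], 0
        for i in range(n - 1):
            if mask >> i & 1:
                blocks.append((start, i + 1))
                start = i + 1
        blocks.append((start, n))
        yield blocks
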