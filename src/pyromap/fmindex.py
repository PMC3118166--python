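"""Compressed full-text index: suffix array, BWT and FM-index queries.

The suffix array is built by prefix doubling (numpy ``lexsort`` per round,
O(n log^2 n) overall), which is practical for multi-megabase references.
The FM-index stores the BWT, per-symbol cumulative counts (the C table),
checkpointed occurrence counts for O(1) rank, and a text-position-sampled
suffix array for locate.  Forward longest-prefix matching — the primitive
the seeding stage needs — is served by a second FM-index over the reversed
text, so that every query reduces to backward search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._codes import NSYMBOLS
from .reference import ReferenceText, Segment, encode_reference  # noqa: F401  (re-exported surface)

DEFAULT_RANK_STRIDE = 128
DEFAULT_SA_STRIDE = 32


@dataclass(frozen=True)
class SAInterval:
    """Half-open row range ``[low, high)`` into the suffix array."""

    low: int
    high: int

    def __len__(self) -> int:
        return max(0, self.high - self.low)

    @property
    def empty(self) -> bool:
        return self.high <= self.low


EMPTY_INTERVAL = SAInterval(0, 0)


@dataclass
class SuffixArray:
    """Lexicographic order of all suffix start positions of a text."""

    order: np.ndarray

    def __len__(self) -> int:
        return len(self.order)


def build_suffix_array(text: ReferenceText | np.ndarray) -> SuffixArray:
    """Suffix array by prefix doubling; text must end with the sentinel."""
    codes = text.codes if isinstance(text, ReferenceText) else np.asarray(text, dtype=np.uint8)
    if len(codes) == 0 or codes[-1] != 0:
        raise ValueError("text must be non-empty and sentinel-terminated")
    n = len(codes)
    rank = codes.astype(np.int64)
    k = 1
    sa = np.argsort(rank, kind="stable")
    key2 = np.empty(n, dtype=np.int64)
    while True:
        key2.fill(-1)
        key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        r1 = rank[sa]
        r2 = key2[sa]
        distinct = np.empty(n, dtype=np.int64)
        distinct[0] = 0
        distinct[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.cumsum(distinct)
        rank[sa] = new_rank
        if new_rank[-1] == n - 1:
            break
        k *= 2
    return SuffixArray(order=sa.astype(np.int64))


def bwt_from_sa(text: ReferenceText | np.ndarray, sa: SuffixArray) -> np.ndarray:
    """Burrows-Wheeler transform: ``bwt[i] = text[sa[i] - 1]`` (wrapping)."""
    codes = text.codes if isinstance(text, ReferenceText) else np.asarray(text, dtype=np.uint8)
    if len(sa.order) != len(codes):
        raise ValueError("suffix array length does not match text length")
    return codes[(sa.order - 1) % len(codes)]


def inverse_bwt(bwt: np.ndarray) -> np.ndarray:
    """Reconstruct the sentinel-terminated text from its BWT (LF mapping)."""
    n = len(bwt)
    counts = np.bincount(bwt, minlength=NSYMBOLS)
    cum = np.zeros(NSYMBOLS, dtype=np.int64)
    cum[1:] = np.cumsum(counts)[:-1]
    # LF[i] = C[bwt[i]] + rank(bwt[i], i)
    occ = np.zeros(n, dtype=np.int64)
    seen = np.zeros(NSYMBOLS, dtype=np.int64)
    for i in range(n):
        occ[i] = seen[bwt[i]]
        seen[bwt[i]] += 1
    lf = cum[bwt] + occ
    out = np.empty(n, dtype=np.uint8)
    i = int(np.flatnonzero(bwt == 0)[0])  # row whose rotation starts after the sentinel
    for pos in range(n - 1, -1, -1):
        out[pos] = bwt[i]
        i = int(lf[i])
    # out currently ends with the symbol preceding the sentinel; rotate so
    # the sentinel is last: the loop above emits text[n-1::-1] reversed,
    # starting from the sentinel row, so out == text already.
    return out


@dataclass
class FMIndex:
    """BWT-based index supporting backward search and locate."""

    bwt: np.ndarray
    cumcounts: np.ndarray  # C table: cumcounts[c] = #symbols lexicographically < c
    checkpoints: np.ndarray  # (NSYMBOLS, n // rank_stride + 1) occurrence counts
    sa_marked: np.ndarray  # uint8 flags: suffix-array value sampled at this row
    sa_values: np.ndarray  # int64, -1 where unsampled
    rank_stride: int
    sa_stride: int

    @property
    def n(self) -> int:
        return len(self.bwt)

    def rank(self, symbol: int, i: int) -> int:
        """Occurrences of ``symbol`` in ``bwt[:i]``."""
        return int(_kernels.rank_k(self.bwt, self.checkpoints, self.rank_stride, symbol, i))

    def lf(self, i: int) -> int:
        c = int(self.bwt[i])
        return int(self.cumcounts[c]) + self.rank(c, i)


def build_fm_index(
    text: ReferenceText | np.ndarray,
    rank_stride: int = DEFAULT_RANK_STRIDE,
    sa_stride: int = DEFAULT_SA_STRIDE,
    sa: SuffixArray | None = None,
) -> FMIndex:
    codes = text.codes if isinstance(text, ReferenceText) else np.asarray(text, dtype=np.uint8)
    if sa is None:
        sa = build_suffix_array(codes)
    bwt = bwt_from_sa(codes, sa)
    n = len(codes)

    counts = np.bincount(codes, minlength=NSYMBOLS).astype(np.int64)
    cumcounts = np.zeros(NSYMBOLS, dtype=np.int64)
    cumcounts[1:] = np.cumsum(counts)[:-1]

    nblocks = n // rank_stride + 1
    checkpoints = np.zeros((NSYMBOLS, nblocks), dtype=np.int64)
    for c in range(NSYMBOLS):
        cum = np.cumsum(bwt == c)
        checkpoints[c, 1:] = cum[rank_stride - 1 :: rank_stride][: nblocks - 1]

    sa_marked = (sa.order % sa_stride == 0).astype(np.uint8)
    sa_values = np.where(sa_marked.astype(bool), sa.order, -1).astype(np.int64)

    return FMIndex(
        bwt=bwt,
        cumcounts=cumcounts,
        checkpoints=checkpoints,
        sa_marked=sa_marked,
        sa_values=sa_values,
        rank_stride=rank_stride,
        sa_stride=sa_stride,
    )


def backward_search(fm: FMIndex, pattern: np.ndarray) -> SAInterval:
    """Interval of suffixes having ``pattern`` as a prefix (empty if absent)."""
    lo, hi = _kernels.backward_search_k(
        fm.bwt, fm.checkpoints, fm.rank_stride, fm.cumcounts, np.asarray(pattern, dtype=np.uint8)
    )
    if len(pattern) == 0:
        return SAInterval(0, fm.n)
    return SAInterval(int(lo), int(hi))


def locate(fm: FMIndex, interval: SAInterval, max_occ: int | None = None) -> tuple[list[int], bool]:
    """Suffix-array values for an interval's rows.

    Returns ``(positions, truncated)``; when the interval holds more than
    ``max_occ`` rows nothing is located and the truncation flag is set.
    """
    if interval.empty:
        return [], False
    if max_occ is not None and len(interval) > max_occ:
        return [], True
    pos = _kernels.locate_k(
        fm.bwt,
        fm.checkpoints,
        fm.rank_stride,
        fm.cumcounts,
        fm.sa_marked,
        fm.sa_values,
        interval.low,
        interval.high,
    )
    return [int(p) for p in pos], False


class ForwardSearcher:
    """Forward longest-prefix matching over an index of the reversed text.

    An occurrence of pattern ``p`` at position ``i`` of the forward body
    (text without its sentinel, length ``nb``) corresponds to an occurrence
    of ``reversed(p)`` at ``nb - len(p) - i`` in the reversed body, so
    extending the forward pattern on the right is one backward-search step
    on the reverse index.
    """

    def __init__(self, fm_rev: FMIndex):
        self.fm_rev = fm_rev
        self.body_len = fm_rev.n - 1

    def longest_match_from(
        self, query: np.ndarray, start: int, max_occ: int | None = None
    ) -> tuple[int, list[int], int, bool]:
        """Maximal ``l`` with ``query[start:start+l]`` present in the text.

        Returns ``(length, forward positions, occurrence count, truncated)``.
        """
        length, interval, _, _ = self.match_interval(query, start)
        if length == 0:
            return 0, [], 0, False
        positions, truncated = self.locate_forward(interval, length, max_occ)
        return length, positions, len(interval), truncated

    def match_interval(
        self, query: np.ndarray, start: int, rare_cap: int = 1, min_len: int = 1
    ) -> tuple[int, SAInterval, int, SAInterval]:
        """Longest match from ``start`` plus its rarest informative prefix.

        Returns ``(length, interval, rare_len, rare_interval)`` where
        ``rare_len`` is the smallest prefix length of at least ``min_len``
        symbols whose interval holds at most ``rare_cap`` rows (0 when none
        does).  Anchoring chains on the rare prefix keeps the true locus
        reachable even when the maximal match overshoots a sequencing
        error via a chance occurrence elsewhere.
        """
        if not 0 <= start <= len(query):
            raise ValueError("start out of range")
        length, lo, hi, rlen, rlo, rhi = _kernels.extend_right_k(
            self.fm_rev.bwt,
            self.fm_rev.checkpoints,
            self.fm_rev.rank_stride,
            self.fm_rev.cumcounts,
            np.asarray(query, dtype=np.uint8),
            start,
            rare_cap,
            min_len,
        )
        if length == 0:
            return 0, EMPTY_INTERVAL, 0, EMPTY_INTERVAL
        rare = SAInterval(int(rlo), int(rhi)) if rlen else EMPTY_INTERVAL
        return int(length), SAInterval(int(lo), int(hi)), int(rlen), rare

    def locate_forward(
        self, interval: SAInterval, pattern_len: int, max_occ: int | None = None
    ) -> tuple[list[int], bool]:
        """Translate reverse-index rows into forward-strand start positions."""
        fwd, truncated = self.locate_forward_array(interval, pattern_len, max_occ)
        return [int(p) for p in fwd], truncated

    def locate_forward_array(
        self, interval: SAInterval, pattern_len: int, max_occ: int | None = None
    ) -> tuple[np.ndarray, bool]:
        """Array variant of :meth:`locate_forward` (hot path)."""
        if interval.empty:
            return np.empty(0, dtype=np.int64), False
        if max_occ is not None and len(interval) > max_occ:
            return np.empty(0, dtype=np.int64), True
        rev_pos = _kernels.locate_k(
            self.fm_rev.bwt,
            self.fm_rev.checkpoints,
            self.fm_rev.rank_stride,
            self.fm_rev.cumcounts,
            self.fm_rev.sa_marked,
            self.fm_rev.sa_values,
            interval.low,
            interval.high,
        )
        return self.body_len - pattern_len - rev_pos, False


@dataclass
class IndexBundle:
    """Reference text plus forward and reverse FM-indexes."""

    ref: ReferenceText
    fm: FMIndex
    fm_rev: FMIndex
    searcher: ForwardSearcher = field(init=False)

    def __post_init__(self) -> None:
        self.searcher = ForwardSearcher(self.fm_rev)

    @classmethod
    def build(
        cls,
        ref: ReferenceText,
        rank_stride: int = DEFAULT_RANK_STRIDE,
        sa_stride: int = DEFAULT_SA_STRIDE,
    ) -> "IndexBundle":
        fm = build_fm_index(ref, rank_stride, sa_stride)
        rev_codes = np.concatenate((ref.codes[-2::-1], ref.codes[-1:]))
        fm_rev = build_fm_index(rev_codes, rank_stride, sa_stride)
        return cls(ref=ref, fm=fm, fm_rev=fm_rev)
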