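"""Coherent grouping of seed occurrences into multi-seed candidates.

All located occurrences of a read's anchor seeds are sorted by reference
position and scanned once from left to right.  The running chain is
extended by the next occurrence whenever the coherence predicate holds —
seed order respected, both positions in the same reference segment, and
the reference distance within slack of the read distance — otherwise the
chain is closed and a new one starts.  This keeps the number of coherence
tests linear in the number of occurrences instead of the product of
per-seed occurrence counts.

Each seed contributes the occurrences of its *rare prefix* (the shortest
prefix at or below the occurrence cap); positions where the full maximal
match occurs are credited with the full length.  Occurrences therefore
carry their own matched length and read start, which the coherence
arithmetic and the extension stage use in place of the seed fields.

Two refinements harden the mapper's internal path (the public functions
keep the strict single-pass partition semantics):

* bounded-lookback chaining — an isolated chance occurrence that lands
  inside another chain's window starts its own chain without cutting the
  chain it interrupted (``ChainParams.lookback``);
* dense rescue anchoring — when no chain covers a useful fraction of the
  read (heavily corrupted reads whose seed starts all sit near errors),
  anchors are re-derived from every homopolymer start of the read rather
  than only from the greedy seed decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._codes import encode_seq
from .config import ChainParams, SeedingParams
from .fmindex import IndexBundle, SAInterval
from .seeding import Read, SeedSet


@dataclass(frozen=True)
class SeedOccurrence:
    """One exact occurrence of (a prefix of) a seed on the reference."""

    seed_index: int
    pos: int  # global 0-based start
    segment: int  # index into ReferenceText.segments
    length: int  # matched bases at this occurrence
    read_start: int  # read position of the matched bases


@dataclass
class Chain:
    """A coherent, order-respecting run of seed occurrences."""

    occurrences: list[SeedOccurrence]
    slacks: list[int] = field(default_factory=list)  # eps used at each link
    span: int = 0  # read bases covered by the anchors

    def __len__(self) -> int:
        return len(self.occurrences)

    @property
    def first_pos(self) -> int:
        return self.occurrences[0].pos

    @property
    def segment(self) -> int:
        return self.occurrences[0].segment


def _segment_filter(bundle: IndexBundle, pos, idx, length, read_start):
    seg = np.searchsorted(bundle.ref._seg_starts, pos, side="right") - 1
    ends = np.array([s.gend for s in bundle.ref.segments], dtype=np.int64)
    ok = (seg >= 0) & (pos + length <= ends[np.clip(seg, 0, None)])
    return pos[ok], idx[ok], length[ok], read_start[ok], seg[ok]


def _occurrence_arrays(
    seedset: SeedSet, bundle: IndexBundle, max_occ: int | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sorted (pos, seed_idx, length, read_start, segment) arrays for all
    anchor seeds; full-length occurrences are upgraded in place."""
    pos_parts: list[np.ndarray] = []
    idx_parts: list[np.ndarray] = []
    len_parts: list[np.ndarray] = []
    rs_parts: list[np.ndarray] = []
    for seed in seedset.anchors():
        rare_pos, truncated = bundle.searcher.locate_forward_array(
            seed.rare_interval, seed.rare_len, max_occ
        )
        if truncated or len(rare_pos) == 0:
            continue
        lengths = np.full(len(rare_pos), seed.rare_len, dtype=np.int64)
        if seed.length > seed.rare_len:
            full_pos, _ = bundle.searcher.locate_forward_array(seed.interval, seed.length)
            lengths[np.isin(rare_pos, full_pos)] = seed.length
        pos_parts.append(rare_pos)
        idx_parts.append(np.full(len(rare_pos), seed.index, dtype=np.int64))
        len_parts.append(lengths)
        rs_parts.append(np.full(len(rare_pos), seed.read_start, dtype=np.int64))
    if not pos_parts:
        z = np.empty(0, dtype=np.int64)
        return z, z, z, z, z
    pos = np.concatenate(pos_parts)
    idx = np.concatenate(idx_parts)
    length = np.concatenate(len_parts)
    read_start = np.concatenate(rs_parts)
    order = np.lexsort((idx, pos))
    return _segment_filter(
        bundle, pos[order], idx[order], length[order], read_start[order]
    )


def _dense_anchor_arrays(
    codes: np.ndarray, bundle: IndexBundle, params: SeedingParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Rescue anchors: shortest informative match from every homopolymer
    start of the read (pyrosequencing errors sit on homopolymer
    boundaries, so these cursors tile all candidate exact stretches)."""
    m = len(codes)
    starts = np.flatnonzero(
        np.concatenate(([True], codes[1:] != codes[:-1]))
    ).astype(np.int64)
    fm = bundle.fm_rev
    lens, los, his = _kernels.rare_matches_k(
        fm.bwt,
        fm.checkpoints,
        fm.rank_stride,
        fm.cumcounts,
        codes,
        starts,
        params.effective_rare_cap,
        max(1, params.min_seed_len),
    )
    pos_parts, idx_parts, len_parts, rs_parts = [], [], [], []
    for k in range(len(starts)):
        if lens[k] == 0:
            continue
        fwd, _ = bundle.searcher.locate_forward_array(
            SAInterval(int(los[k]), int(his[k])), int(lens[k])
        )
        pos_parts.append(fwd)
        idx_parts.append(np.full(len(fwd), k, dtype=np.int64))
        len_parts.append(np.full(len(fwd), lens[k], dtype=np.int64))
        rs_parts.append(np.full(len(fwd), starts[k], dtype=np.int64))
    if not pos_parts:
        z = np.empty(0, dtype=np.int64)
        return z, z, z, z, z
    pos = np.concatenate(pos_parts)
    idx = np.concatenate(idx_parts)
    length = np.concatenate(len_parts)
    read_start = np.concatenate(rs_parts)
    order = np.lexsort((idx, pos))
    return _segment_filter(
        bundle, pos[order], idx[order], length[order], read_start[order]
    )


def collect_occurrences(
    seedset: SeedSet, bundle: IndexBundle, max_occ: int | None = None
) -> list[SeedOccurrence]:
    """Located anchor occurrences, sorted by position (ties: lower seed
    index first, making the greedy scan deterministic)."""
    pos, idx, length, read_start, seg = _occurrence_arrays(seedset, bundle, max_occ)
    return [
        SeedOccurrence(int(i), int(p), int(s), int(l), int(r))
        for p, i, l, r, s in zip(pos, idx, length, read_start, seg)
    ]


def coherent(
    prev: SeedOccurrence,
    nxt: SeedOccurrence,
    seedset: SeedSet | None = None,
    params: ChainParams | None = None,
) -> bool:
    """Order and distance test for two occurrences of distinct seeds.

    The read-side distance is taken between the matched blocks' read
    coordinates (concatenating any skipped regions in between), the
    reference distance between the occurrence ends; they must agree
    within ``eps = max(eps_min, ceil(rho * read_gap))``.
    """
    params = params or ChainParams()
    if nxt.seed_index <= prev.seed_index:
        return False
    if nxt.segment != prev.segment:
        return False
    if nxt.pos < prev.pos:
        return False
    read_gap = nxt.read_start - (prev.read_start + prev.length)
    genome_gap = nxt.pos - (prev.pos + prev.length)
    eps = params.eps_for_gap(read_gap)
    return abs(genome_gap - read_gap) <= eps


def chain_occurrences(
    occs: list[SeedOccurrence],
    seedset: SeedSet | None = None,
    params: ChainParams | None = None,
    stats: dict | None = None,
) -> list[Chain]:
    """Single left-to-right greedy pass partitioning ``occs`` into chains.

    The current chain is extended by the next occurrence iff coherent
    with the chain's last member; otherwise the chain is closed and a new
    one starts there.  Every occurrence belongs to exactly one chain;
    partial chains (not containing all seeds) are kept as candidates too.
    """
    params = params or ChainParams()
    chains: list[Chain] = []
    tests = 0
    cur: Chain | None = None
    for occ in occs:
        if cur is not None:
            tests += 1
        if cur is not None and coherent(cur.occurrences[-1], occ, seedset, params):
            prev = cur.occurrences[-1]
            cur.slacks.append(params.eps_for_gap(occ.read_start - (prev.read_start + prev.length)))
            cur.occurrences.append(occ)
            cur.span += occ.length
        else:
            cur = Chain(occurrences=[occ], span=occ.length)
            chains.append(cur)
    if stats is not None:
        stats["coherence_tests"] = tests
    return chains


def select_candidates(chains: list[Chain], top: int = 10) -> list[Chain]:
    """The ``top`` largest-span chains (ties leftmost first).

    Downstream extension breaks span near-ties by error count, which is
    what disambiguates a short true-locus chain from a chance occurrence
    of comparable span.
    """
    if not chains:
        return []
    return sorted(chains, key=lambda c: (-c.span, c.first_pos))[:top]


def _top_chains_from_arrays(
    arrays, params: ChainParams
) -> list[Chain]:
    pos, idx, length, read_start, seg = arrays
    n = len(pos)
    if n == 0:
        return []
    chain_id, nch, spans, first_occ = _kernels.chain_build_k(
        pos, idx, length, read_start, seg, params.eps_min, params.rho, params.lookback
    )
    spans = spans[:nch]
    first_occ = first_occ[:nch]
    order = np.lexsort((pos[first_occ], -spans))[: params.top]
    keep = np.isin(chain_id, order)
    out: dict[int, Chain] = {int(c): Chain(occurrences=[], span=int(spans[c])) for c in order}
    for k in np.flatnonzero(keep):
        c = int(chain_id[k])
        out[c].occurrences.append(
            SeedOccurrence(int(idx[k]), int(pos[k]), int(seg[k]), int(length[k]), int(read_start[k]))
        )
    return [out[int(c)] for c in order]


def best_candidate_chains(
    seedset: SeedSet,
    bundle: IndexBundle,
    chain_params: ChainParams | None = None,
    max_occ: int | None = None,
) -> list[Chain]:
    """Fused locate-sort-scan-select path used by the mapper.

    Equivalent in spirit to ``select_candidates(chain_occurrences(
    collect_occurrences(...)))`` but with bounded-lookback chaining,
    union-coverage spans, and only the selected chains materialised.
    """
    chain_params = chain_params or ChainParams()
    return _top_chains_from_arrays(
        _occurrence_arrays(seedset, bundle, max_occ), chain_params
    )


def rescue_candidate_chains(
    read: Read,
    bundle: IndexBundle,
    chain_params: ChainParams | None = None,
    seeding_params: SeedingParams | None = None,
) -> list[Chain]:
    """Dense-anchored candidates for reads whose seed chains are weak."""
    chain_params = chain_params or ChainParams()
    seeding_params = seeding_params or SeedingParams()
    codes = encode_seq(read.seq)
    return _top_chains_from_arrays(
        _dense_anchor_arrays(codes, bundle, seeding_params), chain_params
    )
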