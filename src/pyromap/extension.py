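"""Turn candidate chains into full alignments.

Seed blocks are taken as exact-match runs; each inter-anchor pair of
read/reference segments is aligned by a banded Needleman-Wunsch DP with
Gotoh's affine-gap modification, and the two read ends are aligned
semi-globally against reference windows so that reference overhang beyond
the read is free.  The blocks are stitched into one edit path covering
the entire read, and the finished mapping is accepted either by a minimum
percent identity ``t`` or by a maximum error count ``e``.

Costs are edit-distance-like (match 0), because acceptance is error-based
rather than similarity-based; identity is matches over alignment columns
and errors are mismatch plus gap *bases* (not gap events).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._codes import encode_seq
from .chaining import Chain, best_candidate_chains, rescue_candidate_chains
from .config import AcceptParams, RunConfig, ScoringScheme
from .fmindex import IndexBundle
from .seeding import Read, extract_seeds

_BIG = int(_kernels.BIG)

# traceback states
_M, _X, _Y = 0, 1, 2


def _rle(ops: list[str]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op in ops:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + 1)
        else:
            out.append((op, 1))
    return out


@dataclass
class AlignmentBlock:
    """One aligned stretch: run-length encoded ops over {=, X, I, D}."""

    ops: list[tuple[str, int]]
    cost: int

    @property
    def matches(self) -> int:
        return sum(n for op, n in self.ops if op == "=")

    @property
    def mismatches(self) -> int:
        return sum(n for op, n in self.ops if op == "X")

    @property
    def ins_bases(self) -> int:
        return sum(n for op, n in self.ops if op == "I")

    @property
    def del_bases(self) -> int:
        return sum(n for op, n in self.ops if op == "D")

    @property
    def read_span(self) -> int:
        return self.matches + self.mismatches + self.ins_bases

    @property
    def ref_span(self) -> int:
        return self.matches + self.mismatches + self.del_bases


_EMPTY_BLOCK = AlignmentBlock(ops=[], cost=0)


def _pick_state(m: int, x: int, y: int) -> int:
    """Deterministic tie-break: match/mismatch beats insert beats delete."""
    best = _M
    val = m
    if x < val:
        best, val = _X, x
    if y < val:
        best, val = _Y, y
    return best


def _traceback(a, b, M, X, Y, scoring: ScoringScheme, i: int, j: int, state: int) -> list[str]:
    """Recover the op string (read order) ending at cell (i, j) in ``state``."""
    go, ge, mm = scoring.gap_open, scoring.gap_extend, scoring.mismatch
    ops_rev: list[str] = []
    while i > 0 or j > 0:
        if state == _M:
            sub = 0 if a[i - 1] == b[j - 1] else mm
            ops_rev.append("=" if sub == 0 else "X")
            target = M[i, j] - sub
            i -= 1
            j -= 1
            state = _pick_state(
                M[i, j] if M[i, j] == target else _BIG,
                X[i, j] if X[i, j] == target else _BIG,
                Y[i, j] if Y[i, j] == target else _BIG,
            )
        elif state == _X:
            ops_rev.append("I")
            target = X[i, j]
            i -= 1
            state = _pick_state(
                M[i, j] if M[i, j] + go + ge == target else _BIG,
                X[i, j] if X[i, j] + ge == target else _BIG,
                Y[i, j] if Y[i, j] + go + ge == target else _BIG,
            )
        else:
            ops_rev.append("D")
            target = Y[i, j]
            j -= 1
            state = _pick_state(
                M[i, j] if M[i, j] + go + ge == target else _BIG,
                X[i, j] if X[i, j] + go + ge == target else _BIG,
                Y[i, j] if Y[i, j] + ge == target else _BIG,
            )
    return ops_rev[::-1]


def _band(la: int, lb: int, scoring: ScoringScheme) -> tuple[int, int]:
    # indel drift accumulates along the segment, so the padding scales
    # with segment length on top of the fixed term
    pad = scoring.band_pad + int(scoring.band_scale * min(la, lb))
    delta = lb - la
    return min(0, delta) - pad, max(0, delta) + pad


def banded_affine_align(a: np.ndarray, b: np.ndarray, scoring: ScoringScheme | None = None) -> AlignmentBlock:
    """Global banded affine-gap alignment of read segment ``a`` vs reference
    segment ``b``; optimal whenever the true path stays inside the band."""
    scoring = scoring or ScoringScheme()
    a = np.asarray(a, dtype=np.uint8)
    b = np.asarray(b, dtype=np.uint8)
    la, lb = len(a), len(b)
    if la == 0 and lb == 0:
        return _EMPTY_BLOCK
    if la == 0:
        return AlignmentBlock([("D", lb)], scoring.gap_open + lb * scoring.gap_extend)
    if lb == 0:
        return AlignmentBlock([("I", la)], scoring.gap_open + la * scoring.gap_extend)
    blo, bhi = _band(la, lb, scoring)
    M, X, Y = _kernels.gotoh_band_k(
        a, b, scoring.mismatch, scoring.gap_open, scoring.gap_extend, blo, bhi
    )
    state = _pick_state(M[la, lb], X[la, lb], Y[la, lb])
    cost = int(min(M[la, lb], X[la, lb], Y[la, lb]))
    ops = _traceback(a, b, M, X, Y, scoring, la, lb, state)
    return AlignmentBlock(_rle(ops), cost)


def semiglobal_end_align(
    segment: np.ndarray,
    window: np.ndarray,
    scoring: ScoringScheme | None = None,
    end: str = "right",
) -> AlignmentBlock:
    """Align a read-end segment to a reference window.

    Reference overhang at the *outer* end (right of a right-end segment,
    left of a left-end one) is cost-free; every read symbol is consumed.
    """
    scoring = scoring or ScoringScheme()
    a = np.asarray(segment, dtype=np.uint8)
    b = np.asarray(window, dtype=np.uint8)
    if end == "left":
        inner = semiglobal_end_align(a[::-1], b[::-1], scoring, end="right")
        return AlignmentBlock(inner.ops[::-1], inner.cost)
    la, lb = len(a), len(b)
    if la == 0:
        return _EMPTY_BLOCK
    if lb == 0:
        return AlignmentBlock([("I", la)], scoring.gap_open + la * scoring.gap_extend)
    blo, bhi = _band(la, lb, scoring)
    M, X, Y = _kernels.gotoh_band_k(
        a, b, scoring.mismatch, scoring.gap_open, scoring.gap_extend, blo, bhi
    )
    best_j, best_cost, best_state = -1, _BIG, _M
    for j in range(max(0, la + blo), min(lb, la + bhi) + 1):
        state = _pick_state(M[la, j], X[la, j], Y[la, j])
        cost = int(min(M[la, j], X[la, j], Y[la, j]))
        if cost < best_cost:
            best_j, best_cost, best_state = j, cost, state
    ops = _traceback(a, b, M, X, Y, scoring, la, best_j, best_state)
    return AlignmentBlock(_rle(ops), best_cost)


@dataclass
class Mapping:
    """A finished whole-read alignment."""

    read_id: str
    ref_name: str
    ref_start: int  # 0-based, record-local
    gstart: int  # 0-based, global text coordinate
    strand: str  # "+" | "-"
    cigar: list[tuple[str, int]]  # ops over {=, X, I, D}, read order
    matches: int
    mismatches: int
    ins_bases: int
    del_bases: int
    cost: int
    seq: str  # read sequence as aligned (reverse-complemented on "-")
    qual: str | None = None
    accepted: bool = False

    @property
    def errors(self) -> int:
        return self.mismatches + self.ins_bases + self.del_bases

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.ins_bases + self.del_bases

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    @property
    def ref_span(self) -> int:
        return self.matches + self.mismatches + self.del_bases

    @property
    def read_span(self) -> int:
        return self.matches + self.mismatches + self.ins_bases

    @property
    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)


def extend_chain(
    read: Read,
    bundle: IndexBundle,
    chain: Chain,
    scoring: ScoringScheme | None = None,
) -> Mapping | None:
    """Expand one coherent chain into a whole-read mapping.

    Anchor occurrences that overlap the previous anchor on the read or
    the reference (possible for dense rescue anchors, or for occurrences
    admitted within slack) are dropped greedily; seed blocks become
    all-match runs, inter-anchor gaps are aligned globally and the read
    ends semi-globally.  Returns ``None`` only when no usable anchor
    remains.
    """
    scoring = scoring or ScoringScheme()
    codes = encode_seq(read.seq)
    # greedy non-overlap filter: rescue anchors may overlap on the read
    anchors: list[tuple[int, int, int]] = []
    for o in chain.occurrences:
        if anchors:
            rs_prev, l_prev, p_prev = anchors[-1]
            if o.read_start < rs_prev + l_prev or o.pos < p_prev + l_prev:
                continue
        anchors.append((o.read_start, o.length, o.pos))
    if not anchors:
        return None
    seg = bundle.ref.segments[chain.segment]
    ops: list[tuple[str, int]] = []
    cost = 0

    rs0, _, p0 = anchors[0]
    left_read = codes[:rs0]
    wlen = len(left_read) + scoring.end_slack + int(scoring.end_scale * len(left_read))
    wstart = max(seg.gstart, p0 - wlen)
    left = semiglobal_end_align(left_read, bundle.ref.codes[wstart:p0], scoring, end="left")
    ops.extend(left.ops)
    cost += left.cost
    start = p0 - left.ref_span

    for k, (rs, length, p) in enumerate(anchors):
        ops.append(("=", length))
        if k + 1 < len(anchors):
            rs2, _, p2 = anchors[k + 1]
            block = banded_affine_align(codes[rs + length : rs2], bundle.ref.codes[p + length : p2], scoring)
            ops.extend(block.ops)
            cost += block.cost

    rs_last, l_last, p_last = anchors[-1]
    pe = p_last + l_last
    right_read = codes[rs_last + l_last :]
    wlen = len(right_read) + scoring.end_slack + int(scoring.end_scale * len(right_read))
    wend = min(seg.gend, pe + wlen)
    right = semiglobal_end_align(right_read, bundle.ref.codes[pe:wend], scoring, end="right")
    ops.extend(right.ops)
    cost += right.cost

    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))

    nmatch = sum(n for op, n in merged if op == "=")
    nmis = sum(n for op, n in merged if op == "X")
    nins = sum(n for op, n in merged if op == "I")
    ndel = sum(n for op, n in merged if op == "D")
    assert nmatch + nmis + nins == len(codes), "edit path must consume the full read"

    ref_name, local = bundle.ref.to_record(start)
    return Mapping(
        read_id=read.id,
        ref_name=ref_name,
        ref_start=local,
        gstart=start,
        strand="+",
        cigar=merged,
        matches=nmatch,
        mismatches=nmis,
        ins_bases=nins,
        del_bases=ndel,
        cost=cost,
        seq=read.seq,
        qual=read.qual,
    )


def accept_mapping(mapping: Mapping, params: AcceptParams | None = None) -> bool:
    params = params or AcceptParams()
    if params.mode == "identity":
        return mapping.identity * 100.0 >= params.t
    return mapping.errors <= params.e


def map_read(read: Read, bundle: IndexBundle, config: RunConfig | None = None) -> list[Mapping]:
    """Seed, chain and extend a read on both orientations.

    Returns accepted mappings; ``report="best"`` keeps only those with the
    minimum error count, ordered by (errors, leftmost position, forward
    strand first).  Unmapped reads yield an empty list.
    """
    config = config or RunConfig()
    per_strand: dict[str, tuple[Read, list[Chain]]] = {}
    for strand in ("+", "-"):
        oriented = read if strand == "+" else read.reverse_complement()
        seedset = extract_seeds(oriented, bundle.searcher, config.seeding)
        candidates = best_candidate_chains(
            seedset, bundle, config.chaining, config.seeding.max_occ
        )
        per_strand[strand] = (oriented, candidates)
    # dense rescue: when no strand produced a chain covering a useful
    # fraction of the read, re-anchor from every homopolymer start
    best_span = max(
        (c.span for _, cands in per_strand.values() for c in cands), default=0
    )
    threshold = max(
        config.seeding.rescue_min_span,
        int(config.seeding.rescue_span_frac * len(read)),
    )
    if config.seeding.rescue and best_span < threshold:
        for strand, (oriented, cands) in per_strand.items():
            dense = rescue_candidate_chains(
                oriented, bundle, config.chaining, config.seeding
            )
            merged = sorted(cands + dense, key=lambda c: (-c.span, c.first_pos))
            per_strand[strand] = (oriented, merged[: config.chaining.top])
    results: list[Mapping] = []
    for strand, (oriented, candidates) in per_strand.items():
        for cand in candidates:
            mapping = extend_chain(oriented, bundle, cand, config.scoring)
            if mapping is None:
                continue
            mapping.strand = strand
            mapping.accepted = accept_mapping(mapping, config.accept)
            if mapping.accepted:
                results.append(mapping)
    unique: dict[tuple, Mapping] = {}
    for m in results:
        unique.setdefault((m.gstart, m.strand, m.cigar_string), m)
    ordered = sorted(
        unique.values(), key=lambda m: (m.errors, m.gstart, 0 if m.strand == "+" else 1)
    )
    if config.report == "best" and ordered:
        best = ordered[0].errors
        ordered = [m for m in ordered if m.errors == best]
    return ordered
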