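"""Greedy decomposition of a read into maximal exact-match seeds.

From a cursor, the longest read prefix with at least one exact occurrence
in the reference becomes a seed.  The symbol that blocked the match is
then skipped: if it differs from the last matched symbol the cursor
advances by exactly one position (a putative substitution), while if it
repeats the last matched symbol the difference sits inside a homopolymer
(a putative pyrosequencing indel) and the cursor jumps to the start of
the next homopolymer.  The process repeats to the read end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._codes import encode_seq, revcomp
from .config import SeedingParams
from .fmindex import ForwardSearcher, SAInterval


@dataclass
class Read:
    """A sequencing read; quality is carried through but never used."""

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if len(self.seq) == 0:
            raise ValueError(f"read {self.id!r} is empty")
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "Read":
        q = self.qual[::-1] if self.qual is not None else None
        return Read(self.id, revcomp(self.seq), q)


@dataclass
class Seed:
    """One maximal exact-match block of the read.

    Besides the full maximal match, the seed remembers its *rare prefix*:
    the shortest prefix whose occurrence count is already at or below the
    configured cap.  Chains are anchored on rare-prefix occurrences (with
    full-length occurrences upgraded to the full length), because a
    maximal match can overshoot a sequencing error through a chance
    occurrence elsewhere in the genome, which would otherwise hide the
    read's true locus from the chaining stage entirely.
    """

    index: int  # position in read order, 0-based
    read_start: int
    length: int
    interval: SAInterval  # rows of the reverse-text index, full-length match
    occ_count: int
    rare_len: int  # shortest prefix length with occ_count <= cap (0: none)
    rare_interval: SAInterval
    truncated: bool  # even the full match has more occurrences than the cap
    is_anchor: bool  # usable for chaining
    skip_kind: str  # "mismatch" | "homopolymer" | "read-end" after this seed

    @property
    def read_end(self) -> int:
        return self.read_start + self.length


@dataclass
class SeedSet:
    """Ordered, non-overlapping seeds of one read (possibly empty)."""

    read: Read
    seeds: list[Seed] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seeds)

    def gap_between(self, i: int, j: int) -> int:
        """Read symbols skipped between seeds ``i`` and ``j`` (i < j).

        When intermediate seeds are absent from a chain this is the
        concatenated length of all skipped regions and absent seeds.
        """
        a, b = self.seeds[i], self.seeds[j]
        return b.read_start - a.read_end

    def anchors(self) -> list[Seed]:
        return [s for s in self.seeds if s.is_anchor]


def homopolymer_runs(seq: str) -> list[tuple[str, int]]:
    """Maximal runs of identical symbols; a single base is a run of length 1."""
    runs: list[tuple[str, int]] = []
    for ch in seq:
        if runs and runs[-1][0] == ch:
            runs[-1] = (ch, runs[-1][1] + 1)
        else:
            runs.append((ch, 1))
    return runs


def extract_seeds(read: Read, searcher: ForwardSearcher, params: SeedingParams | None = None) -> SeedSet:
    """Decompose ``read`` into seeds using the greedy maximal-match procedure."""
    params = params or SeedingParams()
    codes = encode_seq(read.seq)
    m = len(codes)
    seeds: list[Seed] = []
    cursor = 0
    while cursor < m:
        length, interval, rare_len, rare_interval = searcher.match_interval(
            codes, cursor, rare_cap=params.effective_rare_cap, min_len=params.min_seed_len
        )
        if length == 0:
            # first symbol absent from the reference (or not ACGT):
            # treated as the mismatch-skip case
            cursor += 1
            continue
        occ = len(interval)
        truncated = occ > params.max_occ
        end = cursor + length
        if end >= m:
            skip_kind = "read-end"
            next_cursor = m
        elif codes[end] != codes[end - 1]:
            skip_kind = "mismatch"
            next_cursor = end + 1
        else:
            skip_kind = "homopolymer"
            j = end + 1
            while j < m and codes[j] == codes[j - 1]:
                j += 1
            # if the homopolymer runs to the read end there is no next
            # homopolymer to resume from: seeding terminates
            next_cursor = j if j < m else m
        seeds.append(
            Seed(
                index=len(seeds),
                read_start=cursor,
                length=length,
                interval=interval,
                occ_count=occ,
                rare_len=rare_len,
                rare_interval=rare_interval,
                truncated=truncated,
                is_anchor=rare_len > 0,
                skip_kind=skip_kind,
            )
        )
        cursor = next_cursor
    return SeedSet(read=read, seeds=seeds)


def dump_seeds_bed(seedset: SeedSet) -> str:
    """Diagnostic BED-like dump: read id, start, end, occurrence count."""
    rows = [
        f"{seedset.read.id}\t{s.read_start}\t{s.read_end}\t{s.occ_count}"
        for s in seedset.seeds
    ]
    return "\n".join(rows)
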