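"""Encoded reference text with segment-aware coordinate bookkeeping.

Reference records are uppercased, concatenated and terminated by a single
sentinel.  Records are joined by separator symbols, and every maximal run
of non-ACGT symbols (ambiguity codes, usually ``N``) inside a record is
collapsed to one separator that splits the record into distinct segments.
Alignments therefore can never cross a record boundary or an ambiguous
stretch, and no sequence is ever fabricated in place of ambiguous bases.

Coordinates are 0-based half-open throughout; SAM emission converts to
1-based on output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._codes import SENTINEL, SEPARATOR, CODE_A, CODE_T, encode_seq, decode_codes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Segment:
    """A maximal gap-free stretch of one record, in global coordinates."""

    record: str
    gstart: int  # global start (inclusive)
    gend: int  # global end (exclusive)
    local_start: int  # offset of gstart within the original record

    def __len__(self) -> int:
        return self.gend - self.gstart


@dataclass
class ReferenceText:
    """Sentinel-terminated concatenation of reference records.

    Attributes
    ----------
    codes:
        ``uint8`` symbol array over {sentinel, separator, A, C, G, T};
        exactly one sentinel, at the end.
    segments:
        Sorted, disjoint :class:`Segment` intervals covering every base.
    records:
        ``(record id, original record length)`` pairs, in input order,
        for records that contributed at least one base.
    """

    codes: np.ndarray
    segments: list[Segment]
    records: list[tuple[str, int]]
    _seg_starts: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._seg_starts = np.array([s.gstart for s in self.segments], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def alphabet_size(self) -> int:
        return 4

    def segment_index_of(self, gpos: int) -> int:
        """Index of the segment containing global position ``gpos`` (-1 if none)."""
        i = int(np.searchsorted(self._seg_starts, gpos, side="right")) - 1
        if i >= 0 and gpos < self.segments[i].gend:
            return i
        return -1

    def to_record(self, gpos: int) -> tuple[str, int]:
        """Map a global position to ``(record id, record-local offset)``."""
        i = self.segment_index_of(gpos)
        if i < 0:
            raise ValueError(f"global position {gpos} is not inside any segment")
        seg = self.segments[i]
        return seg.record, seg.local_start + (gpos - seg.gstart)

    def to_global(self, record: str, offset: int) -> int:
        """Inverse of :meth:`to_record` for positions inside a segment."""
        for seg in self.segments:
            if seg.record == record and seg.local_start <= offset < seg.local_start + len(seg):
                return seg.gstart + (offset - seg.local_start)
        raise ValueError(f"({record!r}, {offset}) is not inside any segment")

    def decode(self, gstart: int, gend: int) -> str:
        return decode_codes(self.codes[gstart:gend])


def encode_reference(records: list[tuple[str, str]]) -> ReferenceText:
    """Build a :class:`ReferenceText` from ``(id, sequence)`` records.

    Records with no ACGT symbol at all are dropped with a warning; an
    empty input (or input where every record is dropped) is an error.
    """
    if not records:
        raise ValueError("reference must contain at least one record")

    pieces: list[np.ndarray] = []
    segments: list[Segment] = []
    kept: list[tuple[str, int]] = []
    gpos = 0
    sep = np.array([SEPARATOR], dtype=np.uint8)

    for rid, seq in records:
        codes = encode_seq(seq)
        good = (codes >= CODE_A) & (codes <= CODE_T)
        if not good.any():
            logger.warning("record %r has no ACGT symbols; dropped", rid)
            continue
        if kept:
            pieces.append(sep)
            gpos += 1
        kept.append((rid, len(seq)))
        # maximal clean runs -> segments; maximal dirty runs -> one separator
        boundaries = np.flatnonzero(np.diff(good.astype(np.int8))) + 1
        run_starts = np.concatenate(([0], boundaries))
        run_ends = np.concatenate((boundaries, [len(codes)]))
        for rs, re_ in zip(run_starts, run_ends):
            rs, re_ = int(rs), int(re_)
            if good[rs]:
                segments.append(Segment(rid, gpos, gpos + (re_ - rs), rs))
                pieces.append(codes[rs:re_])
                gpos += re_ - rs
            else:
                pieces.append(sep)
                gpos += 1

    if not kept:
        raise ValueError("no reference record contains ACGT symbols")

    pieces.append(np.array([SENTINEL], dtype=np.uint8))
    text = np.concatenate(pieces)
    return ReferenceText(codes=text, segments=segments, records=kept)
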