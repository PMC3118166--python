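"""File formats: FASTA/FASTQ input, SAM output, truth tables, index files."""

from __future__ import annotations

import json
import logging
import struct
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

from . import __version__
from .fmindex import FMIndex, IndexBundle
from .reference import ReferenceText, Segment
from .seeding import Read
from .extension import Mapping
from .simulator import SimulatedReadSet

logger = logging.getLogger(__name__)

INDEX_MAGIC = b"PYROMIDX"
INDEX_VERSION = 1


class IndexFormatError(ValueError):
    pass


# ---------------------------------------------------------------- sequences


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Multi-record FASTA (wrapped lines, case preserved) as (id, seq) pairs."""
    try:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    except ValueError as exc:
        raise ValueError(f"malformed FASTA in {path}: {exc}") from exc
    if not records:
        logger.warning("no records found in %s", path)
    return records


def read_reads(path: str | Path) -> Iterator[Read]:
    """Stream reads from FASTA or FASTQ, auto-detected by leading character."""
    path = Path(path)
    fmt = None
    with open(path) as fh:
        for line in fh:
            if line.strip():
                fmt = "fastq" if line[0] == "@" else "fasta"
                break
    if fmt is None:
        logger.warning("empty reads file %s", path)
        return
    for rec in SeqIO.parse(str(path), fmt):
        qual = None
        if fmt == "fastq":
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield Read(rec.id, str(rec.seq), qual)


def write_reads(readset: SimulatedReadSet, path: str | Path, fmt: str = "fasta") -> None:
    """Write simulated reads as FASTA or FASTQ (uniform quality)."""
    with open(path, "w") as fh:
        for sim in readset.reads:
            if fmt == "fasta":
                fh.write(f">{sim.read.id}\n{sim.read.seq}\n")
            else:
                fh.write(f"@{sim.read.id}\n{sim.read.seq}\n+\n{'I' * len(sim.read.seq)}\n")


# ------------------------------------------------------------- truth tables

_TRUTH_HEADER = "#read_id\trecord\tstart\tlength\tstrand\tn_sub\tn_ins_bases\tn_del_bases"


def write_truth_table(readset: SimulatedReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_TRUTH_HEADER + "\n")
        for sim in readset.reads:
            t = sim.truth
            fh.write(
                f"{sim.read.id}\t{t.source}\t{t.start}\t{t.length}\t{t.strand}"
                f"\t{t.n_sub}\t{t.n_ins_bases}\t{t.n_del_bases}\n"
            )


def read_truth_table(path: str | Path) -> dict[str, tuple[str, int, int, str]]:
    """Truth rows keyed by read id: (record, start, length, strand)."""
    out: dict[str, tuple[str, int, int, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            out[fields[0]] = (fields[1], int(fields[2]), int(fields[3]), fields[4])
    return out


# --------------------------------------------------------------------- SAM


def write_sam(
    results: Iterable[tuple[Read, list[Mapping]]], ref: ReferenceText, path: str | Path
) -> None:
    """Emit mappings as SAM with =/X/I/D CIGAR operators and an NM tag.

    The first mapping of a read is primary; any further ones are marked
    secondary.  Unmapped reads get FLAG 4 and no coordinates.  Output
    order follows input read order.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for rid, length in ref.records:
            fh.write(f"@SQ\tSN:{rid}\tLN:{length}\n")
        fh.write(f"@PG\tID:pyromap\tPN:pyromap\tVN:{__version__}\n")
        for read, mappings in results:
            if not mappings:
                fh.write(f"{read.id}\t4\t*\t0\t0\t*\t*\t0\t0\t{read.seq}\t{read.qual or '*'}\n")
                continue
            for k, m in enumerate(mappings):
                flag = 0
                if m.strand == "-":
                    flag |= 16
                if k > 0:
                    flag |= 256
                fh.write(
                    f"{m.read_id}\t{flag}\t{m.ref_name}\t{m.ref_start + 1}\t255\t"
                    f"{m.cigar_string}\t*\t0\t0\t{m.seq}\t{m.qual or '*'}\tNM:i:{m.errors}\n"
                )


# ----------------------------------------------------------- index on disk
#
# Byte layout (little-endian):
#   bytes 0..7    magic "PYROMIDX"
#   bytes 8..11   uint32 format version (currently 1)
#   bytes 12..19  uint64 JSON header length H
#   bytes 20..20+H-1  UTF-8 JSON: text_len, rank_stride, sa_stride,
#                     records [[id, length]...], segments
#                     [[record, gstart, gend, local_start]...]
#   then raw arrays, in order: text (uint8[n]); for each of the forward
#   and reverse index: bwt uint8[n], cumcounts int64[6],
#   checkpoints int64[6 * (n // rank_stride + 1)], sa_marked uint8[n],
#   sa_values int64[n].


def save_index(bundle: IndexBundle, path: str | Path) -> None:
    n = len(bundle.ref.codes)
    header = {
        "text_len": n,
        "rank_stride": bundle.fm.rank_stride,
        "sa_stride": bundle.fm.sa_stride,
        "records": [[rid, int(length)] for rid, length in bundle.ref.records],
        "segments": [
            [s.record, int(s.gstart), int(s.gend), int(s.local_start)]
            for s in bundle.ref.segments
        ],
    }
    blob = json.dumps(header).encode()
    with open(path, "wb") as fh:
        fh.write(INDEX_MAGIC)
        fh.write(struct.pack("<IQ", INDEX_VERSION, len(blob)))
        fh.write(blob)
        fh.write(np.ascontiguousarray(bundle.ref.codes, dtype=np.uint8).tobytes())
        for fm in (bundle.fm, bundle.fm_rev):
            fh.write(np.ascontiguousarray(fm.bwt, dtype=np.uint8).tobytes())
            fh.write(np.ascontiguousarray(fm.cumcounts, dtype="<i8").tobytes())
            fh.write(np.ascontiguousarray(fm.checkpoints, dtype="<i8").tobytes())
            fh.write(np.ascontiguousarray(fm.sa_marked, dtype=np.uint8).tobytes())
            fh.write(np.ascontiguousarray(fm.sa_values, dtype="<i8").tobytes())


def _take(buf: memoryview, offset: int, nbytes: int, what: str) -> tuple[memoryview, int]:
    if offset + nbytes > len(buf):
        raise IndexFormatError(f"index file truncated while reading {what}")
    return buf[offset : offset + nbytes], offset + nbytes


def load_index(path: str | Path) -> IndexBundle:
    data = memoryview(Path(path).read_bytes())
    if len(data) < 20 or bytes(data[:8]) != INDEX_MAGIC:
        raise IndexFormatError(f"{path} is not a pyromap index file")
    version, hlen = struct.unpack("<IQ", data[8:20])
    if version != INDEX_VERSION:
        raise IndexFormatError(
            f"unsupported index format version {version} (expected {INDEX_VERSION})"
        )
    blob, off = _take(data, 20, hlen, "header")
    header = json.loads(bytes(blob).decode())
    n = header["text_len"]
    rank_stride = header["rank_stride"]
    sa_stride = header["sa_stride"]
    nck = 6 * (n // rank_stride + 1)

    raw, off = _take(data, off, n, "text")
    codes = np.frombuffer(raw, dtype=np.uint8)
    fms = []
    for which in ("forward", "reverse"):
        raw, off = _take(data, off, n, f"{which} bwt")
        bwt = np.frombuffer(raw, dtype=np.uint8)
        raw, off = _take(data, off, 6 * 8, f"{which} counts")
        cumcounts = np.frombuffer(raw, dtype="<i8")
        raw, off = _take(data, off, nck * 8, f"{which} checkpoints")
        checkpoints = np.frombuffer(raw, dtype="<i8").reshape(6, nck // 6)
        raw, off = _take(data, off, n, f"{which} SA marks")
        sa_marked = np.frombuffer(raw, dtype=np.uint8)
        raw, off = _take(data, off, n * 8, f"{which} SA samples")
        sa_values = np.frombuffer(raw, dtype="<i8")
        fms.append(
            FMIndex(
                bwt=bwt.copy(),
                cumcounts=cumcounts.copy(),
                checkpoints=checkpoints.copy(),
                sa_marked=sa_marked.copy(),
                sa_values=sa_values.copy(),
                rank_stride=rank_stride,
                sa_stride=sa_stride,
            )
        )
    if off != len(data):
        raise IndexFormatError("trailing bytes in index file")
    ref = ReferenceText(
        codes=codes.copy(),
        segments=[Segment(r, gs, ge, ls) for r, gs, ge, ls in header["segments"]],
        records=[(rid, length) for rid, length in header["records"]],
    )
    return IndexBundle(ref=ref, fm=fms[0], fm_rev=fms[1])
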