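"""Synthetic GS FLX pyrosequencing read generator and truth-based scoring.

Pyrosequencing reads one maximal homopolymer per flow, so its dominant
errors are homopolymer length over/under-calls.  The generator extracts
random subsequences of a source sequence (lengths Normal(mu_l, sigma_l)),
then visits each homopolymer run of the template and draws one mutually
exclusive event: a substitution with probability ``p_sub`` (one uniformly
chosen base of the run is miscalled according to a substitution matrix), an
insertion with probability ``p_ins`` (the run gains k copies of its base),
a deletion with probability ``p_del`` (the run loses min(k, run length)
bases), or no error.  Indel lengths k follow a truncated Zipf (power-law)
distribution ``P(k) = k^-gamma / sum_{j=1..omega} j^-gamma``.

Errors are uniform along the read and independent of homopolymer length —
a deliberate simplification relative to real instruments, where quality
decays toward the 3' end and long homopolymers are harder to call.
Every read carries an edit log; replaying it against the template must
reproduce the read exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._codes import revcomp
from .seeding import Read, homopolymer_runs

_BASES = "ACGT"


def zipf_pmf(omega: int, gamma: float) -> np.ndarray:
    """Mass function of the truncated power law on {1..omega}."""
    if omega < 1 or gamma <= 0:
        raise ValueError("require omega >= 1 and gamma > 0")
    k = np.arange(1, omega + 1, dtype=float)
    w = k**-gamma
    return w / w.sum()


def zipf_sample(omega: int, gamma: float, rng: np.random.Generator, size: int | None = None):
    """Draw gap length(s) in 1..omega from the truncated power law."""
    pmf = zipf_pmf(omega, gamma)
    cdf = np.cumsum(pmf)
    u = rng.random(size)
    out = np.searchsorted(cdf, u, side="right") + 1
    return out if size is not None else int(out)


@dataclass
class SimParams:
    """Generator configuration."""

    n_reads: int = 1000
    mu_len: float = 250.0
    sigma_len: float = 50.0
    p_sub: float = 0.01
    p_ins: float = 0.01
    p_del: float = 0.01
    omega: int = 10
    gamma_ins: float = 3.0
    gamma_del: float = 3.0
    #: substitution matrix, rows/cols ordered ACGT; sub_matrix[a, b] is the
    #: probability that a is miscalled as b; None means uniform 1/3 off-diagonal
    sub_matrix: np.ndarray | None = None
    both_strands: bool = False
    min_len: int = 30
    seed: int | None = None

    def validate(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")
        if not 0 <= self.p_sub + self.p_ins + self.p_del <= 1:
            raise ValueError("error probabilities must sum to at most 1")
        if self.omega < 1 or self.gamma_ins <= 0 or self.gamma_del <= 0:
            raise ValueError("invalid Zipf parameters")
        if self.sub_matrix is not None:
            m = np.asarray(self.sub_matrix, dtype=float)
            if m.shape != (4, 4) or not np.allclose(np.diag(m), 0) or not np.allclose(m.sum(axis=1), 1):
                raise ValueError("substitution matrix rows must sum to 1 with zero diagonal")

    def matrix(self) -> np.ndarray:
        if self.sub_matrix is not None:
            return np.asarray(self.sub_matrix, dtype=float)
        m = np.full((4, 4), 1.0 / 3.0)
        np.fill_diagonal(m, 0.0)
        return m


@dataclass(frozen=True)
class EditEvent:
    """One per-homopolymer event of the edit log.

    ``kind`` is "sub" (``pos`` = offset within the run, ``frm``/``to``
    bases), "ins" (``length`` extra copies of the run base) or "del"
    (``length`` bases removed, capped at the run length).
    """

    kind: str
    run_index: int
    pos: int = 0
    frm: str = ""
    to: str = ""
    length: int = 0


@dataclass
class ReadTruth:
    source: str
    start: int  # 0-based template origin on the source
    length: int  # template length
    strand: str
    edits: list[EditEvent] = field(default_factory=list)

    @property
    def n_sub(self) -> int:
        return sum(1 for e in self.edits if e.kind == "sub")

    @property
    def n_ins_bases(self) -> int:
        return sum(e.length for e in self.edits if e.kind == "ins")

    @property
    def n_del_bases(self) -> int:
        return sum(e.length for e in self.edits if e.kind == "del")


@dataclass
class SimulatedRead:
    read: Read
    truth: ReadTruth


@dataclass
class SimulatedReadSet:
    reads: list[SimulatedRead]
    params: SimParams
    source_id: str

    def __len__(self) -> int:
        return len(self.reads)


def replay_edits(template: str, edits: list[EditEvent]) -> str:
    """Apply an edit log to a template; must reproduce the simulated read."""
    runs = homopolymer_runs(template)
    by_run: dict[int, EditEvent] = {e.run_index: e for e in edits}
    parts: list[str] = []
    for idx, (base, rl) in enumerate(runs):
        e = by_run.get(idx)
        if e is None:
            parts.append(base * rl)
        elif e.kind == "sub":
            parts.append(base * e.pos + e.to + base * (rl - e.pos - 1))
        elif e.kind == "ins":
            parts.append(base * (rl + e.length))
        else:
            parts.append(base * (rl - e.length))
    return "".join(parts)


def simulate_read(
    source: str,
    start: int,
    length: int,
    params: SimParams,
    rng: np.random.Generator,
    source_id: str = "source",
) -> SimulatedRead:
    """Extract ``source[start:start+length]`` and corrupt it run by run."""
    if start < 0 or start + length > len(source):
        raise ValueError("template extraction out of range")
    template = source[start : start + length]
    runs = homopolymer_runs(template)
    matrix = params.matrix()
    p_sub, p_ins, p_del = params.p_sub, params.p_ins, params.p_del
    u = rng.random(len(runs))
    parts: list[str] = []
    edits: list[EditEvent] = []
    for idx, (base, rl) in enumerate(runs):
        ui = u[idx]
        if ui < p_sub:
            pos = int(rng.integers(rl))
            row = matrix[_BASES.index(base)]
            to = _BASES[int(rng.choice(4, p=row))]
            parts.append(base * pos + to + base * (rl - pos - 1))
            edits.append(EditEvent("sub", idx, pos=pos, frm=base, to=to))
        elif ui < p_sub + p_ins:
            k = zipf_sample(params.omega, params.gamma_ins, rng)
            parts.append(base * (rl + k))
            edits.append(EditEvent("ins", idx, length=k))
        elif ui < p_sub + p_ins + p_del:
            k = min(zipf_sample(params.omega, params.gamma_del, rng), rl)
            parts.append(base * (rl - k))
            edits.append(EditEvent("del", idx, length=k))
        else:
            parts.append(base * rl)
    seq = "".join(parts)
    truth = ReadTruth(source=source_id, start=start, length=length, strand="+", edits=edits)
    return SimulatedRead(read=Read("sim", seq), truth=truth)


def generate_read_set(
    source: str,
    params: SimParams,
    rng: np.random.Generator | int | None = None,
    source_id: str = "source",
) -> SimulatedReadSet:
    """Draw ``n_reads`` error-bearing reads from ``source``.

    Lengths are Normal(mu_len, sigma_len) rounded and clamped to
    ``[min_len, len(source)]``; starts are uniform over valid positions.
    Bit-for-bit reproducible for a fixed seed.
    """
    params.validate()
    if len(source) <= params.mu_len:
        raise ValueError("source must be longer than the mean read length")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    sims: list[SimulatedRead] = []
    for i in range(params.n_reads):
        length = int(round(rng.normal(params.mu_len, params.sigma_len)))
        length = max(params.min_len, min(length, len(source)))
        start = int(rng.integers(0, len(source) - length + 1))
        sim = simulate_read(source, start, length, params, rng, source_id=source_id)
        sim.read.id = f"sim_{i:06d}"
        if params.both_strands and rng.random() < 0.5:
            sim.read.seq = revcomp(sim.read.seq)
            sim.truth.strand = "-"
        sims.append(sim)
    return SimulatedReadSet(reads=sims, params=params, source_id=source_id)


def evaluate_accuracy(
    best_mappings: dict[str, object | None],
    truth: SimulatedReadSet,
    tolerance: int = 10,
) -> float:
    """Fraction of reads mapped back to their original positions.

    ``best_mappings`` maps read id to the best mapping (anything exposing
    ``ref_name``, ``ref_start`` and ``strand``) or ``None`` when unmapped.
    A read counts as correct iff mapped to the true source record, on the
    true strand, with start within ``tolerance`` bases of the true origin.
    """
    rows = {
        sim.read.id: (sim.truth.source, sim.truth.start, sim.truth.strand)
        for sim in truth.reads
    }
    return evaluate_accuracy_rows(best_mappings, rows, tolerance)


def evaluate_accuracy_rows(
    best_mappings: dict[str, object | None],
    truth_rows: dict[str, tuple[str, int, str]],
    tolerance: int = 10,
) -> float:
    """Same scoring as :func:`evaluate_accuracy` over plain truth rows
    ``read id -> (record, true start, strand)``."""
    if not truth_rows:
        return 0.0
    correct = 0
    for rid, (source, start, strand) in truth_rows.items():
        m = best_mappings.get(rid)
        if m is None:
            continue
        if m.ref_name == source and m.strand == strand and abs(m.ref_start - start) <= tolerance:
            correct += 1
    return correct / len(truth_rows)


def matches_per_error(mappings: list) -> float | None:
    """Pooled base-pair matches per error over accepted mappings.

    The denominator is floored at 1; an empty input is undefined and
    reported as ``None``.
    """
    accepted = [m for m in mappings if getattr(m, "accepted", True)]
    if not accepted:
        return None
    total_matches = sum(m.matches for m in accepted)
    total_errors = sum(m.errors for m in accepted)
    return total_matches / max(1, total_errors)
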