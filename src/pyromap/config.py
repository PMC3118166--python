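"""Tunable parameters for indexing, seeding, chaining, extension, acceptance."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class IndexParams:
    rank_stride: int = 128
    sa_stride: int = 32

    def validate(self) -> None:
        if self.rank_stride < 1 or self.sa_stride < 1:
            raise ValueError("index strides must be positive")


@dataclass
class SeedingParams:
    #: anchors whose rare-prefix length is below this are still emitted as
    #: seeds but excluded from chaining; their read span is recovered by
    #: the gap-filling DP
    min_seed_len: int = 5
    #: occurrence cap: a seed anchors chains at the shortest prefix with at
    #: most this many occurrences; seeds that never get this rare are
    #: flagged truncated and excluded from chaining
    max_occ: int = 200
    #: rarity threshold for the anchoring prefix; defaults to max_occ.
    #: 1 anchors every seed at its full maximal-match length only.
    rare_cap: int | None = None
    #: when the best chain covers less than rescue_span_frac of the read
    #: (and at least rescue_min_span bases), re-anchor densely from every
    #: homopolymer start instead of only from seed starts
    rescue: bool = True
    rescue_span_frac: float = 0.125
    rescue_min_span: int = 16

    def validate(self) -> None:
        if self.min_seed_len < 1 or self.max_occ < 1:
            raise ValueError("seeding parameters must be positive")
        if self.rare_cap is not None and self.rare_cap < 1:
            raise ValueError("rare_cap must be positive")

    @property
    def effective_rare_cap(self) -> int:
        return self.rare_cap if self.rare_cap is not None else self.max_occ


@dataclass
class ChainParams:
    """Coherence slack policy: eps(gap) = max(eps_min, ceil(rho * gap)).

    Homopolymer indels make the reference-vs-read distance between two
    anchors drift like a random walk in the gap length, so the slack
    grows with the gap; the defaults cover ~3 sigma of drift at a 10%
    per-homopolymer indel rate.
    """

    eps_min: int = 8
    rho: float = 0.25
    #: number of largest-span candidates extended per read and strand
    top: int = 10
    #: recent chains the greedy scan may extend; 1 reproduces the strict
    #: partition into runs of consecutive coherent occurrences
    lookback: int = 4

    def validate(self) -> None:
        if self.eps_min < 0 or self.rho < 0 or self.top < 1 or self.lookback < 1:
            raise ValueError("invalid chaining parameters")

    def eps_for_gap(self, read_gap: int) -> int:
        import math

        return max(self.eps_min, math.ceil(self.rho * read_gap))


@dataclass
class ScoringScheme:
    """Edit-distance-like affine costs; match is free, a gap of length k
    costs ``gap_open + k * gap_extend``."""

    mismatch: int = 1
    gap_open: int = 1
    gap_extend: int = 1
    #: band half-padding added around the length-difference corridor;
    #: grows with segment length (band_pad + band_scale * min(len a, len b))
    #: because homopolymer indel drift accumulates along the segment
    band_pad: int = 8
    band_scale: float = 0.125
    #: extra reference bases exposed beyond each read end, plus an
    #: end_scale fraction of the end segment's length
    end_slack: int = 16
    end_scale: float = 0.25

    def validate(self) -> None:
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("costs must be non-negative")
        if self.band_pad < 0 or self.end_slack < 0:
            raise ValueError("band_pad and end_slack must be non-negative")
        if self.band_scale < 0 or self.end_scale < 0:
            raise ValueError("band_scale and end_scale must be non-negative")


@dataclass
class AcceptParams:
    """Accept a finished alignment by identity threshold or error budget."""

    mode: str = "identity"  # "identity" | "errors"
    t: float = 50.0  # minimum percent identity
    e: int = 0  # maximum error bases (errors mode)

    def validate(self) -> None:
        if self.mode not in ("identity", "errors"):
            raise ValueError("mode must be 'identity' or 'errors'")
        if not 0 <= self.t <= 100:
            raise ValueError("identity threshold must be in [0, 100]")
        if self.e < 0:
            raise ValueError("error budget must be non-negative")


@dataclass
class RunConfig:
    """Full mapper configuration; serialized alongside outputs for provenance."""

    index: IndexParams = field(default_factory=IndexParams)
    seeding: SeedingParams = field(default_factory=SeedingParams)
    chaining: ChainParams = field(default_factory=ChainParams)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    accept: AcceptParams = field(default_factory=AcceptParams)
    report: str = "best"  # "best" | "all"
    threads: int = 1
    seed: int | None = None

    def validate(self) -> None:
        self.index.validate()
        self.seeding.validate()
        self.chaining.validate()
        self.scoring.validate()
        self.accept.validate()
        if self.report not in ("best", "all"):
            raise ValueError("report must be 'best' or 'all'")
        if self.threads != 1:
            raise ValueError("only single-threaded operation is supported")

    def to_dict(self) -> dict:
        return asdict(self)
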