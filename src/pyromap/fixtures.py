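"""Hand-constructed worked-example instance for the seed-chain-extend pipeline.

The instance plants a 14-base template at reference position 100 (0-based;
101 in 1-based output) whose read copy carries one inserted base at read
position 5 and one substituted base at read position 9 (1-based), plus a
decoy exact occurrence of the read's second seed 100 bases downstream.
Greedy seeding must produce seeds AAAA / CCCT / GGGTT; the first and third
chain coherently (9 seed bases, beating the lone decoy occurrence), and
extension must recover the planted origin.

Every constraint is checked programmatically at generation time, so the
fixture cannot silently drift.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import RunConfig, SeedingParams, AcceptParams
from .seeding import Read

FIG2B_READ = "AAAAGCCCTAGGGTT"
FIG2B_TEMPLATE = "AAAACCCAAGGGTT"
FIG2B_TEMPLATE_START = 100  # 0-based; printed as 101
FIG2B_DECOY_START = 200  # 0-based; printed as 201
FIG2B_SEEDS = ("AAAA", "CCCT", "GGGTT")
FIG2B_CHAIN_SPAN = 9


@dataclass
class WorkedExample:
    records: list[tuple[str, str]]
    read: Read
    template_start: int  # 0-based origin of the planted template
    expected_cigar: str
    expected_identity: float


def _occurrences(text: str, pattern: str) -> list[int]:
    out, i = [], text.find(pattern)
    while i != -1:
        out.append(i)
        i = text.find(pattern, i + 1)
    return out


def fig2b() -> WorkedExample:
    """Build and verify the worked-example reference and read."""
    filler1 = "ACGT" * 25  # 100 bases before the template
    filler2 = ("ACGT" * 22)[:86]  # template end (114) .. decoy start (200)
    filler3 = ("CGTA" * 24)  # 96 bases after the decoy
    genome = filler1 + FIG2B_TEMPLATE + filler2 + "CCCT" + filler3

    # read/template relation: insertion of G after read position 4,
    # substitution A->T at template offset 7
    derived = (
        FIG2B_TEMPLATE[:4]
        + "G"
        + FIG2B_TEMPLATE[4:7]
        + "T"
        + FIG2B_TEMPLATE[8:]
    )
    assert derived == FIG2B_READ

    assert genome[FIG2B_TEMPLATE_START : FIG2B_TEMPLATE_START + len(FIG2B_TEMPLATE)] == FIG2B_TEMPLATE
    assert _occurrences(genome, "AAAA") == [FIG2B_TEMPLATE_START], "s1 must be unique"
    assert _occurrences(genome, "CCCT") == [FIG2B_DECOY_START], "s2 must hit only the decoy"
    assert _occurrences(genome, "GGGTT") == [FIG2B_TEMPLATE_START + 9], "s3 must be unique"
    # seed maximality: the blocked read symbols must not extend any match
    assert "AAAAG" not in genome
    assert "CCCTA" not in genome

    return WorkedExample(
        records=[("fig2b_ref", genome)],
        read=Read("fig2b_read", FIG2B_READ),
        template_start=FIG2B_TEMPLATE_START,
        expected_cigar="4=1I3=1X6=",
        expected_identity=13 / 15,
    )


def fig2b_config() -> RunConfig:
    """Mapper settings suited to the 15-base worked example (short seeds)."""
    cfg = RunConfig()
    # the 15-base read has 4-5 base seeds, each with a unique relevant
    # occurrence: anchor at full maximal-match length only
    cfg.seeding = SeedingParams(min_seed_len=1, max_occ=50, rare_cap=1)
    cfg.accept = AcceptParams(mode="identity", t=50.0)
    return cfg
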