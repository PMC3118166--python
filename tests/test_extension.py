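"""Banded affine alignment, end alignment, stitching and whole-read mapping."""

from __future__ import annotations

import numpy as np
import pytest

import pyromap as pm
from pyromap._codes import encode_seq, revcomp
from pyromap.config import AcceptParams, RunConfig, ScoringScheme

from .conftest import random_dna
from . import oracles


def block_errors(block):
    return block.mismatches + block.ins_bases + block.del_bases


class TestBandedAffineAlign:
    def test_worked_example_gap_block(self):
        # the read gap "gcccta" vs reference gap "cccaa" of the worked
        # example: one 1-base gap (cost 2) plus one mismatch
        a, b = encode_seq("GCCCTA"), encode_seq("CCCAA")
        block = pm.banded_affine_align(a, b)
        cost, ops = oracles.gotoh_full(a, b)
        assert block.cost == cost == 3
        assert block.matches == 4
        assert block_errors(block) == 2

    def test_identical_segments(self):
        a = encode_seq("ACGTACGT")
        block = pm.banded_affine_align(a, a.copy())
        assert block.cost == 0 and block.ops == [("=", 8)]

    def test_forced_gap(self):
        block = pm.banded_affine_align(encode_seq("AAA"), encode_seq(""))
        assert block.cost == 4 and block.ops == [("I", 3)]
        block = pm.banded_affine_align(encode_seq(""), encode_seq("TT"))
        assert block.cost == 3 and block.ops == [("D", 2)]

    def test_both_empty(self):
        block = pm.banded_affine_align(encode_seq(""), encode_seq(""))
        assert block.cost == 0 and block.ops == []

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_unbanded_oracle(self, trial):
        rng = np.random.default_rng(trial)
        la, lb = int(rng.integers(1, 25)), int(rng.integers(1, 25))
        a = encode_seq(random_dna(la, seed=trial * 2 + 1))
        b = encode_seq(random_dna(lb, seed=trial * 2 + 2))
        block = pm.banded_affine_align(a, b)
        cost, _ = oracles.gotoh_full(a, b)
        assert block.cost == cost
        assert block.read_span == la and block.ref_span == lb


class TestSemiglobalEnd:
    def test_right_end_free_overhang(self):
        block = pm.semiglobal_end_align(encode_seq("AG"), encode_seq("ATG"), end="right")
        assert block.cost == 1  # match, mismatch, free trailing overhang
        assert block.ops == [("=", 1), ("X", 1)]

    def test_left_end_mirror(self):
        block = pm.semiglobal_end_align(encode_seq("AG"), encode_seq("AAG"), end="left")
        assert block.cost == 0 and block.ops == [("=", 2)]

    def test_empty_segment(self):
        block = pm.semiglobal_end_align(encode_seq(""), encode_seq("ACGT"))
        assert block.cost == 0 and block.ops == []

    def test_no_room_all_insertions(self):
        block = pm.semiglobal_end_align(encode_seq("ACG"), encode_seq(""))
        assert block.ops == [("I", 3)] and block.cost == 4

    def test_matches_semiglobal_oracle(self):
        for trial in range(6):
            a = encode_seq(random_dna(12, seed=40 + trial))
            b = encode_seq(random_dna(20, seed=60 + trial))
            block = pm.semiglobal_end_align(a, b, end="right")
            cost, _ = oracles.gotoh_full(a, b, free_b_ends=True)
            # oracle frees both b ends; right-end alignment frees only the
            # trailing end, so it can never beat the oracle
            assert block.cost >= cost
            block0 = pm.semiglobal_end_align(a, b[: len(a) + 4], end="right")
            assert block0.read_span == len(a)


class TestExtendChain:
    def test_worked_example_mapping(self, worked_example, worked_bundle, worked_config):
        ss = pm.extract_seeds(worked_example.read, worked_bundle.searcher, worked_config.seeding)
        occs = pm.collect_occurrences(ss, worked_bundle, worked_config.seeding.max_occ)
        chains = pm.chain_occurrences(occs, ss, worked_config.chaining)
        best = pm.select_candidates(chains, 1)[0]
        m = pm.extend_chain(worked_example.read, worked_bundle, best)
        assert m.cigar_string == worked_example.expected_cigar == "4=1I3=1X6="
        assert (m.matches, m.ins_bases, m.mismatches) == (13, 1, 1)
        assert m.identity == pytest.approx(13 / 15)
        assert m.ref_start == worked_example.template_start

    def test_error_free_read_all_match(self, small_ref):
        seq, bundle = small_ref
        read = pm.Read("c", seq[1000:1200])
        m = pm.map_read(read, bundle)[0]
        assert m.cigar == [("=", 200)]
        assert m.identity == 1.0 and m.errors == 0

    def test_edit_path_consumes_read(self, small_ref):
        seq, bundle = small_ref
        rng = np.random.default_rng(3)
        raw = list(seq[500:680])
        for p in rng.integers(0, 180, size=12):
            raw[p] = "ACGT"[int(rng.integers(4))]
        read = pm.Read("mut", "".join(raw))
        for m in pm.map_read(read, bundle, RunConfig(report="all")):
            assert m.read_span == len(read)
            assert m.ref_span == m.matches + m.mismatches + m.del_bases


class TestAcceptMapping:
    def _mapping(self, matches, mismatches, ins, dele):
        return pm.Mapping(
            read_id="r", ref_name="c", ref_start=0, gstart=0, strand="+",
            cigar=[], matches=matches, mismatches=mismatches,
            ins_bases=ins, del_bases=dele, cost=0, seq="A",
        )

    def test_identity_thresholds_around_worked_example(self):
        m = self._mapping(13, 1, 1, 0)  # identity 86.7%
        assert pm.accept_mapping(m, AcceptParams(mode="identity", t=85))
        assert not pm.accept_mapping(m, AcceptParams(mode="identity", t=90))

    def test_perfect_mapping_any_threshold(self):
        m = self._mapping(200, 0, 0, 0)
        assert pm.accept_mapping(m, AcceptParams(mode="identity", t=100))

    def test_errors_mode_boundary(self):
        two = self._mapping(100, 1, 1, 0)
        three = self._mapping(100, 1, 1, 1)
        assert pm.accept_mapping(two, AcceptParams(mode="errors", e=2))
        assert not pm.accept_mapping(three, AcceptParams(mode="errors", e=2))


class TestMapRead:
    def test_worked_example_best_position(self, worked_example, worked_bundle, worked_config):
        maps = pm.map_read(worked_example.read, worked_bundle, worked_config)
        assert maps[0].ref_start + 1 == 101
        assert maps[0].strand == "+"

    def test_exact_unique_200mer(self, small_ref):
        seq, bundle = small_ref
        read = pm.Read("fwd", seq[2300:2500])
        m = pm.map_read(read, bundle)[0]
        assert (m.ref_start, m.strand, m.identity) == (2300, "+", 1.0)

    def test_reverse_complement_strand_symmetry(self, small_ref):
        seq, bundle = small_ref
        read = pm.Read("rev", revcomp(seq[2300:2500]))
        m = pm.map_read(read, bundle)[0]
        assert (m.ref_start, m.strand) == (2300, "-")
        assert m.identity == 1.0
        # SAM convention: sequence emitted as aligned (forward strand)
        assert m.seq == seq[2300:2500]

    def test_unmapped_read_empty_list(self, small_ref):
        _, bundle = small_ref
        # a read over a disjoint alphabet composition cannot be placed
        read = pm.Read("x", "A" * 60)
        cfg = RunConfig()
        cfg.accept.t = 90.0
        assert pm.map_read(read, bundle, cfg) == []

    def test_report_all_superset_of_best(self, small_ref):
        seq, bundle = small_ref
        read = pm.Read("c", seq[100:260])
        best = pm.map_read(read, bundle, RunConfig(report="best"))
        all_cfg = RunConfig(report="all")
        everything = pm.map_read(read, bundle, all_cfg)
        assert len(everything) >= len(best)
        assert best[0].gstart in [m.gstart for m in everything]


class TestTwinLoci:
    def test_duplicate_locus_tie_broken_by_errors(self):
        """Two identical planted loci: both extended, tie resolved to the
        leftmost; a read with an error near one copy maps to the exact copy."""
        core = random_dna(150, seed=77)
        filler = random_dna(400, seed=78)
        genome = filler[:100] + core + filler[100:250] + core + filler[250:]
        bundle = pm.IndexBundle.build(pm.encode_reference([("twin", genome)]))
        read = pm.Read("t", core)
        cfg = RunConfig(report="all")
        cfg.accept.t = 90.0
        maps = pm.map_read(read, bundle, cfg)
        starts = sorted(m.ref_start for m in maps)
        assert starts == [100, 400]
        best = pm.map_read(read, bundle, RunConfig(report="best"))
        assert [m.ref_start for m in best] == [100, 400]  # equal errors: both kept
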