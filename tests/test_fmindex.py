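"""Suffix array, BWT and FM-index queries against brute-force oracles.

The two-letter examples follow the classic textbook text "abbbab",
mapped into the DNA alphabet as a -> A, b -> C (relative symbol order,
and hence the suffix array, is unchanged by the renaming).
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pyromap as pm
from pyromap._codes import encode_seq, decode_codes, SENTINEL
from pyromap.fmindex import EMPTY_INTERVAL, SAInterval

from .conftest import random_dna
from . import oracles


def text_codes(s: str) -> np.ndarray:
    """Terminated code array for a plain ACGT string."""
    return np.concatenate((encode_seq(s), np.array([SENTINEL], dtype=np.uint8)))


ABBBAB = text_codes("ACCCAC")  # a->A, b->C


class TestEncodeReference:
    def test_single_clean_record(self):
        ref = pm.encode_reference([("chr1", "ACGT")])
        assert decode_codes(ref.codes) == "ACGT$"
        assert len(ref.segments) == 1
        seg = ref.segments[0]
        assert (seg.record, seg.gstart, seg.gend) == ("chr1", 0, 4)

    def test_two_records_round_trip(self):
        ref = pm.encode_reference([("a", "ACG"), ("b", "TT")])
        assert len(ref.segments) == 2
        g = ref.to_global("b", 0)
        assert ref.to_record(g) == ("b", 0)
        # every position round-trips
        for seg in ref.segments:
            for p in range(seg.gstart, seg.gend):
                rec, off = ref.to_record(p)
                assert ref.to_global(rec, off) == p

    def test_ambiguity_run_splits_segments(self):
        ref = pm.encode_reference([("c", "ACNNGT")])
        assert [(-s.gstart + s.gend) for s in ref.segments] == [2, 2]
        assert ref.to_record(ref.segments[1].gstart) == ("c", 4)
        # no search result may cross the split: scan each segment only
        bundle = pm.IndexBundle.build(ref)
        iv = pm.backward_search(bundle.fm, encode_seq("CG"))
        assert len(iv) == 0  # "CG" spans the split in the original record

    def test_case_insensitive_and_drop_empty(self):
        with pytest.raises(ValueError):
            pm.encode_reference([])
        ref = pm.encode_reference([("x", "acgt"), ("y", "NNN")])
        assert [r for r, _ in ref.records] == ["x"]
        assert decode_codes(ref.codes) == "ACGT$"


class TestSuffixArray:
    def test_figure_text(self):
        sa = pm.build_suffix_array(ABBBAB)
        assert sa.order.tolist() == [6, 4, 0, 5, 3, 2, 1]

    def test_smallest_case(self):
        assert pm.build_suffix_array(text_codes("A")).order.tolist() == [1, 0]

    def test_random_text_matches_naive_sort(self):
        codes = text_codes(random_dna(200, seed=3))
        sa = pm.build_suffix_array(codes)
        assert sa.order.tolist() == oracles.naive_suffix_array(codes)

    def test_is_permutation(self):
        codes = text_codes(random_dna(500, seed=4))
        sa = pm.build_suffix_array(codes)
        assert sorted(sa.order.tolist()) == list(range(len(codes)))


class TestBWT:
    def test_figure_text_rotation_oracle(self):
        sa = pm.build_suffix_array(ABBBAB)
        bwt = pm.bwt_from_sa(ABBBAB, sa)
        assert bwt.tolist() == oracles.bwt_by_rotation(ABBBAB)
        assert decode_codes(bwt) == "CC$ACCA"  # "bb$abba" under a->A, b->C

    def test_trivial_text(self):
        codes = text_codes("A")
        bwt = pm.bwt_from_sa(codes, pm.build_suffix_array(codes))
        assert decode_codes(bwt) == "A$"

    def test_inversion_reproduces_text(self):
        for seed in (1, 2):
            codes = text_codes(random_dna(300, seed=seed))
            bwt = pm.bwt_from_sa(codes, pm.build_suffix_array(codes))
            assert pm.inverse_bwt(bwt).tolist() == codes.tolist()
            assert oracles.inverse_bwt_by_lf(bwt) == codes.tolist()

    def test_length_mismatch_rejected(self):
        sa = pm.build_suffix_array(ABBBAB)
        with pytest.raises(ValueError):
            pm.bwt_from_sa(text_codes("A"), sa)


class TestFMIndex:
    def test_counts_table(self):
        fm = pm.build_fm_index(ABBBAB)
        # number of strictly smaller symbols: $:0, a:1, b:3
        assert fm.cumcounts[SENTINEL] == 0
        assert fm.cumcounts[encode_seq("A")[0]] == 1
        assert fm.cumcounts[encode_seq("C")[0]] == 3

    def test_rank_conservation(self):
        codes = text_codes(random_dna(400, seed=5))
        fm = pm.build_fm_index(codes)
        for c in range(6):
            assert fm.rank(c, fm.n) == int(np.sum(fm.bwt == c))

    def test_rank_matches_exhaustive_prefix_counts(self):
        codes = text_codes(random_dna(1000, seed=6))
        fm = pm.build_fm_index(codes, rank_stride=64)
        rng = np.random.default_rng(0)
        for _ in range(50):
            i = int(rng.integers(0, fm.n + 1))
            c = int(rng.integers(0, 6))
            assert fm.rank(c, i) == int(np.sum(fm.bwt[:i] == c))

    def test_bwt_is_permutation_of_text(self):
        codes = text_codes(random_dna(200, seed=8))
        fm = pm.build_fm_index(codes)
        assert np.array_equal(np.sort(fm.bwt), np.sort(codes))


class TestBackwardSearch:
    def test_common_prefix_interval(self):
        fm = pm.build_fm_index(ABBBAB)
        iv = pm.backward_search(fm, encode_seq("C"))  # "b"
        assert len(iv) == 4

    def test_empty_pattern_full_interval(self):
        fm = pm.build_fm_index(ABBBAB)
        iv = pm.backward_search(fm, encode_seq(""))
        assert (iv.low, iv.high) == (0, fm.n)

    def test_absent_pattern_empty(self):
        fm = pm.build_fm_index(ABBBAB)
        assert pm.backward_search(fm, encode_seq("AA")).empty

    def test_non_alphabet_symbol_empty(self):
        fm = pm.build_fm_index(ABBBAB)
        assert pm.backward_search(fm, encode_seq("AN")).empty

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_naive_scan(self, data):
        n = data.draw(st.integers(20, 300))
        seed = data.draw(st.integers(0, 10**6))
        text = random_dna(n, seed=seed)
        codes = text_codes(text)
        fm = pm.build_fm_index(codes, rank_stride=32, sa_stride=8)
        plen = data.draw(st.integers(1, 8))
        start = data.draw(st.integers(0, n - 1))
        pattern = encode_seq(text[start : start + plen])
        iv = pm.backward_search(fm, pattern)
        positions, truncated = pm.locate(fm, iv)
        assert not truncated
        assert sorted(positions) == oracles.naive_occurrences(codes, pattern)


class TestLocate:
    def test_positions_of_ab(self):
        fm = pm.build_fm_index(ABBBAB)
        iv = pm.backward_search(fm, encode_seq("AC"))  # "ab"
        positions, _ = pm.locate(fm, iv)
        assert sorted(positions) == [0, 4]

    def test_empty_interval(self):
        fm = pm.build_fm_index(ABBBAB)
        assert pm.locate(fm, EMPTY_INTERVAL) == ([], False)

    def test_full_interval_is_permutation(self):
        fm = pm.build_fm_index(ABBBAB)
        positions, _ = pm.locate(fm, SAInterval(0, fm.n))
        assert sorted(positions) == list(range(fm.n))

    def test_max_occ_truncation(self):
        fm = pm.build_fm_index(ABBBAB)
        positions, truncated = pm.locate(fm, SAInterval(0, fm.n), max_occ=2)
        assert positions == [] and truncated


class TestLongestMatchFrom:
    def test_example(self):
        # query "abbbba" vs reference "abbbab": l = 4 ("abbb") at position 0
        ref = pm.encode_reference([("r", "ACCCAC")])
        bundle = pm.IndexBundle.build(ref)
        query = encode_seq("ACCCCA")
        length, positions, occ, truncated = bundle.searcher.longest_match_from(query, 0)
        assert length == 4
        assert positions == [0]
        assert occ == 1 and not truncated

    def test_start_at_query_end(self):
        ref = pm.encode_reference([("r", "ACCCAC")])
        bundle = pm.IndexBundle.build(ref)
        q = encode_seq("AC")
        assert bundle.searcher.longest_match_from(q, 2)[:2] == (0, [])

    def test_absent_first_symbol(self):
        ref = pm.encode_reference([("r", "AAAA")])
        bundle = pm.IndexBundle.build(ref)
        assert bundle.searcher.longest_match_from(encode_seq("G"), 0)[0] == 0

    def test_maximality_against_oracle(self, small_ref):
        seq, bundle = small_ref
        codes = bundle.ref.codes
        rng = np.random.default_rng(11)
        query = encode_seq(random_dna(60, seed=12))
        for start in rng.integers(0, 50, size=10):
            start = int(start)
            length, _, _, _ = bundle.searcher.longest_match_from(query, start)
            assert length == oracles.naive_longest_match(codes, query, start)
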