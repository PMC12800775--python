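"""kLCP arrays, interval extension, and streamed-query equivalence."""

import numpy as np
import pytest

from msindex import (
    KmerSet,
    build_index,
    build_klcp,
    build_suffix_array,
    backward_search,
    extend_to_prefix_interval,
    greedy_superstring,
    stream_query,
)
from msindex.fixtures import random_genome
from conftest import naive_adjacent_lcp, naive_prefix_interval, random_dna, random_kmer_set


class TestBuildKlcp:
    @pytest.mark.parametrize(
        "s,k,expected",
        [("ACGT", 3, [0, 0, 0, 0, 0]), ("AAAA", 3, [0, 0, 1, 1, 0]), ("A", 2, [0, 0])],
    )
    def test_examples(self, s, k, expected):
        sa = build_suffix_array(s)
        assert build_klcp(sa, k).bits.tolist() == expected

    @pytest.mark.parametrize("k", [2, 3, 5, 12])
    def test_matches_naive_threshold(self, k, rng):
        for n in (0, 1, 5, 50, 400, 2000):
            s = random_dna(rng, n)
            sa = build_suffix_array(s)
            bits = build_klcp(sa, k).bits
            naive = [int(h >= k - 1) for h in naive_adjacent_lcp(s)] + [0]
            assert bits.tolist() == naive


class TestExtendToPrefixInterval:
    def test_extends_to_prefix_interval_on_runs(self):
        from msindex import MaskedSuperstring

        # S = AAAA: the interval of AAA widens to the interval of AA
        ms = MaskedSuperstring(k=3, model="uni", S="AAAA", M="1100")
        idx = build_index(ms, "memb", with_klcp=True, allow_general_mask=True)
        iv = backward_search(idx, "AAA")
        assert (iv.i, iv.j) == naive_prefix_interval("AAAA", "AAA")
        out = extend_to_prefix_interval(iv, idx.klcp)
        assert (out.i, out.j) == naive_prefix_interval("AAAA", "AA")
        assert (out.i, out.j) == (2, 5)

    def test_no_extension_when_neighbors_differ(self):
        idx = _uni_index({"ACG", "CGT"}, 3)
        iv = backward_search(idx, "ACG")
        out = extend_to_prefix_interval(iv, idx.klcp)
        assert (out.i, out.j) == (iv.i, iv.j)

    def test_idempotent(self):
        idx = _uni_index({"AAA"}, 3)
        iv = backward_search(idx, "AAA")
        once = extend_to_prefix_interval(iv, idx.klcp)
        twice = extend_to_prefix_interval(once, idx.klcp)
        assert once == twice

    def test_empty_interval_rejected(self):
        idx = _uni_index({"ACG"}, 3)
        with pytest.raises(ValueError):
            extend_to_prefix_interval(backward_search(idx, "TTT"), idx.klcp)

    def test_matches_brute_force_on_random_superstrings(self, rng):
        S = random_dna(np.random.default_rng(61), 300)
        from msindex import MaskedSuperstring

        ms = MaskedSuperstring(k=4, model="uni", S=S, M="0" * len(S))
        idx = build_index(ms, "memb", with_klcp=True, allow_general_mask=True)
        for p in range(0, len(S) - 3, 7):
            q = S[p : p + 4]
            iv = backward_search(idx, q)
            out = extend_to_prefix_interval(iv, idx.klcp)
            assert (out.i, out.j) == naive_prefix_interval(S, q[:-1])


def _uni_index(kmers, k, mode="memb"):
    pol = "max-one" if mode == "memb" else "min-one"
    ks = KmerSet(k=k, model="uni", kmers=kmers)
    return build_index(greedy_superstring(ks, pol), mode, with_klcp=True)


def _bi_index_from_seq(seq, k, mode="memb"):
    from msindex import extract_kmer_set

    pol = "max-one" if mode == "memb" else "min-one"
    ks = extract_kmer_set([seq], k, "bi")
    return build_index(greedy_superstring(ks, pol), mode, with_klcp=True), ks


class TestStreamQuery:
    def test_positive_stream_single_full_search(self):
        idx = _uni_index({"ACG", "CGT"}, 3)
        res = stream_query(idx, "ACGT", "member")
        assert res.answers == [True, True]
        assert res.full_searches == 1

    def test_all_negative_stream(self):
        idx = _uni_index({"ACG", "CGT"}, 3)
        res = stream_query(idx, "AAAA", "member")
        assert res.answers == [False, False]
        assert res.full_searches == 2

    def test_degenerate_single_window(self):
        idx = _uni_index({"ACG", "CGT"}, 3)
        res = stream_query(idx, "CGT", "member")
        assert res.answers == [idx.member("CGT")]

    def test_too_short_text(self):
        idx = _uni_index({"ACG"}, 3)
        assert stream_query(idx, "AC", "member").answers == []

    def test_requires_klcp(self):
        ks = KmerSet(k=3, model="uni", kmers={"ACG"})
        idx = build_index(greedy_superstring(ks, "max-one"), "memb")
        with pytest.raises(ValueError):
            stream_query(idx, "ACGT")

    def test_non_acgt_windows_answer_false_and_reset(self):
        idx = _uni_index({"ACG", "CGT"}, 3)
        res = stream_query(idx, "ACGNACGT", "member")
        assert res.answers == [True, False, False, False, True, True]

    def test_fully_positive_unidirectional_amortization(self):
        seq = random_genome(3000, 17)
        from msindex import extract_kmer_set

        ks = extract_kmer_set([seq], 11, "uni")
        idx = build_index(greedy_superstring(ks, "max-one"), "memb", with_klcp=True)
        res = stream_query(idx, seq, "member")
        assert all(res.answers)
        assert res.full_searches == 1
        assert res.extensions == len(res.answers) - 1

    @pytest.mark.parametrize("model", ["uni", "bi"])
    @pytest.mark.parametrize("op", ["member", "lookup"])
    @pytest.mark.parametrize("block_size", [None, 1, 5, 64])
    def test_streamed_equals_isolated(self, model, op, block_size, rng):
        seq = random_genome(600, 23)
        from msindex import extract_kmer_set

        k = 7
        ks = extract_kmer_set([seq[:400]], k, model)
        mode = "memb" if op == "member" else "dict"
        pol = "max-one" if op == "member" else "min-one"
        idx = build_index(greedy_superstring(ks, pol), mode, with_klcp=True)
        # positive-rich and negative-rich query texts
        for text in (seq[:200], random_dna(rng, 200), seq[300:500]):
            res = stream_query(idx, text, op, block_size=block_size)
            isolated = []
            for p in range(len(text) - k + 1):
                q = text[p : p + k]
                isolated.append(idx.member(q) if op == "member" else idx.lookup(q))
            assert res.answers == isolated

    def test_bidirectional_full_search_budget(self):
        # full searches are bounded by blocks plus positions where the
        # superstring stores the k-mer only on the other strand (each such
        # position costs at most one miss-retry and one chain break)
        seq = random_genome(2000, 29)
        idx, ks = _bi_index_from_seq(seq, 11)
        res = stream_query(idx, seq, "member")
        m = len(res.answers)
        assert all(res.answers)
        n_blocks = -(-m // max(11, int(2 * np.sqrt(len(seq)))))
        from msindex import backward_search as bs
        from msindex import reverse_complement as rc

        fwd_missing = rc_missing = 0
        for p in range(m):
            w = seq[p : p + 11]
            if bs(idx, w).empty:
                fwd_missing += 1
            if bs(idx, rc(w)).empty:
                rc_missing += 1
        inconsistent = min(fwd_missing, rc_missing) + max(fwd_missing, rc_missing)
        assert res.full_searches <= 2 * (n_blocks + inconsistent) + 2

    def test_bidirectional_strand_consistent_text_tight_budget(self):
        # a slice of the superstring itself is fully strand-consistent, so
        # the cost is one full search per block plus ghost-window retries
        seq = random_genome(2000, 47)
        idx, ks = _bi_index_from_seq(seq, 11)
        from msindex import invert_mbwt

        S = invert_mbwt(idx.image).S
        text = S[:1500]
        res = stream_query(idx, text, "member")
        m = len(res.answers)
        B = max(11, int(2 * np.sqrt(len(text))))
        n_blocks = -(-m // B)
        n_negative = m - sum(res.answers)
        assert res.full_searches <= n_blocks + n_negative

    def test_block_size_changes_only_telemetry(self):
        seq = random_genome(800, 31)
        idx, _ = _bi_index_from_seq(seq, 9)
        baseline = stream_query(idx, seq, "member", block_size=32).answers
        for B in (1, 7, 200):
            assert stream_query(idx, seq, "member", block_size=B).answers == baseline

    def test_streamed_lookup_equals_isolated_on_battery(self, small_battery):
        for name, ks in small_battery[:4]:
            idx = build_index(greedy_superstring(ks, "min-one"), "dict", with_klcp=True)
            text = "".join(list(ks.kmers)[:3])
            res = stream_query(idx, text, "lookup")
            for p, ans in enumerate(res.answers):
                assert ans == idx.lookup(text[p : p + ks.k]), (name, p)
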