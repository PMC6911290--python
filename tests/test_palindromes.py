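"""Approximate palindromes: window extraction, DP detector vs brute force,
shuffles, and the paired test."""

from __future__ import annotations

import math

import numpy as np
import pytest

from retronest.palindromes import (
    extract_site_window,
    element_site_window,
    max_approx_palindrome,
    paired_shuffle_test,
    shuffle_seq,
    stem_score,
)
from retronest.models import AnnotatedElement, SimConfig, TsdRecord
from retronest.sequences import random_dna, revcomp
from retronest.simulate import plant_genome


def brute_force_stem(seq: str, min_stem=3, rate=1.0 / 3.0, max_loop=None):
    """Independent oracle: enumerate every (left arm, right arm start) and
    compute the best semi-global edit distance with a hand-rolled DP."""
    n = len(seq)
    best = 0
    for s in range(min_stem, n):
        allowed = math.floor(s * rate)
        if s + max(1, s - allowed) > n:
            break
        found = False
        for a in range(0, n - s):
            b = a + s
            pattern = revcomp(seq[a:b])
            starts = range(b, n) if max_loop is None else \
                range(b, min(n, b + max_loop + 1))
            for c in starts:
                text = seq[c:]
                if not text:
                    continue
                # semi-global DP: pattern fully aligned, text prefix free at
                # the end (min over all end positions)
                prev = list(range(len(pattern) + 1))
                best_dist = prev[-1]
                for ch in text:
                    cur = [0] * (len(pattern) + 1)
                    cur[0] = prev[0] + 1
                    for j in range(1, len(pattern) + 1):
                        cost = 0 if pattern[j - 1] == ch else 1
                        cur[j] = min(prev[j - 1] + cost, prev[j] + 1,
                                     cur[j - 1] + 1)
                    best_dist = min(best_dist, cur[-1])
                    prev = cur
                if best_dist <= allowed:
                    found = True
                    break
            if found:
                break
        if found:
            best = s
    return best


class TestWindows:
    def test_window_coordinates(self, rng):
        genome = random_dna(10_000, rng=rng)
        win = extract_site_window(genome, 5_000)
        assert win == genome[4_990:5_010]
        assert len(win) == 20

    def test_edge_rejected(self, rng):
        genome = random_dna(100, rng=rng)
        with pytest.raises(ValueError):
            extract_site_window(genome, 5)

    def test_adjacent_sites_overlap_but_differ(self, rng):
        genome = random_dna(1_000, rng=rng)
        assert extract_site_window(genome, 500) != \
            extract_site_window(genome, 501)

    def test_element_window_reconstructs_preinsertion_site(self, rng):
        """Skipping the element plus one TSD copy yields the 20 bp the host
        read before the insertion, with the target word just 3' of the cut."""
        host = random_dna(2_000, rng=rng)
        elem = random_dna(500, rng=rng)
        p, k = 1_000, 5
        t = host[p:p + k]
        genome = host[:p] + t + elem + t + host[p + k:]
        el = AnnotatedElement(id="x", genome_id="g", start=p + k,
                              end=p + k + 500)
        el.tsd = TsdRecord(element_id="x", length=k, seq=t)
        win = element_site_window(genome, el)
        assert win == host[p - 10:p + 10]


class TestDetector:
    def test_perfect_hexamer_palindrome(self):
        hit = max_approx_palindrome("AAATTT")
        assert hit is not None
        assert hit.stem_length == 3
        assert hit.edit_count == 0

    def test_motif_with_tsd_loop(self):
        """The ANGTT-TSD-AACNT arrangement scores a >= 5 bp stem with at
        most one mismatch."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            n1, n2 = (random_dna(1, rng=rng) for _ in range(2))
            tsd = random_dna(5, rng=rng)
            seq = f"A{n1}GTT{tsd}AAC{n2}T"
            hit = max_approx_palindrome(seq)
            assert hit is not None
            assert hit.stem_length >= 5
            assert hit.edit_count <= math.floor(hit.stem_length / 3)

    @pytest.mark.parametrize("max_loop", [None, 0])
    def test_dp_equals_bruteforce_oracle(self, max_loop):
        rng = np.random.default_rng(8)
        for _ in range(120):
            seq = random_dna(20, gc=0.4, rng=rng)
            got = stem_score(seq, max_loop=max_loop)
            want = brute_force_stem(seq, max_loop=max_loop)
            assert got == (want if want >= 3 else 2)

    def test_indel_requiring_optimum(self):
        """An arm whose reverse complement appears with one deletion still
        counts at the permitted error budget."""
        arm = "ACGTGCA"          # s=7, allowed=2
        rc = revcomp(arm)        # TGCACGT
        seq = arm + "AA" + rc[:3] + rc[4:]  # right arm with one deletion
        hit = max_approx_palindrome(seq)
        assert hit.stem_length >= 7

    def test_error_rate_monotonicity(self, rng):
        for _ in range(40):
            seq = random_dna(20, gc=0.4, rng=rng)
            s30 = stem_score(seq, max_error_rate=0.30)
            s33 = stem_score(seq, max_error_rate=1.0 / 3.0)
            s40 = stem_score(seq, max_error_rate=0.40)
            assert s30 <= s33 <= s40


class TestShuffle:
    def test_multiset_preserved(self, rng):
        seq = random_dna(50, rng=rng)
        sh = shuffle_seq(seq, rng)
        assert sorted(sh) == sorted(seq)
        assert len(sh) == len(seq)

    def test_reproducible_given_seed(self):
        seq = "ACGTACGTACGTACGT"
        a = shuffle_seq(seq, np.random.default_rng(5))
        b = shuffle_seq(seq, np.random.default_rng(5))
        assert a == b


class TestPairedShuffleTest:
    def test_self_comparison_gives_p_one(self, rng, monkeypatch):
        import retronest.palindromes as pal
        monkeypatch.setattr(pal, "shuffle_seq", lambda s, r: s)
        seqs = [random_dna(20, rng=rng) for _ in range(10)]
        res = pal.paired_shuffle_test({"ALL": seqs}, rng)
        assert res[0].paired_t_p == 1.0
        assert res[0].mean_native == res[0].mean_random

    def test_planted_palindromes_detected(self):
        """Sites seeded with perfect >= 5 bp inverted repeats around the cut
        separate from their shuffles (planted signal power)."""
        rng = np.random.default_rng(44)
        wins = []
        for _ in range(200):
            arm = random_dna(6, rng=rng)
            loop = random_dna(5, rng=rng)
            pad = random_dna(3, rng=rng)
            seq = pad + arm + loop + revcomp(arm) + random_dna(3, rng=rng)
            wins.append(seq[:20])
        res = paired_shuffle_test({"ALL": wins}, rng)[0]
        assert res.mean_native > res.mean_random
        assert res.paired_t_p < 0.01

    def test_bh_applied_to_family_groups_only(self, rng):
        seqs = lambda: [random_dna(20, rng=rng) for _ in range(12)]
        groups = {"ALL": seqs(), "Tekay": seqs(), "Ogre": seqs(),
                  "Reina": seqs()}
        results = {r.group: r for r in paired_shuffle_test(groups, rng)}
        assert results["ALL"].p_adj == results["ALL"].paired_t_p
        fams = [results[g] for g in ("Tekay", "Ogre", "Reina")]
        for r in fams:
            assert r.p_adj is not None and r.p_adj >= r.paired_t_p - 1e-12


class TestSimulatedPalindromeBias:
    def test_planted_bias_recovered_from_genome(self):
        """With palindrome_bias = 1 the reconstructed insertion-site windows
        score higher than their shuffles."""
        cfg = SimConfig(genome_length_bp=300_000, n_elements=30,
                        nesting_fraction=0.0, palindrome_bias=1.0, rng_seed=21)
        genome, truth = plant_genome(cfg)
        wins = [w for w in (element_site_window(genome, el)
                            for el in truth.elements) if w]
        assert len(wins) >= 20
        rng = np.random.default_rng(1)
        res = paired_shuffle_test({"ALL": wins}, rng)[0]
        assert res.mean_native > res.mean_random
        assert res.paired_t_p < 0.05
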