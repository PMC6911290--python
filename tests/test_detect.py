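"""Structural detector: direct-repeat search, excision, recursion, pairing."""

from __future__ import annotations

import numpy as np
import pytest

from retronest.detect import (
    CoordinateMap,
    DetectionParams,
    call_nested_pairs,
    excise,
    find_intact_elements,
    recursive_detect,
)
from retronest.models import AnnotatedElement, SimConfig
from retronest.sequences import random_dna
from retronest.simulate import plant_genome, synthesize_element


def _insert(host: str, pos: int, element_seq: str, tsd_len: int) -> str:
    t = host[pos:pos + tsd_len]
    return host[:pos] + t + element_seq + t + host[pos + tsd_len:]


class TestFindIntact:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_genome_has_no_candidates(self, seed):
        """A >= 100 bp direct repeat at >= 80% identity is vanishingly
        unlikely in 50 kb of i.i.d. sequence."""
        genome = random_dna(50_000, gc=0.4, rng=np.random.default_rng(seed))
        assert find_intact_elements(genome) == []

    def test_single_young_element_recovered_exactly(self, panel, rng):
        host = random_dna(40_000, gc=0.4, rng=rng)
        el = synthesize_element(panel[0], 0.0, 1.3e-8, rng)
        genome = _insert(host, 20_000, el.seq, 5)
        cands = find_intact_elements(genome)
        assert len(cands) == 1
        assert cands[0].span == (20_005, 20_005 + el.length)
        assert cands[0].tsd_candidate == host[20_000:20_005]
        # inner LTR ends are not pinned by a TSD; chance matches may extend
        # them a few bases, so identity can sit marginally below 100
        assert cands[0].ltr_identity_pct > 99.5

    def test_identity_threshold_semantics(self, panel):
        """An element whose LTRs share ~85% identity is found at the 80%
        threshold and missed at 90%."""
        rng = np.random.default_rng(7)
        host = random_dna(40_000, gc=0.4, rng=rng)
        # age chosen so pairwise LTR divergence ~= 15%
        mu = 1.3e-8
        age = 0.15 / 2 / (mu * 1e6)
        el = synthesize_element(panel[2], age, mu, rng)
        genome = _insert(host, 20_000, el.seq, 5)
        lo = find_intact_elements(genome, DetectionParams(min_ltr_identity=80.0))
        hi = find_intact_elements(genome, DetectionParams(min_ltr_identity=90.0))
        assert len(lo) == 1
        assert hi == []


class TestExcise:
    def test_excision_inverts_insertion(self, panel, rng):
        host = random_dna(30_000, gc=0.4, rng=rng)
        el = synthesize_element(panel[5], 0.0, 1.3e-8, rng)
        genome = _insert(host, 12_345, el.seq, 4)
        cand = find_intact_elements(genome)[0]
        restored, _ = excise(genome, cand)
        assert restored == host

    def test_coordinate_map_roundtrip(self, panel, rng):
        host = random_dna(30_000, gc=0.4, rng=rng)
        el = synthesize_element(panel[5], 0.0, 1.3e-8, rng)
        genome = _insert(host, 9_000, el.seq, 5)
        cand = find_intact_elements(genome)[0]
        shorter, cmap = excise(genome, cand)
        for pos in (0, 100, 8_999, 9_000, len(shorter) - 1):
            assert cmap.to_current(cmap.to_original(pos)) == pos

    def test_excision_without_tsd_removes_span_only(self):
        cmap = CoordinateMap(100)
        from retronest.detect import CandidateElement
        cand = CandidateElement(genome_id="g", span=(10, 20),
                                ltr5_span=(10, 12), ltr3_span=(18, 20),
                                ltr_identity_pct=100.0, tsd_candidate=None)
        genome = "A" * 100
        shorter, _ = excise(genome, cand)
        assert len(shorter) == 90


class TestRecursiveDetect:
    def test_two_level_nest_found_across_rounds(self, panel):
        rng = np.random.default_rng(21)
        host_genome = random_dna(60_000, gc=0.4, rng=rng)
        outer = synthesize_element(panel[1], 0.3, 1.3e-8, rng)
        inner = synthesize_element(panel[10], 0.1, 1.3e-8, rng)
        genome = _insert(host_genome, 30_000, outer.seq, 5)
        # plant the inner element in the middle of the outer one
        inner_pos = 30_005 + outer.length // 2
        genome = _insert(genome, inner_pos, inner.seq, 4)
        cands = recursive_detect(genome)
        assert len(cands) == 2
        outer_span = (30_005, 30_005 + outer.length + inner.length + 4)
        inner_span = (inner_pos + 4, inner_pos + 4 + inner.length)
        rounds = {}
        for want in (inner_span, outer_span):
            got = min(cands, key=lambda c: abs(c.span[0] - want[0])
                      + abs(c.span[1] - want[1]))
            # TSD-boundary ambiguity allows <= 2 bp
            assert abs(got.span[0] - want[0]) <= 2
            assert abs(got.span[1] - want[1]) <= 2
            rounds[want] = got.detection_round
        assert rounds[inner_span] == 1
        assert rounds[outer_span] == 2

    def test_empty_genome_terminates_immediately(self, rng):
        genome = random_dna(30_000, gc=0.4, rng=rng)
        assert recursive_detect(genome) == []

    def test_three_level_nest_levels_assigned(self, sim, detected):
        """Ground-truth oracle: every planted nesting level is represented
        and levels from containment match the generator's levels."""
        _, _, truth = sim
        els = [AnnotatedElement(id=f"c{i}", genome_id="g", start=c.span[0],
                                end=c.span[1])
               for i, c in enumerate(detected)]
        call_nested_pairs(els)
        got = {}
        for el in els:
            got[(el.start, el.end)] = el.nesting_level
        matched = 0
        for t in truth.elements:
            for (s, e), lvl in got.items():
                if abs(s - t.start) <= 2 and abs(e - t.end) <= 2:
                    assert lvl == t.nesting_level
                    matched += 1
                    break
        assert matched >= 0.9 * len(truth.elements)


def _brute_force_pairs(spans):
    """O(n^2) containment oracle: each span pairs with its smallest strict
    container."""
    out = []
    for i, (s, e) in enumerate(spans):
        containers = [
            j for j, (s2, e2) in enumerate(spans)
            if (s2, e2) != (s, e) and s2 <= s and e <= e2
        ]
        if containers:
            j = min(containers, key=lambda j: spans[j][1] - spans[j][0])
            out.append((i, j))
    return sorted(out)


class TestCallNestedPairs:
    def _elements(self, spans):
        return [AnnotatedElement(id=f"e{i}", genome_id="g", start=s, end=e)
                for i, (s, e) in enumerate(spans)]

    def test_chain_pairs_with_immediate_host_only(self):
        els = self._elements([(0, 100), (10, 90), (20, 80)])
        pairs = {(p.nested_id, p.original_id) for p in call_nested_pairs(els)}
        assert pairs == {("e1", "e0"), ("e2", "e1")}

    def test_disjoint_elements_not_paired(self):
        els = self._elements([(0, 10), (20, 30), (40, 55)])
        assert call_nested_pairs(els) == []

    def test_one_host_two_nested(self):
        els = self._elements([(0, 100), (10, 30), (50, 70)])
        pairs = call_nested_pairs(els)
        assert {(p.nested_id, p.original_id) for p in pairs} == \
            {("e1", "e0"), ("e2", "e0")}

    def test_identical_spans_rejected(self):
        els = self._elements([(0, 10), (0, 10)])
        with pytest.raises(ValueError):
            call_nested_pairs(els)

    def test_first_level_only_flag(self):
        els = self._elements([(0, 100), (10, 90), (20, 80)])
        pairs = call_nested_pairs(els, first_level_only=True)
        assert {(p.nested_id, p.original_id) for p in pairs} == {("e1", "e0")}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_forests(self, seed):
        rng = np.random.default_rng(seed)
        spans = set()
        while len(spans) < 30:
            s = int(rng.integers(0, 5_000))
            e = s + int(rng.integers(5, 2_000))
            # keep the laminar structure a nesting process produces:
            # reject spans partially overlapping an existing span
            if all(e2 <= s or s2 >= e or (s2 <= s and e <= e2)
                   or (s <= s2 and e2 <= e) for s2, e2 in spans):
                spans.add((s, e))
        spans = sorted(spans)
        els = self._elements(spans)
        got = sorted(
            (int(p.nested_id[1:]), int(p.original_id[1:]))
            for p in call_nested_pairs(els)
        )
        assert got == _brute_force_pairs(spans)

    def test_no_same_level_overlap_in_detection(self, detected):
        els = [AnnotatedElement(id=f"c{i}", genome_id="g", start=c.span[0],
                                end=c.span[1]) for i, c in enumerate(detected)]
        call_nested_pairs(els)
        by_level: dict[int, list] = {}
        for el in els:
            by_level.setdefault(el.nesting_level, []).append(el)
        for level_els in by_level.values():
            level_els.sort(key=lambda e: e.start)
            for a, b in zip(level_els, level_els[1:]):
                assert a.end <= b.start
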