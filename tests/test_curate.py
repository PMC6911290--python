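"""Curation: TSD calls, RT filter, superfamily/family classification."""

from __future__ import annotations

import numpy as np
import pytest

from retronest.curate import (
    classify_family,
    classify_superfamily,
    curate,
    detect_tsd,
    require_rt_domain,
)
from retronest.models import COPIA, GYPSY, UNKNOWN, AnnotatedElement
from retronest.sequences import mutate, random_dna
from retronest.simulate import plant_genome
from retronest.models import SimConfig


def _element(regions, start=0, end=1000, **kw):
    return AnnotatedElement(id="x", genome_id="g", start=start, end=end,
                            regions=regions, **kw)


class TestDetectTsd:
    def _genome_with(self, left_word, right_word, elem_len=50, pad=100):
        rng = np.random.default_rng(0)
        left = random_dna(pad, rng=rng) + left_word
        right = right_word + random_dna(pad, rng=rng)
        elem = random_dna(elem_len, rng=rng)
        genome = left + elem + right
        el = _element({}, start=len(left), end=len(left) + elem_len)
        return genome, el

    def test_exact_five_bp_duplication(self):
        genome, el = self._genome_with("ATGCA", "ATGCA")
        rec = detect_tsd(genome, el)
        assert rec is not None and rec.length == 5 and rec.seq == "ATGCA"

    def test_longest_k_wins(self):
        genome, el = self._genome_with("GATGCA", "GATGCA")
        rec = detect_tsd(genome, el)
        assert rec.length == 6 and rec.seq == "GATGCA"

    def test_longest_first_matches_bruteforce(self):
        """Brute force over k confirms the 6,5,4 search order returns the
        longest exact duplication."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            word = random_dna(6, rng=rng)
            genome, el = self._genome_with(word, word)
            expect = max(
                (k for k in (4, 5, 6)
                 if genome[el.start - k:el.start] == genome[el.end:el.end + k]),
                default=None,
            )
            rec = detect_tsd(genome, el)
            assert rec is not None and rec.length == expect

    def test_absent_when_flanks_unrelated(self):
        genome, el = self._genome_with("AAAAA", "CCCCC")
        # guard against accidental 4-mers
        if genome[el.start - 4:el.start] != genome[el.end:el.end + 4]:
            assert detect_tsd(genome, el) is None

    def test_contig_edge_returns_none(self):
        genome = random_dna(60, rng=np.random.default_rng(1))
        el = _element({}, start=2, end=58)
        assert detect_tsd(genome, el) is None


class TestRtFilter:
    def test_mixed_set_counts(self):
        els = [_element({"RT": (10, 20)}) for _ in range(7)]
        els += [_element({"GAG": (5, 9)}) for _ in range(3)]
        assert len(require_rt_domain(els)) == 7

    def test_identity_on_complete_set(self):
        els = [_element({"RT": (10, 20)}) for _ in range(4)]
        assert require_rt_domain(els) == els


class TestClassifySuperfamily:
    def test_gypsy_order(self):
        el = _element({"GAG": (0, 10), "AP": (10, 20), "RT": (20, 30),
                       "RH": (30, 40), "INT": (40, 50)})
        assert classify_superfamily(el) == GYPSY

    def test_copia_order(self):
        el = _element({"GAG": (0, 10), "AP": (10, 20), "INT": (20, 30),
                       "RT": (30, 40), "RH": (40, 50)})
        assert classify_superfamily(el) == COPIA

    def test_insufficient_domains_unknown(self):
        assert classify_superfamily(_element({"GAG": (0, 10)})) == UNKNOWN


class TestClassifyFamily:
    def test_verbatim_rt_hits_its_family(self, panel):
        model = next(m for m in panel if m.family == "Tekay")
        el = _element({"RT": (0, 1)})
        el.rt_seq = model.consensus["RT"]
        family, ident = classify_family(el, panel)
        assert family == "Tekay"
        assert ident == pytest.approx(100.0)

    def test_mutated_rt_still_classified(self, panel, rng):
        model = next(m for m in panel if m.family == "Ogre")
        el = _element({"RT": (0, 1)})
        el.rt_seq = mutate(model.consensus["RT"], 0.10, rng)
        family, ident = classify_family(el, panel)
        assert family == "Ogre"
        assert ident > 85

    def test_random_sequence_unknown(self, panel, rng):
        el = _element({"RT": (0, 1)})
        el.rt_seq = random_dna(800, gc=0.44, rng=rng)
        family, ident = classify_family(el, panel)
        assert family == UNKNOWN
        assert ident < 60

    def test_empty_panel_invalid(self):
        el = _element({"RT": (0, 1)})
        el.rt_seq = "ACGT" * 100
        with pytest.raises(ValueError):
            classify_family(el, [])


class TestCurate:
    def test_planted_families_recovered(self, sim, curated):
        """Nearly all elements at <= 10% divergence are assigned their true
        planted family and superfamily."""
        _, _, truth = sim

        def truth_match(el):
            return min(truth.elements,
                       key=lambda t: abs(t.start - el.start) + abs(t.end - el.end))

        fam_ok = sf_ok = 0
        for el in curated.elements:
            t = truth_match(el)
            fam_ok += el.family == t.family
            sf_ok += el.superfamily == t.superfamily
        assert fam_ok >= 0.95 * len(curated.elements)
        assert sf_ok >= 0.95 * len(curated.elements)

    def test_pairs_require_original_tsd(self, curated):
        by_id = {el.id: el for el in curated.elements}
        for p in curated.pairs:
            assert by_id[p.original_id].tsd is not None
        for p in curated.pairs_motif:
            assert by_id[p.nested_id].tsd is not None

    def test_non_nested_are_solitary_with_tsd(self, curated):
        nested_or_host = {p.nested_id for p in curated.pairs} | \
            {p.original_id for p in curated.pairs}
        for el in curated.non_nested:
            assert el.tsd is not None
            assert el.id not in nested_or_host

    def test_order_stable(self, sim, panel, detected):
        from retronest.curate import annotate_elements
        _, genome, _ = sim
        els = annotate_elements(detected, panel, genome=genome)
        fwd = curate(els, genome)
        rev = curate(list(reversed(els)), genome)
        assert [e.id for e in fwd.elements] == [e.id for e in rev.elements]
        assert [(p.nested_id, p.original_id) for p in fwd.pairs] == \
            [(p.nested_id, p.original_id) for p in rev.pairs]

    def test_planted_tsds_recalled_exactly_on_truth_spans(self):
        """detect_tsd at the true element boundaries returns the planted TSD
        for every non-edge element (flanks are age-0 by construction)."""
        cfg = SimConfig(genome_length_bp=200_000, n_elements=15,
                        nesting_fraction=0.3, rng_seed=8)
        genome, truth = plant_genome(cfg)
        for el in truth.elements:
            rec = detect_tsd(genome, el)
            assert rec is not None
            assert (rec.length, rec.seq) == (el.tsd.length, el.tsd.seq)
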