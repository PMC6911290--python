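"""Region preference statistics: assignment, expectations, GOF testing,
autoinsertion matrix, superfamily enrichment, recent/old split."""

from __future__ import annotations

import numpy as np
import pytest

from retronest.models import AnnotatedElement, NestedPair
from retronest.regions import (
    assign_region,
    autoinsertion_matrix,
    expected_counts,
    gof_test,
    recent_old_split,
    superfamily_enrichment,
)


def _original():
    regions = {
        "LTR5": (1000, 1900), "pbs": (1900, 1918), "5UTR": (1918, 2400),
        "GAG": (2400, 3600), "GAG-AP": (3600, 3750), "AP": (3750, 4350),
        "AP-RT": (4350, 4500), "RT": (4500, 5250), "RT-RH": (5250, 5410),
        "RH": (5410, 5860), "RH-INT": (5860, 6010), "INT": (6010, 6860),
        "3UTR": (6860, 8060), "ppt": (8060, 8075), "LTR3": (8075, 8975),
    }
    return AnnotatedElement(id="orig", genome_id="g", start=1000, end=8975,
                            regions=regions, superfamily="gypsy")


def _pair(offset):
    return NestedPair(nested_id="n", original_id="orig",
                      insertion_offset=offset)


class TestAssignRegion:
    def test_offset_inside_domain(self):
        # offsets are relative to the element start at genome position 1000
        assert assign_region(_pair(3600), _original()) == "RT"
        assert assign_region(_pair(2900), _original()) == "AP"

    def test_interdomain_label(self):
        assert assign_region(_pair(4300), _original()) == "RT-RH"
        assert assign_region(_pair(3400), _original()) == "AP-RT"

    def test_boundary_base_belongs_downstream(self):
        # offset 2600 is genome position 3600, the first base of GAG-AP
        assert assign_region(_pair(2600), _original()) == "GAG-AP"
        # one before is the last base of GAG
        assert assign_region(_pair(2599), _original()) == "GAG"

    def test_gap_uses_nearest_boundary_with_warning(self):
        orig = _original()
        del orig.regions["AP"]
        with pytest.warns(UserWarning):
            label = assign_region(_pair(3000), orig)
        assert label in ("GAG-AP", "AP-RT")

    def test_offset_outside_original_rejected(self):
        with pytest.raises(ValueError):
            assign_region(_pair(20_000), _original())


class TestExpectedCounts:
    def test_formula(self):
        lengths = {"3UTR": 1_000.0, "rest": 9_000.0}
        exp = expected_counts(lengths, 50)
        assert exp["3UTR"] == pytest.approx(5.0)

    def test_zero_nested(self):
        exp = expected_counts({"a": 10.0, "b": 20.0}, 0)
        assert all(v == 0 for v in exp.values())

    @pytest.mark.parametrize("n", [1, 17, 400])
    def test_sum_is_exactly_n(self, n):
        rng = np.random.default_rng(n)
        lengths = {f"r{i}": float(v)
                   for i, v in enumerate(rng.integers(10, 2_000, size=12))}
        assert sum(expected_counts(lengths, n).values()) == \
            pytest.approx(n, rel=1e-12)


class TestGofTest:
    def test_perfect_fit(self):
        O = {"a": 10, "b": 20}
        E = {"a": 10.0, "b": 20.0}
        res = gof_test(O, E, region_order=["a", "b"])
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_global == pytest.approx(1.0)
        assert not res.table.significant.any()

    def test_hand_computed_statistic(self):
        # O=(16,4) vs E=(10,10): X^2 = 3.6 + 3.6 = 7.2 on 1 df
        res = gof_test({"a": 16, "b": 4}, {"a": 10.0, "b": 10.0},
                       region_order=["a", "b"])
        assert res.chi2 == pytest.approx(7.2)
        assert res.df == 1

    def test_bh_adjustment_textbook_example(self):
        from statsmodels.stats.multitest import multipletests
        _, adj, _, _ = multipletests([0.01, 0.02, 0.9], method="fdr_bh")
        assert adj == pytest.approx([0.03, 0.03, 0.9])

    def test_sparse_regions_pooled(self):
        O = {"a": 30, "b": 1, "c": 30}
        E = {"a": 30.0, "b": 0.4, "c": 30.6}
        res = gof_test(O, E, region_order=["a", "b", "c"])
        assert all(res.table.expected >= 1.0)
        assert res.pooled  # b merged somewhere

    def test_mismatched_regions_rejected(self):
        with pytest.raises(ValueError):
            gof_test({"a": 5, "z": 1}, {"a": 6.0})

    def test_null_global_p_approximately_uniform(self):
        """Counts drawn from the length-proportional null give a global p
        whose rejection rate at 0.05 stays near nominal (200 replicates)."""
        rng = np.random.default_rng(12)
        lengths = {f"r{i}": float(v)
                   for i, v in enumerate([900, 18, 480, 1200, 150, 600, 750,
                                          450, 850, 1200, 15, 900])}
        total = sum(lengths.values())
        probs = np.array([v / total for v in lengths.values()])
        names = list(lengths)
        hits = 0
        for _ in range(200):
            counts = rng.multinomial(2_000, probs)
            O = dict(zip(names, counts))
            E = expected_counts(lengths, 2_000)
            res = gof_test(O, E, region_order=names)
            hits += res.p_global < 0.05
        assert 0.02 * 200 <= hits <= 0.09 * 200


class TestAutoinsertionMatrix:
    def test_pure_autoinsertion(self):
        pairs = [NestedPair("n", "o", 0, nested_family="Tekay",
                            original_family="Tekay") for _ in range(5)]
        matrix, frac = autoinsertion_matrix(pairs)
        assert matrix.loc["Tekay", "Tekay"] == 5
        assert frac["Tekay"] == 1.0

    def test_counts_conserved(self, curated):
        matrix, _ = autoinsertion_matrix(curated.pairs)
        assert matrix.to_numpy().sum() == len(curated.pairs)

    def test_biased_fraction_recovered(self):
        """1,000 pairs with autoinsertion probability 0.5 recover a diagonal
        fraction inside the binomial 99% CI."""
        rng = np.random.default_rng(5)
        fams = ["Tekay", "Ogre", "Reina", "Ale"]
        pairs = []
        for _ in range(1_000):
            if rng.random() < 0.5:
                f = "Tekay"
                pairs.append(NestedPair("n", "o", 0, nested_family=f,
                                        original_family=f))
            else:
                pairs.append(NestedPair(
                    "n", "o", 0, nested_family="Tekay",
                    original_family=fams[rng.integers(1, 4)]))
        _, frac = autoinsertion_matrix(pairs)
        se = np.sqrt(0.5 * 0.5 / 1_000)
        assert abs(frac["Tekay"] - 0.5) < 2.58 * se


class TestSuperfamilyEnrichment:
    def test_independence_gives_zero(self):
        res = superfamily_enrichment((10, 10), (10, 10))
        assert res["chi2"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_swap_invariance(self):
        a = superfamily_enrichment((20, 5), (100, 200))
        b = superfamily_enrichment((5, 20), (200, 100))
        assert a["chi2"] == pytest.approx(b["chi2"])

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            superfamily_enrichment((0, 0), (10, 10))


class TestRecentOldSplit:
    def _pairs(self, deltas):
        out = []
        for i, d in enumerate(deltas):
            p = NestedPair(f"n{i}", "o", 0)
            p.identity_delta = d
            out.append(p)
        return out

    def test_threshold_semantics(self):
        pairs = self._pairs([0.5, 1.0, 3.0, 5.0, 7.2, 0.0])
        recent, old = recent_old_split(pairs)
        assert {p.nested_id for p in recent} == {"n0", "n1"}
        assert {p.nested_id for p in old} == {"n3", "n4"}

    def test_subsets_disjoint(self):
        pairs = self._pairs(list(np.linspace(-1, 10, 45)))
        recent, old = recent_old_split(pairs)
        assert not ({p.nested_id for p in recent}
                    & {p.nested_id for p in old})
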