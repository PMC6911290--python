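"""Reference counts from a published 12-genome plant survey of nested LTR
retrotransposons, used as consistency inputs.

These are the printed summary counts of the genome-scale survey whose
analysis workflow this package re-implements at desk scale: curated
nested/original pair and solitary-element totals, per-superfamily
decompositions, and target-site-duplication length spectra. They serve two
purposes: (i) arithmetic consistency targets (totals, fractions and ratios
recomputed from the per-class counts), and (ii) realistic default
proportions for the simulator (e.g. the 5/4/6-bp TSD spectrum).
"""

from __future__ import annotations

#: nested pairs retained after curation, by TSD length of the nested element
NESTED_TSD_COUNTS = {5: 765, 4: 61, 6: 4}

#: solitary (non-nested) elements with TSDs, by TSD length
NON_NESTED_TSD_COUNTS = {5: 12_144, 4: 1_661, 6: 178}

#: all elements (nested + non-nested) by TSD length
ALL_TSD_COUNTS = {5: 12_909, 4: 1_722, 6: 182}

#: nested and non-nested elements by superfamily (gypsy, copia)
NESTED_BY_SUPERFAMILY = (2_407, 353)
NON_NESTED_BY_SUPERFAMILY = (8_635, 5_348)

#: nested insertions whose original element belongs to each superfamily
INSERTIONS_INTO_SUPERFAMILY = {"gypsy": 674, "copia": 156}

#: original elements with an established insertion position (gypsy, copia)
ORIGINALS_WITH_POSITION = (1_015, 230)

#: curated totals reported directly
REPORTED_PAIR_TOTAL = 1_491
REPORTED_NON_NESTED_TOTAL = 13_983


def nested_pairs_with_tsd_total() -> int:
    """Total curated nested pairs with a TSD on the nested element."""
    return sum(NESTED_TSD_COUNTS.values())


def non_nested_total() -> int:
    """Total solitary elements, from the per-TSD decomposition."""
    return sum(NON_NESTED_TSD_COUNTS.values())


def tsd_fraction_pct(k: int) -> float:
    """Percentage of all elements flanked by a k-bp TSD."""
    total = sum(ALL_TSD_COUNTS.values())
    return 100.0 * ALL_TSD_COUNTS[k] / total


def gypsy_copia_insertion_ratio() -> float:
    """How many times more often nested elements target gypsy originals."""
    return (INSERTIONS_INTO_SUPERFAMILY["gypsy"]
            / INSERTIONS_INTO_SUPERFAMILY["copia"])


def originals_with_position_total() -> int:
    return sum(ORIGINALS_WITH_POSITION)
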