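"""Synthetic genomes with planted LTR retrotransposons and exact ground truth.

The generator emulates the phenomenology of nested LTR retrotransposons in
plant genomes: 18 families split evenly between the Ty3/gypsy and Ty1/copia
superfamilies, superfamily-specific protein domain order (gypsy:
GAG-AP-RT-RH-INT[-CHR]; copia: GAG-AP-INT-RT-RH), 4/5/6-bp target site
duplications with composition biases, age-dependent LTR divergence, and
nesting events drawn from a configurable region-preference distribution.
Optionally, insertion sites are seeded with approximate palindromes and/or
10-bp phased WW dinucleotides so that downstream motif and nucleosome
analyses have a planted signal to recover.

Mutations are substitutions only, so every planted coordinate stays exact.
Elements are inserted oldest first; a nested element is therefore always
younger than its host.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .models import (
    COPIA,
    GYPSY,
    AnnotatedElement,
    ElementModel,
    GroundTruth,
    NestedPair,
    SimConfig,
    Span,
    TsdRecord,
)
from .sequences import mutate, random_dna, revcomp

GYPSY_FAMILIES = (
    "Athila", "CRM", "Galadriel", "Ogre", "Phygy",
    "Reina", "Retand", "Tcn1", "Tekay",
)
COPIA_FAMILIES = (
    "Ale", "Angela", "Bryco", "Bianca", "Ikeros",
    "Ivana", "SIRE", "TAR", "Tork",
)

#: gypsy families modelled with a chromodomain; the others route their 3'
#: noncoding region through the "CHR-ppt" slot of the gypsy region schema
CHR_FAMILIES = frozenset({"Tekay", "CRM", "Tcn1", "Phygy"})

#: families whose TSD-length spectrum favours 4 bp over the canonical 5 bp
SHORT_TSD_FAMILIES = frozenset({"Galadriel", "Phygy", "Bryco"})

_TSD_PROBS_DEFAULT = {5: 0.87, 4: 0.11, 6: 0.02}
_TSD_PROBS_SHORT = {4: 0.60, 5: 0.35, 6: 0.05}

#: the seed pinning the reference family panel used for classification
PANEL_SEED = 1729

# minimum clearance (bp) between an insertion cut and any element boundary,
# so that TSD ground truth is never split by a later insertion
_CUT_CLEARANCE = 10
_EDGE_MARGIN = 20

_WW = ("AA", "AT", "TA", "TT")

# per-position base profiles for composition-biased TSDs (A, C, G, T)
_P_AT = (0.40, 0.10, 0.10, 0.40)
_P_GC = (0.10, 0.40, 0.40, 0.10)
_P_LEFT = (0.30, 0.30, 0.30, 0.10)   # T depleted 5' of the TSD core
_P_RIGHT = (0.10, 0.30, 0.30, 0.30)  # A depleted 3' of the TSD core
_TSD_PROFILE = {
    4: (_P_AT, _P_GC, _P_GC, _P_AT),
    5: (_P_LEFT, _P_AT, _P_AT, _P_AT, _P_RIGHT),
    6: (_P_LEFT, _P_AT, _P_AT, _P_AT, _P_AT, _P_RIGHT),
}


class CapacityError(RuntimeError):
    """The genome cannot host the requested number of insertions."""


def _gypsy_layout(has_chr: bool) -> list[tuple[str, int, int]]:
    layout = [
        ("LTR5", 900, 60),
        ("pbs", 18, 0),
        ("5UTR", 480, 60),
        ("GAG", 1200, 80),
        ("GAG-AP", 150, 30),
        ("AP", 600, 50),
        ("AP-RT", 150, 30),
        ("RT", 750, 50),
        ("RT-RH", 160, 30),
        ("RH", 450, 40),
        ("RH-INT", 150, 30),
        ("INT", 850, 60),
    ]
    if has_chr:
        layout += [("INT-CHR", 130, 30), ("CHR", 400, 40), ("3UTR", 1200, 100)]
    else:
        layout += [("CHR-ppt", 1200, 100)]
    layout += [("ppt", 15, 0), ("LTR3", 900, 60)]
    return layout


def _copia_layout() -> list[tuple[str, int, int]]:
    return [
        ("LTR5", 900, 60),
        ("pbs", 18, 0),
        ("5UTR", 480, 60),
        ("GAG", 1100, 80),
        ("GAG-AP", 150, 30),
        ("AP", 600, 50),
        ("AP-INT", 150, 30),
        ("INT", 850, 60),
        ("INT-RT", 150, 30),
        ("RT", 750, 50),
        ("RT-RH", 160, 30),
        ("RH", 450, 40),
        ("3UTR", 900, 100),
        ("ppt", 15, 0),
        ("LTR3", 900, 60),
    ]


def build_family_panel(seed: int = PANEL_SEED, element_gc: float = 0.44) -> list[ElementModel]:
    """Build the 18-family reference panel (9 gypsy + 9 copia).

    Consensus sequences are drawn i.i.d. at ``element_gc`` from a generator
    seeded with ``seed``, so the panel is fully deterministic. Each region's
    consensus is generated 3 SD longer than its mean so that realized region
    lengths sampled at synthesis time always fit within it.
    """
    rng = np.random.default_rng(seed)
    panel: list[ElementModel] = []
    for superfamily, families in ((GYPSY, GYPSY_FAMILIES), (COPIA, COPIA_FAMILIES)):
        for family in families:
            has_chr = superfamily == GYPSY and family in CHR_FAMILIES
            layout = _gypsy_layout(has_chr) if superfamily == GYPSY else _copia_layout()
            consensus: dict[str, str] = {}
            for name, mean, sd in layout:
                if name == "LTR3":
                    consensus[name] = consensus["LTR5"]
                    continue
                consensus[name] = random_dna(mean + 3 * sd, gc=element_gc, rng=rng)
            probs = _TSD_PROBS_SHORT if family in SHORT_TSD_FAMILIES else _TSD_PROBS_DEFAULT
            panel.append(
                ElementModel(
                    family=family,
                    superfamily=superfamily,
                    layout=layout,
                    consensus=consensus,
                    tsd_length_probs=dict(probs),
                    has_chr=has_chr,
                    gc=element_gc,
                )
            )
    return panel


def synthesize_element(
    model: ElementModel,
    age_mya: float,
    mu: float,
    rng: np.random.Generator,
    element_id: str = "el",
    genome_id: str = "genome",
) -> AnnotatedElement:
    """Realize one element from its family template at a given age.

    Both LTRs start from the same realized LTR sequence; the whole element
    then accumulates substitutions at per-site probability ``q = mu * age *
    1e6`` independently per copy, so the expected pairwise LTR divergence is
    approximately ``2 q (1 - q)`` — the classical molecular clock the dating
    stage inverts. The element's annotated sub-spans (local, 0-based) are
    exact because no indels are introduced.
    """
    if age_mya < 0:
        raise ValueError(f"age must be >= 0, got {age_mya}")
    if mu <= 0:
        raise ValueError(f"mu must be > 0, got {mu}")
    realized: dict[str, int] = {}
    for name, mean, sd in model.layout:
        if name == "LTR3":
            realized[name] = realized["LTR5"]
            continue
        if sd == 0:
            length = mean
        else:
            length = int(round(rng.normal(mean, sd)))
            length = max(30, min(length, len(model.consensus[name])))
        realized[name] = length

    parts: list[str] = []
    regions: dict[str, Span] = {}
    pos = 0
    for name, _, _ in model.layout:
        length = realized[name]
        parts.append(model.consensus[name][:length])
        regions[name] = (pos, pos + length)
        pos += length
    seq = "".join(parts)

    q = min(0.75, mu * age_mya * 1e6)
    seq = mutate(seq, q, rng)

    element = AnnotatedElement(
        id=element_id,
        genome_id=genome_id,
        start=0,
        end=len(seq),
        ltr5=regions["LTR5"],
        ltr3=regions["LTR3"],
        regions=regions,
        family=model.family,
        superfamily=model.superfamily,
        tsd=None,
        age_mya=age_mya,
        seq=seq,
        ltr5_seq=seq[regions["LTR5"][0]:regions["LTR5"][1]],
        ltr3_seq=seq[regions["LTR3"][0]:regions["LTR3"][1]],
        rt_seq=seq[regions["RT"][0]:regions["RT"][1]],
    )
    return element


def _sample_tsd(k: int, rng: np.random.Generator) -> str:
    """Sample a composition-biased TSD of length k (AT-rich core for 5/6 bp,
    GC-rich core for 4 bp, with the flanking asymmetry seen in TSD logos)."""
    bases = np.array(list("ACGT"))
    return "".join(rng.choice(bases, p=np.array(p)) for p in _TSD_PROFILE[k])


def _region_weight(name: str, weights: dict[str, float]) -> float:
    if name in weights:
        return weights[name]
    if name == "CHR-ppt" and "3UTR" in weights:
        return weights["3UTR"]
    return weights.get("*", 1.0)


def _subtract_intervals(base: Span, blocked: list[Span]) -> list[Span]:
    """Intervals of ``base`` not covered by any blocked interval."""
    out: list[Span] = []
    lo, hi = base
    for bs, be in sorted(blocked):
        if be <= lo or bs >= hi:
            continue
        if bs > lo:
            out.append((lo, bs))
        lo = max(lo, be)
        if lo >= hi:
            break
    if lo < hi:
        out.append((lo, hi))
    return out


@dataclass
class _Placed:
    element: AnnotatedElement
    tsd_left: Span
    tsd_right: Span


def _shift_span(span: Span, q: int, b: int) -> Span:
    s, e = span
    if s >= q:
        return (s + b, e + b)
    if e > q:
        return (s, e + b)
    return span


def _shift_all(placed: list[_Placed], q: int, b: int) -> None:
    for p in placed:
        el = p.element
        el.start, el.end = _shift_span((el.start, el.end), q, b)
        if el.ltr5:
            el.ltr5 = _shift_span(el.ltr5, q, b)
        if el.ltr3:
            el.ltr3 = _shift_span(el.ltr3, q, b)
        el.regions = {n: _shift_span(s, q, b) for n, s in el.regions.items()}
        p.tsd_left = _shift_span(p.tsd_left, q, b)
        p.tsd_right = _shift_span(p.tsd_right, q, b)


def plant_genome(
    config: SimConfig, panel: list[ElementModel] | None = None
) -> tuple[str, GroundTruth]:
    """Simulate a genome with planted elements and return (sequence, truth).

    Insertions proceed oldest first. Each insertion cuts the genome at a
    sampled site, duplicates a 4/5/6-bp target word on both sides of the new
    element, and shifts/expands all previously planted annotations so the
    ground truth stays in final-genome coordinates. Nested insertion offsets
    are drawn per-region from ``config.region_preference_weights`` applied to
    the host's realized region spans. Cut sites keep >= 10 bp clearance from
    every element boundary so TSDs are never split.
    """
    config.validate()
    if panel is None:
        panel = build_family_panel(config.panel_seed, element_gc=config.element_gc)
    by_family = {m.family: m for m in panel}

    ss = np.random.SeedSequence(config.rng_seed)
    plan_rng, seq_rng, place_rng, bias_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    genome_id = "synth1"
    genome = random_dna(config.genome_length_bp, gc=config.gc_fraction, rng=seq_rng)
    base_genome = genome

    # oldest-first insertion plan
    fam_idx = plan_rng.integers(0, len(panel), size=config.n_elements)
    ages = plan_rng.uniform(config.age_range_mya[0], config.age_range_mya[1],
                            size=config.n_elements)
    order = np.argsort(-ages)
    plan = [(panel[fam_idx[i]], float(ages[i])) for i in order]

    placed: list[_Placed] = []
    pairs: list[NestedPair] = []

    def blocked_intervals() -> list[Span]:
        out = []
        for p in placed:
            out.append((p.tsd_left[0] - _CUT_CLEARANCE, p.tsd_right[1] + _CUT_CLEARANCE))
        return out

    def write(pos: int, word: str, host: AnnotatedElement | None) -> None:
        """Rewrite genome bases, refusing to touch other elements (the host
        body may legitimately be rewritten at a nested target site)."""
        nonlocal genome, base_genome
        if pos < 0 or pos + len(word) > len(genome):
            return
        for p in placed:
            if host is not None and p.element.id == host.id:
                continue
            if host is not None and _contains(p.element, host):
                continue  # ancestors of the host contain the cut by definition
            if pos < p.tsd_right[1] and pos + len(word) > p.tsd_left[0]:
                return
        genome = genome[:pos] + word + genome[pos + len(word):]

    def _contains(outer: AnnotatedElement, inner: AnnotatedElement) -> bool:
        return outer.start <= inner.start and inner.end <= outer.end and outer.id != inner.id

    for idx, (model, age) in enumerate(plan):
        el_id = f"TE{idx + 1:04d}"
        element = synthesize_element(model, age, config.mutation_rate_mu,
                                     seq_rng, element_id=el_id, genome_id=genome_id)

        # -- choose a host (or none) --------------------------------------
        host: AnnotatedElement | None = None
        eligible = [p.element for p in placed
                    if p.element.nesting_level < config.max_nesting_depth]
        if eligible and plan_rng.random() < config.nesting_fraction:
            bias = config.autoinsertion_bias.get(model.family, 0.0)
            same = [h for h in eligible if h.family == model.family]
            if same and plan_rng.random() < bias:
                host = same[plan_rng.integers(0, len(same))]
            else:
                host = eligible[plan_rng.integers(0, len(eligible))]

        # -- choose the cut -----------------------------------------------
        cut = None
        region_label = None
        if host is not None:
            names = list(host.regions)
            w = np.array([_region_weight(n, config.region_preference_weights)
                          for n in names], dtype=float)
            if w.sum() <= 0:
                w[:] = 1.0
            w = w / w.sum()
            interior = (host.start + _CUT_CLEARANCE, host.end - _CUT_CLEARANCE)
            # blocked spans: every element except the host and its ancestors
            blk = []
            for p in placed:
                if p.element.id == host.id or _contains(p.element, host):
                    continue
                blk.append((p.tsd_left[0] - _CUT_CLEARANCE,
                            p.tsd_right[1] + _CUT_CLEARANCE))
            for _ in range(60):
                name = names[place_rng.choice(len(names), p=w)]
                rs, re = host.regions[name]
                lo, hi = max(rs, interior[0]), min(re, interior[1])
                if hi <= lo:
                    continue
                free = _subtract_intervals((lo, hi), blk)
                total = sum(b - a for a, b in free)
                if total <= 0:
                    continue
                r = int(place_rng.integers(0, total))
                for a, b in free:
                    if r < b - a:
                        cut = a + r
                        break
                    r -= b - a
                region_label = name
                break
            if cut is None:
                host = None  # host too crowded; fall through to intergenic

        if host is None:
            blk = blocked_intervals()
            lo, hi = _EDGE_MARGIN, len(genome) - _EDGE_MARGIN
            if hi <= lo:
                raise CapacityError("genome too short for requested insertions")
            free = _subtract_intervals((lo, hi), blk)
            total = sum(b - a for a, b in free)
            if total <= 0:
                raise CapacityError(
                    f"no insertion site left after {len(placed)} insertions"
                )
            r = int(place_rng.integers(0, total))
            for a, b in free:
                if r < b - a:
                    cut = a + r
                    break
                r -= b - a

        assert cut is not None

        # -- target-site rewrites (biases) ---------------------------------
        probs = model.tsd_length_probs
        ks = sorted(probs)
        k = int(place_rng.choice(ks, p=np.array([probs[x] for x in ks])))
        if bias_rng.random() < config.tsd_motif_bias:
            write(cut, _sample_tsd(k, bias_rng), host)
        if config.palindrome_bias > 0 and bias_rng.random() < config.palindrome_bias:
            arm = genome[cut - 5:cut]
            if len(arm) == 5 and "N" not in arm:
                write(cut + k, revcomp(arm), host)
        if config.periodicity_bias > 0 and bias_rng.random() < config.periodicity_bias:
            for off in range(-70, 71, 10):
                write(cut + off, _WW[bias_rng.integers(0, 4)], host)

        # -- insert ---------------------------------------------------------
        tsd_seq = genome[cut:cut + k]
        el_len = element.length
        b_ins = el_len + k  # net inserted length
        q = cut + k         # element start after duplication
        genome = genome[:q] + element.seq + tsd_seq + genome[q:]
        _shift_all(placed, q, b_ins)

        element.start += q
        element.end += q
        element.ltr5 = (element.ltr5[0] + q, element.ltr5[1] + q)
        element.ltr3 = (element.ltr3[0] + q, element.ltr3[1] + q)
        element.regions = {n: (s + q, e + q) for n, (s, e) in element.regions.items()}
        element.tsd = TsdRecord(element_id=el_id, length=k, seq=tsd_seq)
        if host is not None:
            element.parent_id = host.id
            element.nesting_level = host.nesting_level + 1
            pairs.append(
                NestedPair(
                    nested_id=el_id,
                    original_id=host.id,
                    insertion_offset=q - host.start,
                    region_label=region_label,
                    same_family=model.family == host.family,
                    nested_family=model.family,
                    original_family=host.family,
                    original_superfamily=host.superfamily,
                )
            )
        placed.append(_Placed(element=element,
                              tsd_left=(q - k, q),
                              tsd_right=(element.end, element.end + k)))

    elements = [p.element for p in placed]
    for el in elements:
        if el.tsd is not None:
            el.tsd.left_flank = genome[max(0, el.start - el.tsd.length - 50):
                                       el.start - el.tsd.length]
            el.tsd.right_flank = genome[el.end + el.tsd.length:
                                        el.end + el.tsd.length + 50]
    truth = GroundTruth(genome_id=genome_id, elements=elements, pairs=pairs,
                        base_genome=base_genome)
    _check_truth(truth)
    return genome, truth


def _check_truth(truth: GroundTruth) -> None:
    by_id = {el.id: el for el in truth.elements}
    for el in truth.elements:
        if el.parent_id is not None:
            host = by_id[el.parent_id]
            if not (host.start < el.start and el.end < host.end):
                raise AssertionError(f"{el.id} not strictly inside {host.id}")
            if not (el.age_mya < host.age_mya):
                warnings.warn(f"{el.id} not younger than host {host.id}")


def excise_all(genome: str, truth: GroundTruth) -> str:
    """Remove every planted element (plus one TSD copy) innermost first.

    With all site-rewrite biases at zero this reconstructs the pre-insertion
    genome byte for byte; with biases on, the rewritten target-site bases
    remain (they were written before insertion by construction).
    """
    spans = {
        el.id: [el.start, el.end, el.tsd.length if el.tsd else 0, el.nesting_level]
        for el in truth.elements
    }
    order = sorted(spans, key=lambda i: (-spans[i][3], -spans[i][0]))
    g = genome
    for el_id in order:
        s, e, k, _ = spans.pop(el_id)
        cut_end = e + k
        g = g[:s] + g[cut_end:]
        removed = cut_end - s
        for sp in spans.values():
            if sp[0] >= cut_end:
                sp[0] -= removed
                sp[1] -= removed
            elif sp[1] >= cut_end:  # a host containing the removed block
                sp[1] -= removed
    return g
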