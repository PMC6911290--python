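"""Quality filters and family/superfamily assignment for detected elements.

The curation pipeline mirrors the selection applied to genome-scale nested
TE surveys: require a detectable RT domain, call nested/original pairs by
containment, keep only pairs whose original element is flanked by an exact
target site duplication (and, for motif analyses, whose nested element has
one too), and assign each element a family by reverse-transcriptase
similarity against an 18-family reference panel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import edlib

from .detect import CandidateElement, call_nested_pairs
from .models import (
    COPIA,
    DOMAIN_NAMES,
    GYPSY,
    UNKNOWN,
    AnnotatedElement,
    ElementModel,
    NestedPair,
    Span,
    TsdRecord,
)

logger = logging.getLogger(__name__)

#: worst acceptable normalized edit distance when locating a domain consensus
_MAX_DOMAIN_DIST = 0.35


def detect_tsd(
    genome: str, element: AnnotatedElement, allowed_k: tuple[int, ...] = (6, 5, 4)
) -> TsdRecord | None:
    """Exact TSD call: longest k in ``allowed_k`` (checked in order) such that
    the k bases immediately 5' of the element equal the k bases immediately
    3' of it. Returns None when no flank word of any allowed length matches,
    or (with ``edge=True`` logged) when the element abuts a contig edge."""
    s, e = element.start, element.end
    if s < max(allowed_k) or e + max(allowed_k) > len(genome):
        logger.info("element %s at contig edge; no TSD call", element.id)
        return None
    for k in allowed_k:
        left = genome[s - k:s]
        if "N" not in left and left == genome[e:e + k]:
            lf = genome[max(0, s - k - 50):s - k]
            rf = genome[e + k:e + k + 50]
            return TsdRecord(element_id=element.id, length=k, seq=left,
                            left_flank=lf, right_flank=rf)
    return None


def require_rt_domain(elements: list[AnnotatedElement]) -> list[AnnotatedElement]:
    """Keep only elements whose annotated regions include an RT domain."""
    kept = [el for el in elements if "RT" in el.regions]
    removed = len(elements) - len(kept)
    if removed:
        logger.info("RT filter removed %d of %d elements", removed, len(elements))
    return kept


def classify_superfamily(element: AnnotatedElement) -> str:
    """gypsy if INT lies 3' of RH, copia if INT lies 5' of RT, else unknown."""
    regions = element.regions
    int_span = regions.get("INT")
    rt_span = regions.get("RT")
    rh_span = regions.get("RH")
    if int_span is None or (rt_span is None and rh_span is None):
        return UNKNOWN

    def center(span: Span) -> float:
        return (span[0] + span[1]) / 2.0

    is_gypsy = rh_span is not None and center(int_span) > center(rh_span)
    is_copia = rt_span is not None and center(int_span) < center(rt_span)
    if is_gypsy and not is_copia:
        return GYPSY
    if is_copia and not is_gypsy:
        return COPIA
    if is_gypsy and is_copia:
        warnings.warn(f"{element.id}: contradictory domain order; superfamily unknown")
    return UNKNOWN


def _global_identity_pct(a: str, b: str) -> float:
    """Global (NW, unit-cost) alignment identity as 1 - dist/max(len)."""
    res = edlib.align(a, b, mode="NW", task="distance")
    return 100.0 * (1.0 - res["editDistance"] / max(len(a), len(b)))


def classify_family(
    element: AnnotatedElement,
    panel: list[ElementModel],
    min_identity: float = 60.0,
) -> tuple[str, float]:
    """Assign a family by global RT identity against the reference panel.

    Returns ``(family, identity_pct)``; family is ``unknown`` when the best
    identity falls below ``min_identity``. Ties break by panel order.
    """
    if not panel:
        raise ValueError("empty reference panel")
    rt = element.rt_seq
    if rt is None:
        if "RT" not in element.regions:
            raise ValueError(f"{element.id} has no RT span")
        raise ValueError(f"{element.id} has an RT span but no stored RT sequence")
    best_family, best_identity = UNKNOWN, -1.0
    for model in panel:
        ident = _global_identity_pct(rt, model.consensus["RT"])
        if ident > best_identity:
            best_family, best_identity = model.family, ident
    if best_identity < min_identity:
        return UNKNOWN, best_identity
    return best_family, best_identity


def _locate(consensus: str, target: str) -> tuple[Span, float] | None:
    """Best infix placement of a consensus inside a target sequence."""
    if not consensus or not target:
        return None
    res = edlib.align(consensus, target, mode="HW", task="locations")
    dist = res["editDistance"]
    if dist < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    return (start, end + 1), dist / len(consensus)


def fill_gap_regions(
    element: AnnotatedElement, named: dict[str, Span], has_chr: bool | None = None
) -> dict[str, Span]:
    """Complete a region tiling from LTRs plus located named features.

    Gaps between protein domains get hyphenated interdomain labels; the gap
    between pbs and the first domain is the 5UTR; the gap between the last
    domain and ppt is the 3UTR — labeled ``CHR-ppt`` for gypsy elements
    lacking a chromodomain, matching the gypsy region schema.
    """
    regions: dict[str, Span] = {}
    if element.ltr5 is None or element.ltr3 is None:
        raise ValueError("element lacks LTR spans")
    regions["LTR5"] = element.ltr5
    anchors = [("LTR5", element.ltr5)]
    order = [n for n in ("pbs", "GAG", "AP", "RT", "RH", "INT", "CHR", "ppt")
             if n in named]
    # sort by position; annotation should already be collinear
    order.sort(key=lambda n: named[n][0])
    for n in order:
        anchors.append((n, named[n]))
    anchors.append(("LTR3", element.ltr3))

    domains_present = [n for n, _ in anchors if n in DOMAIN_NAMES]
    gypsy_no_chr = (
        has_chr is False
        or (has_chr is None and "CHR" not in domains_present
            and classify_superfamily_from_order(domains_present) == GYPSY)
    )
    for (name_a, span_a), (name_b, span_b) in zip(anchors, anchors[1:]):
        if name_b != "LTR5":
            regions[name_b] = span_b
        gap = (span_a[1], span_b[0])
        if gap[1] <= gap[0]:
            continue
        if name_a == "pbs" or (name_a == "LTR5" and name_b in DOMAIN_NAMES):
            label = "5UTR"
        elif name_b == "ppt" or name_b == "LTR3":
            if name_a in DOMAIN_NAMES:
                label = "CHR-ppt" if gypsy_no_chr else "3UTR"
            else:
                continue  # ppt..LTR3 sliver: leave unlabeled
        elif name_a in DOMAIN_NAMES and name_b in DOMAIN_NAMES:
            label = f"{name_a}-{name_b}"
        elif name_a == "LTR5" and name_b == "pbs":
            continue
        else:
            label = f"{name_a}-{name_b}"
        regions[label] = gap
    regions["LTR3"] = element.ltr3
    return regions


def classify_superfamily_from_order(domains: list[str]) -> str:
    """Superfamily from an ordered 5'->3' domain name list."""
    if "INT" not in domains:
        return UNKNOWN
    i = domains.index("INT")
    after = domains[i + 1:]
    before = domains[:i]
    if "RH" in before and "RT" in before:
        return GYPSY
    if "RT" in after and "RH" in after:
        return COPIA
    return UNKNOWN


def rt_validator(panel: list[ElementModel], max_dist: float = _MAX_DOMAIN_DIST,
                 require_motifs: bool = True, motif_window: int = 60,
                 motif_dist: float = 0.4):
    """Build a detection-time structural validator for LTR-pair candidates.

    The returned callable (for :func:`retronest.detect.recursive_detect`)
    accepts a candidate only when (i) some panel family's RT consensus
    matches its inter-LTR region within ``max_dist`` normalized edit
    distance, and (ii) with ``require_motifs``, that family's pbs consensus
    occurs just 3' of the 5' LTR and its ppt just 5' of the 3' LTR. This
    rejects chimeric pairings of LTRs from different neighbouring elements
    and the body-vs-body "shadow" repeats created by same-family
    (auto)insertions, whose interiors may contain an RT but whose pseudo-LTR
    boundaries lack the pbs/ppt context; hosts whose RT is still split by an
    un-excised nested insertion are deferred to a later detection round.
    """
    models = list(panel)

    def validate(cand: CandidateElement) -> bool:
        internal = cand.seq[cand.ltr5_local[1]:cand.ltr3_local[0]]
        if not internal:
            return False
        best_model, best_rt = None, max_dist
        for model in models:
            rt = model.consensus["RT"]
            res = edlib.align(rt, internal, mode="HW", task="distance",
                              k=int(best_rt * len(rt)))
            dist = res["editDistance"]
            if dist >= 0 and dist / len(rt) <= best_rt:
                best_model, best_rt = model, dist / len(rt)
        if best_model is None:
            return False
        if not require_motifs:
            return True
        pbs = best_model.consensus["pbs"]
        ppt = best_model.consensus["ppt"]
        head = internal[:motif_window]
        tail = internal[-motif_window:]
        for motif, region in ((pbs, head), (ppt, tail)):
            res = edlib.align(motif, region, mode="HW", task="distance",
                              k=max(1, int(motif_dist * len(motif))))
            if res["editDistance"] < 0:
                return False
        return True

    return validate


def annotate_elements(
    candidates: list[CandidateElement],
    panel: list[ElementModel],
    genome: str | None = None,
    min_family_identity: float = 60.0,
) -> list[AnnotatedElement]:
    """Turn raw LTR-pair candidates into fully annotated elements.

    For each candidate, the best-matching panel family is found by infix RT
    search over the internal region; that family's domain (and pbs/ppt)
    consensi are then located to produce a complete region tiling in original
    genome coordinates. The formal family label comes from
    :func:`classify_family` (global RT identity with a threshold).
    """
    out: list[AnnotatedElement] = []
    for i, cand in enumerate(candidates):
        internal_lo = cand.ltr5_local[1]
        internal_hi = cand.ltr3_local[0]
        internal = cand.seq[internal_lo:internal_hi]
        best_model, best_dist = None, 1e9
        for model in panel:
            hit = _locate(model.consensus["RT"], internal)
            if hit and hit[1] < best_dist:
                best_model, best_dist = model, hit[1]
        el = AnnotatedElement(
            id=f"DET{i + 1:04d}",
            genome_id=cand.genome_id,
            start=cand.span[0],
            end=cand.span[1],
            ltr5=cand.ltr5_span,
            ltr3=cand.ltr3_span,
            ltr_identity_pct=cand.ltr_identity_pct,
            detection_round=cand.detection_round,
            seq=cand.seq,
            ltr5_seq=cand.seq[cand.ltr5_local[0]:cand.ltr5_local[1]],
            ltr3_seq=cand.seq[cand.ltr3_local[0]:cand.ltr3_local[1]],
        )
        if best_model is not None and best_dist <= _MAX_DOMAIN_DIST:
            named: dict[str, Span] = {}
            domain_names = [n for n, _, _ in best_model.layout
                            if n in DOMAIN_NAMES + ("pbs", "ppt")]
            for name in domain_names:
                hit = _locate(best_model.consensus[name], internal)
                if hit is None:
                    continue
                (s, e), dist = hit
                # short motifs (pbs/ppt) mutate fast; be lenient with them
                limit = 0.5 if name in ("pbs", "ppt") else _MAX_DOMAIN_DIST
                if dist > limit:
                    continue
                named[name] = (s + internal_lo, e + internal_lo)
            # enforce non-overlapping, ordered spans (infix placement of
            # padded consensi can bleed a few bases into the neighbour)
            ordered = sorted(named.items(), key=lambda kv: kv[1][0])
            trimmed: list[tuple[str, Span]] = []
            prev_end = 0
            for name, (s, e) in ordered:
                s = max(s, prev_end)
                if e <= s:
                    continue
                trimmed.append((name, (s, e)))
                prev_end = e
            named = dict(trimmed)
            if "RT" in named:
                rs, re = named["RT"]
                el.rt_seq = cand.seq[rs:re]
            named_orig = {n: cand.local_to_original(s) for n, s in named.items()}
            el.regions = fill_gap_regions(el, named_orig,
                                          has_chr=best_model.has_chr)
            el.superfamily = classify_superfamily(el)
            if el.rt_seq is not None:
                family, _ = classify_family(el, panel, min_family_identity)
                el.family = family
        if genome is not None:
            el.tsd = detect_tsd(genome, el)
        out.append(el)
    return out


@dataclass
class CurationResult:
    """Curated element and pair sets plus per-stage attrition counts."""

    pairs: list[NestedPair] = field(default_factory=list)
    pairs_motif: list[NestedPair] = field(default_factory=list)
    non_nested: list[AnnotatedElement] = field(default_factory=list)
    elements: list[AnnotatedElement] = field(default_factory=list)
    attrition: dict[str, int] = field(default_factory=dict)

    def element(self, element_id: str) -> AnnotatedElement:
        for el in self.elements:
            if el.id == element_id:
                return el
        raise KeyError(element_id)


def curate(
    elements: list[AnnotatedElement],
    genome: str,
    first_level_only: bool = False,
) -> CurationResult:
    """Run the quality-filter pipeline on annotated elements.

    Stages: RT-domain filter -> containment pair calling -> TSD filters
    (a pair is retained when its *original* element has an exact TSD; the
    stricter ``pairs_motif`` set additionally requires a TSD on the nested
    element, as motif analyses do) -> non-nested set restricted to elements
    with TSDs. Output is independent of the input ordering.
    """
    elements = sorted(elements, key=lambda e: (e.genome_id, e.start, e.end, e.id))
    attrition = {"input": len(elements)}

    with_rt = require_rt_domain(elements)
    attrition["rt_filter_removed"] = len(elements) - len(with_rt)

    for el in with_rt:
        if el.tsd is None:
            el.tsd = detect_tsd(genome, el)

    pairs_all = call_nested_pairs(with_rt, first_level_only=first_level_only)
    by_id = {el.id: el for el in with_rt}
    nested_ids = {p.nested_id for p in pairs_all}

    pairs = [p for p in pairs_all if by_id[p.original_id].tsd is not None]
    attrition["pairs_called"] = len(pairs_all)
    attrition["pairs_dropped_no_original_tsd"] = len(pairs_all) - len(pairs)
    pairs_motif = [p for p in pairs if by_id[p.nested_id].tsd is not None]
    attrition["pairs_motif"] = len(pairs_motif)

    # "non-nested" means solitary: neither nested into another element nor
    # hosting one
    original_ids = {p.original_id for p in pairs_all}
    non_nested_all = [el for el in with_rt
                      if el.id not in nested_ids and el.id not in original_ids
                      and el.parent_id is None]
    non_nested = [el for el in non_nested_all if el.tsd is not None]
    attrition["non_nested_called"] = len(non_nested_all)
    attrition["non_nested_dropped_no_tsd"] = len(non_nested_all) - len(non_nested)
    attrition["pairs_curated"] = len(pairs)
    attrition["non_nested_curated"] = len(non_nested)

    return CurationResult(
        pairs=pairs,
        pairs_motif=pairs_motif,
        non_nested=non_nested,
        elements=with_rt,
        attrition=attrition,
    )
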