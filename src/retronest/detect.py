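"""Structural detection of full-length LTR elements and nested-pair calling.

The detector looks for pairs of long direct repeats (the two LTRs) by exact
k-mer seeding on a fixed diagonal followed by ungapped X-drop extension, and
prefers candidates flanked by an exact 4-6 bp target site duplication. A
recursive detect-and-excise loop then recovers elements fragmented by
nesting: each round's candidates are cut out of the working genome (together
with one TSD copy, restoring the pre-insertion state), so that the host's
LTR pair becomes contiguous and discoverable in a later round. All reported
coordinates are mapped back to the original genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .models import AnnotatedElement, NestedPair, Span


@dataclass
class DetectionParams:
    """Tuning knobs of the structural detector."""

    min_ltr_len: int = 100
    min_ltr_identity: float = 80.0
    element_span_bounds: tuple[int, int] = (1_000, 25_000)
    tsd_lengths: tuple[int, ...] = (6, 5, 4)
    max_rounds: int = 6
    trusted_ltr_len: int = 400  # ranking (not rejection) threshold
    seed_k: int = 13
    max_seed_gap: int = 80
    xdrop: int = 25
    max_kmer_positions: int = 64  # skip hyper-repetitive seeds

    def __post_init__(self) -> None:
        if self.min_ltr_len <= 0:
            raise ValueError("min_ltr_len must be > 0")
        lo, hi = self.element_span_bounds
        if lo > hi:
            raise ValueError("element_span_bounds must be ordered")


@dataclass
class CandidateElement:
    """A detected LTR-pair candidate, in original genome coordinates.

    ``seq`` is the contiguous sequence of the candidate as seen in its
    detection round (i.e. with previously excised nested elements removed);
    ``orig_coords`` maps each base of ``seq`` to its original genome
    coordinate, which lets downstream annotation report sub-features of
    fragmented hosts in original space.
    """

    genome_id: str
    span: Span
    ltr5_span: Span
    ltr3_span: Span
    ltr_identity_pct: float
    tsd_candidate: str | None
    detection_round: int = 1
    seq: str = ""
    ltr5_local: Span = (0, 0)
    ltr3_local: Span = (0, 0)
    orig_coords: np.ndarray | None = field(default=None, repr=False)

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]

    def local_to_original(self, local: Span) -> Span:
        if self.orig_coords is None:
            off = self.span[0]
            return (local[0] + off, local[1] + off)
        return (int(self.orig_coords[local[0]]),
                int(self.orig_coords[local[1] - 1]) + 1)


class CoordinateMap:
    """Bijection between a (possibly excised) working genome and the original.

    ``orig_index[i]`` is the original coordinate of current base ``i``.
    """

    def __init__(self, length: int):
        self.orig_index = np.arange(length, dtype=np.int64)

    def remove(self, start: int, end: int) -> None:
        self.orig_index = np.concatenate(
            [self.orig_index[:start], self.orig_index[end:]]
        )

    def to_original(self, pos: int) -> int:
        return int(self.orig_index[pos])

    def to_current(self, orig_pos: int) -> int:
        """Current coordinate of a retained original base (raises if excised)."""
        i = int(np.searchsorted(self.orig_index, orig_pos))
        if i >= self.orig_index.size or self.orig_index[i] != orig_pos:
            raise KeyError(f"original position {orig_pos} was excised")
        return i


def _find_tsd(genome: str, left: int, right: int,
              lengths: tuple[int, ...]) -> str | None:
    for k in lengths:
        if left - k < 0 or right + k > len(genome):
            continue
        a = genome[left - k:left]
        if "N" not in a and a == genome[right:right + k]:
            return a
    return None


def _refine_by_tsd(
    genome: str, left: int, right: int, d: int, lengths: tuple[int, ...],
    max_shift: int = 14, edge: int = 12, edge_out: int = 6,
    max_cost: float = 12.0,
) -> tuple[int, int, str] | None:
    """Search small boundary shifts for an exact flanking TSD.

    Ungapped X-drop extension can overshoot or stop short of the true LTR
    boundaries by a few bases (chance matches / chance mismatches at the
    repeat edges). An exact target site duplication pins the true element
    boundaries. Candidate shift combinations with an exact TSD word are
    scored by how well the implied outermost LTR bases still agree on the
    repeat diagonal ``d`` — a boundary shifted into the flank drags random
    flank bases into the repeat and scores worse — breaking ties by smaller
    shift, then longer TSD.
    """
    n = len(genome)
    shifts = range(-max_shift, max_shift + 1)
    hits: list[tuple[float, int, int, int, str]] = []
    for dl in shifts:
        a = left + dl
        for dr in shifts:
            b = right + dr
            if b - a <= d:  # the two LTR copies must not overlap
                continue
            word = None
            for k in lengths:
                if a - k < 0 or b + k > n:
                    continue
                w = genome[a - k:a]
                if "N" not in w and w == genome[b:b + k]:
                    word = w
                    break
            if word is None:
                continue
            # boundary plausibility on the repeat diagonal d:
            #  - inside the boundary the two LTR copies must agree
            #    (mismatches penalize a boundary pushed into the flank);
            #  - just outside the boundary they must NOT keep agreeing
            #    (continued matches penalize a boundary stopped short of the
            #    true LTR end).
            cost = 0
            for i in range(edge):
                if a + d + i >= n or genome[a + i] != genome[a + d + i]:
                    cost += 1
                if b - d - 1 - i < 0 or genome[b - 1 - i] != genome[b - d - 1 - i]:
                    cost += 1
            for i in range(edge_out):
                if a - 1 - i >= 0 and a - 1 - i + d < n \
                        and genome[a - 1 - i] == genome[a - 1 - i + d]:
                    cost += 1
                if b + i < n and b + i - d >= 0 \
                        and genome[b + i] == genome[b + i - d]:
                    cost += 1
            hits.append((cost + 0.25 * (abs(dl) + abs(dr)),
                         abs(dl) + abs(dr), a, b, word))
    if not hits:
        return None
    best_cost = min(h[0] for h in hits)
    if best_cost > max_cost:
        # an exact word far from the extension boundary (or with ragged LTR
        # edges) is most likely a chance match, not a real TSD
        return None
    # the boundary-cost surface is noisy to ~2 units; within that window a
    # longer duplicated word is far less likely to be a chance match, so
    # prefer it (a 4-bp word is often a 5/6-bp TSD's truncation artifact)
    window = [h for h in hits if h[0] <= best_cost + 2.5]
    _, _, a, b, word = min(window, key=lambda h: (-len(h[4]), h[0], h[1], h[2]))
    return a, b, word


def find_intact_elements(
    genome: str, params: DetectionParams | None = None, genome_id: str = "genome",
    validator=None,
) -> list[CandidateElement]:
    """Find non-overlapping full-length LTR element candidates.

    Candidates are direct-repeat pairs >= ``min_ltr_len`` at
    >= ``min_ltr_identity`` percent identity whose outer span falls inside
    ``element_span_bounds``. When candidates overlap, TSD-supported ones win,
    then shorter spans (so intact nested elements beat their still-fragmented
    hosts within a detection round), then higher identity.
    """
    params = params or DetectionParams()
    n = len(genome)
    k = params.seed_k
    lo_span, hi_span = params.element_span_bounds
    if n < lo_span:
        return []

    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        kmer = genome[i:i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)

    max_d = hi_span - params.min_ltr_len
    min_d = params.min_ltr_len  # the two copies must not overlap
    diagonals: dict[int, list[int]] = {}
    for positions in index.values():
        m = len(positions)
        if m < 2 or m > params.max_kmer_positions:
            continue
        for ai in range(m - 1):
            a = positions[ai]
            for bi in range(ai + 1, m):
                d = positions[bi] - a
                if d > max_d:
                    break
                if d >= min_d:
                    diagonals.setdefault(d, []).append(a)

    raw: dict[tuple[int, int, int], CandidateElement] = {}
    for d, starts in diagonals.items():
        starts.sort()
        clusters: list[list[int]] = [[starts[0]]]
        for s in starts[1:]:
            if s - clusters[-1][-1] <= params.max_seed_gap + k:
                clusters[-1].append(s)
            else:
                clusters.append([s])
        for cl in clusters:
            left, right = _extend(genome, d, cl[0], cl[-1] + k, params)
            length = right - left
            if length < params.min_ltr_len or length > d:
                continue
            matches = sum(genome[i] == genome[i + d] for i in range(left, right))
            identity = 100.0 * matches / length
            if identity < params.min_ltr_identity:
                continue
            span = (left, left + d + length)
            if not (lo_span <= span[1] - span[0] <= hi_span):
                continue
            ltr5_span = (left, right)
            ltr3_span = (left + d, left + d + length)
            refined = _refine_by_tsd(genome, span[0], span[1], d,
                                     params.tsd_lengths)
            if refined is not None:
                a, b, tsd = refined
                ltr5_span = (a, max(ltr5_span[1], a + 1))
                ltr3_span = (min(ltr3_span[0], b - 1), b)
                span = (a, b)
                # re-measure identity over the refined 5' LTR extent
                lo, hi = ltr5_span
                matches = sum(genome[i] == genome[i + d]
                              for i in range(lo, min(hi, n - d)))
                width = min(hi, n - d) - lo
                if width > 0:
                    identity = 100.0 * matches / width
            else:
                tsd = None
            cand = CandidateElement(
                genome_id=genome_id,
                span=span,
                ltr5_span=ltr5_span,
                ltr3_span=ltr3_span,
                ltr_identity_pct=identity,
                tsd_candidate=tsd,
            )
            key = (span[0], span[1], d)
            prev = raw.get(key)
            if prev is None or identity > prev.ltr_identity_pct:
                raw[key] = cand

    # conflict resolution: TSD-supported candidates outrank TSD-less ones;
    # candidates whose repeat unit is much shorter than a credible LTR
    # (fragmentary same-family "shadow" repeats) are demoted; then higher
    # identity wins. The innermost element of a nest is the youngest, hence
    # the most identical pair, so identity ordering realizes innermost-first
    # excision and out-ranks cross-element LTR pairings, whose divergence
    # reflects a sum of two ages.
    ranked = sorted(
        raw.values(),
        key=lambda c: (c.tsd_candidate is None,
                       (c.ltr5_span[1] - c.ltr5_span[0]) < params.trusted_ltr_len,
                       c.length, -c.ltr_identity_pct, c.span[0]),
    )
    def trusted(c: CandidateElement) -> bool:
        return (c.tsd_candidate is not None
                and c.ltr5_span[1] - c.ltr5_span[0] >= params.trusted_ltr_len)

    trusted_cands = [c for c in ranked if trusted(c)]
    # overlapping full-LTR candidates of similar size cannot all be real (a
    # true host is at least one element longer than anything nested in it);
    # the extras pair LTRs across two elements, with a divergence reflecting
    # a sum of ages. Per overlap component, keep only the most identical
    # (= youngest) candidate this round; the others resolve in later rounds
    # once it has been excised.
    m = len(trusted_cands)
    comp = list(range(m))

    def find(x: int) -> int:
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for i in range(m):
        for j in range(i + 1, m):
            c1, c2 = trusted_cands[i], trusted_cands[j]
            if c1.span[0] >= c2.span[1] or c1.span[1] <= c2.span[0]:
                continue
            if min(c1.length, c2.length) / max(c1.length, c2.length) < 0.7:
                continue
            comp[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(m):
        groups.setdefault(find(i), []).append(i)
    dropped: set[int] = set()
    for members in groups.values():
        if len(members) < 2:
            continue
        best_id = max(trusted_cands[i].ltr_identity_pct for i in members)
        dropped.update(
            id(trusted_cands[i]) for i in members
            if trusted_cands[i].ltr_identity_pct < best_id - 0.3
        )
    if dropped:
        ranked = [c for c in ranked if id(c) not in dropped]
        trusted_cands = [c for c in trusted_cands if id(c) not in dropped]
    accepted: list[CandidateElement] = []
    for cand in ranked:
        s, e = cand.span
        if any(s < a.span[1] and e > a.span[0] for a in accepted):
            continue
        if not trusted(cand) and any(
            s < c.span[1] and e > c.span[0] and c.span != cand.span
            for c in trusted_cands
        ):
            # an untrusted candidate may not pre-empt ground claimed by a
            # TSD-supported full-LTR candidate, even one deferred to a later
            # round because it currently overlaps an accepted (nested) one
            continue
        cand.seq = genome[s:e]
        cand.ltr5_local = (cand.ltr5_span[0] - s, cand.ltr5_span[1] - s)
        cand.ltr3_local = (cand.ltr3_span[0] - s, cand.ltr3_span[1] - s)
        # optional structural validation (e.g. an RT-like interior) rejects
        # chimeric pairings of LTRs from different neighbouring elements;
        # rejected candidates are left in place for later rounds
        if validator is not None and not validator(cand):
            continue
        accepted.append(cand)
    accepted.sort(key=lambda c: c.span[0])
    return accepted


def _extend(genome: str, d: int, seed_left: int, seed_right: int,
            params: DetectionParams) -> tuple[int, int]:
    """Ungapped X-drop extension of a seed cluster on diagonal d (copy1 coords)."""
    n = len(genome)
    # right extension
    score = best = 0
    i = seed_right
    right = seed_right
    while i + d < n and i - seed_left < d:
        score += 1 if genome[i] == genome[i + d] else -2
        if score > best:
            best, right = score, i + 1
        if best - score > params.xdrop:
            break
        i += 1
    # left extension
    score = best = 0
    i = seed_left - 1
    left = seed_left
    while i >= 0 and right - i <= d:
        score += 1 if genome[i] == genome[i + d] else -2
        if score > best:
            best, left = score, i
        if best - score > params.xdrop:
            break
        i -= 1
    return _trim_edges(genome, d, left, right)


def _trim_edges(genome: str, d: int, left: int, right: int,
                window: int = 8, min_matches: int = 7) -> tuple[int, int]:
    """Trim extension ends to positions where the repeat is locally solid.

    X-drop extension creeps a few bases past the true repeat ends on chance
    matches. Require each boundary base to match its diagonal partner and to
    start a ``window``-column stretch with at least ``min_matches`` matches;
    chance flank sequence almost never satisfies this, while true LTR edges
    at moderate divergence almost always do.
    """
    def ok_left(i: int) -> bool:
        if genome[i] != genome[i + d]:
            return False
        w = min(window, right - i)
        m = sum(genome[i + j] == genome[i + d + j] for j in range(w))
        return m >= min(min_matches, w)

    def ok_right(i: int) -> bool:
        # i is the exclusive end; test the window ending at i
        if genome[i - 1] != genome[i - 1 + d]:
            return False
        w = min(window, i - left)
        m = sum(genome[i - 1 - j] == genome[i - 1 - j + d] for j in range(w))
        return m >= min(min_matches, w)

    while left < right and not ok_left(left):
        left += 1
    while right > left and not ok_right(right):
        right -= 1
    return left, right


def excise(genome: str, element: CandidateElement,
           coord_map: CoordinateMap | None = None) -> tuple[str, CoordinateMap]:
    """Remove an element (plus one TSD copy, if called) from the genome.

    Returns the shorter genome and a coordinate map from post-excision back
    to pre-excision coordinates (composed with ``coord_map`` if given, so the
    map always points at the original genome). When a TSD was called, the
    right-hand copy is removed with the element, restoring the single target
    word present before insertion.
    """
    s, e = element.span
    if coord_map is not None:
        # element.span is in original coordinates: convert to current
        s = coord_map.to_current(element.span[0])
        e = s + element.length
    if s < 0 or e > len(genome):
        raise ValueError("element span outside genome")
    k = len(element.tsd_candidate) if element.tsd_candidate else 0
    cut_end = min(e + k, len(genome))
    new_genome = genome[:s] + genome[cut_end:]
    if coord_map is None:
        coord_map = CoordinateMap(len(genome))
    coord_map.remove(s, cut_end)
    return new_genome, coord_map


def recursive_detect(
    genome: str, params: DetectionParams | None = None, genome_id: str = "genome",
    validator=None,
) -> list[CandidateElement]:
    """Iterate find -> excise until no new candidates (or ``max_rounds``).

    Candidates carry original-genome coordinates; a fragmented host found
    after its nested elements were excised is reported as its full
    pre-fragmentation span. Nesting levels are not assigned here — use
    :func:`call_nested_pairs` on the result.
    """
    params = params or DetectionParams()
    current = genome
    coord_map = CoordinateMap(len(genome))
    found: list[CandidateElement] = []
    rounds = 0
    while True:
        rounds += 1
        cands = find_intact_elements(current, params, genome_id=genome_id,
                                     validator=validator)
        if not cands:
            break
        for cand in cands:
            s, e = cand.span  # current coords
            cand.orig_coords = coord_map.orig_index[s:e].copy()
            cand.detection_round = rounds
        # excise right-to-left so earlier spans stay valid within the round
        for cand in sorted(cands, key=lambda c: -c.span[0]):
            s, e = cand.span
            k = len(cand.tsd_candidate) if cand.tsd_candidate else 0
            cut_end = min(e + k, len(current))
            current = current[:s] + current[cut_end:]
            coord_map.remove(s, cut_end)
        for cand in cands:
            cand.span = cand.local_to_original((0, cand.length))
            cand.ltr5_span = cand.local_to_original(cand.ltr5_local)
            cand.ltr3_span = cand.local_to_original(cand.ltr3_local)
        found.extend(cands)
        if rounds >= params.max_rounds:
            warnings.warn(
                f"recursive detection stopped at max_rounds={params.max_rounds} "
                "with candidates still being found; result may be partial"
            )
            break
    found.sort(key=lambda c: c.span[0])
    return found


def containment_forest(spans: list[Span]) -> tuple[list[int | None], list[int]]:
    """Immediate container and depth for each span.

    Returns ``(parent, level)`` where ``parent[i]`` is the index of the
    smallest span strictly containing span ``i`` (or None) and ``level[i]``
    is the containment depth (0 for top level). Identical spans are invalid.
    """
    n = len(spans)
    order = sorted(range(n), key=lambda i: (spans[i][0], -spans[i][1]))
    parent: list[int | None] = [None] * n
    level = [0] * n
    stack: list[int] = []
    seen: set[Span] = set()
    for i in order:
        s, e = spans[i]
        if (s, e) in seen:
            raise ValueError(f"identical spans {spans[i]} cannot be ordered")
        seen.add((s, e))
        while stack and spans[stack[-1]][1] <= s:
            stack.pop()
        if stack:
            ps, pe = spans[stack[-1]]
            if ps <= s and e <= pe:
                parent[i] = stack[-1]
                level[i] = level[stack[-1]] + 1
        stack.append(i)
    return parent, level


def call_nested_pairs(
    elements: list[AnnotatedElement], first_level_only: bool = False
) -> list[NestedPair]:
    """Pair each strictly contained element with its immediate host.

    Multi-level chains produce one pair per containment edge (B-in-A and
    C-in-B for A > B > C, never C-in-A). ``first_level_only=True`` instead
    drops pairs whose nested element is itself nested deeper than one level.
    Elements' ``nesting_level`` and ``parent_id`` are updated in place.
    """
    spans = [(el.start, el.end) for el in elements]
    parent, level = containment_forest(spans)
    pairs: list[NestedPair] = []
    for i, el in enumerate(elements):
        el.nesting_level = level[i]
        if parent[i] is None:
            el.parent_id = None
            continue
        host = elements[parent[i]]
        el.parent_id = host.id
        if first_level_only and level[i] > 1:
            continue
        pairs.append(
            NestedPair(
                nested_id=el.id,
                original_id=host.id,
                insertion_offset=el.start - host.start,
                same_family=None
                if "unknown" in (el.family, host.family)
                else el.family == host.family,
                nested_family=el.family,
                original_family=host.family,
                original_superfamily=host.superfamily,
            )
        )
    return pairs
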