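"""Approximate-palindrome detection at insertion sites and shuffle testing.

A palindrome is an inverted repeat: a left arm, a loop of any length
(possibly zero), and a right arm matching the reverse complement of the
left arm up to a bounded fraction of errors (mismatches plus indels). The
stem length is the left-arm length and serves as the score. Native windows
are compared against composition-preserving shuffles of themselves with a
paired t-test, Benjamini-Hochberg corrected across family groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import AnnotatedElement, Span
from .sequences import revcomp

#: labels treated as aggregates (tested, but excluded from the BH family set)
AGGREGATE_LABELS = ("ALL", "nested", "non-nested")


@dataclass
class PalindromeHit:
    sequence_id: str
    stem_length: int
    left_arm_span: Span
    right_arm_span: Span
    edit_count: int
    loop_length: int


def extract_site_window(genome: str, insertion_site: int, half: int = 10) -> str:
    """The ``2*half``-bp window centered on an insertion cut coordinate."""
    if insertion_site < half or insertion_site + half > len(genome):
        raise ValueError(f"site {insertion_site} within {half} bp of a contig edge")
    return genome[insertion_site - half:insertion_site + half]


def element_site_window(
    genome: str, element: AnnotatedElement, half: int = 10
) -> str | None:
    """Reconstruct the pre-insertion target window around an element's cut.

    The element plus one TSD copy are skipped, so the returned ``2*half``-bp
    sequence is the host sequence as it read before the insertion (TSD
    included once, just 3' of the cut). Returns None for elements without a
    TSD call or too close to a contig edge.
    """
    if element.tsd is None:
        return None
    k = element.tsd.length
    if k > half:
        return None
    s, e = element.start, element.end
    left_lo = s - k - half  # = cut - half in pre-insertion coordinates
    right_hi = e + half     # pre-insertion cut + half, past the right TSD copy
    if left_lo < 0 or right_hi > len(genome):
        return None
    left = genome[left_lo:s]       # half + k bases, ending with the TSD
    right = genome[e + k:e + half]  # the remaining half - k bases
    window = left + right
    if len(window) != 2 * half:
        return None
    return window


def max_approx_palindrome(
    seq: str, min_stem: int = 3, max_error_rate: float = 1.0 / 3.0,
    max_loop: int | None = None, sequence_id: str = "seq",
) -> PalindromeHit | None:
    """Maximum-stem approximate palindrome in a sequence.

    Finds the largest stem length s for which some configuration
    (left arm of length s, loop >= 0, right arm) aligns the right arm to the
    reverse complement of the left arm with at most ``floor(s *
    max_error_rate)`` errors. ``max_loop`` bounds the spacer between the
    arms (None = unconstrained within the sequence). Ties at the maximum s
    break by fewer edits, then leftmost arm. Returns None when no stem >=
    ``min_stem`` qualifies.
    """
    n = len(seq)
    if n < 2 * min_stem:
        return None
    seq = seq.upper()
    best: PalindromeHit | None = None
    for s in range(n - 1, min_stem - 1, -1):
        allowed = math.floor(s * max_error_rate)
        if s + max(1, s - allowed) > n:
            continue
        for a in range(0, n - s):
            b = a + s
            pattern = revcomp(seq[a:b])
            hit = None
            if max_loop is None:
                rest = seq[b:]
                if len(rest) < max(1, s - allowed):
                    break
                res = edlib.align(pattern, rest, mode="HW", task="locations")
                dist = res["editDistance"]
                if 0 <= dist <= allowed:
                    loc = res["locations"][0]
                    hit = (dist, b + loc[0], b + loc[1] + 1)
            else:
                # SHW pins the right-arm start, so the loop is exact
                for loop in range(0, max_loop + 1):
                    rest = seq[b + loop:]
                    if len(rest) < max(1, s - allowed):
                        break
                    res = edlib.align(pattern, rest, mode="SHW",
                                      task="locations")
                    dist = res["editDistance"]
                    if 0 <= dist <= allowed:
                        loc = res["locations"][0]
                        if hit is None or dist < hit[0]:
                            hit = (dist, b + loop, b + loop + loc[1] + 1)
            if hit is None:
                continue
            dist, arm_start, arm_end = hit
            candidate = PalindromeHit(
                sequence_id=sequence_id,
                stem_length=s,
                left_arm_span=(a, b),
                right_arm_span=(arm_start, arm_end),
                edit_count=dist,
                loop_length=arm_start - b,
            )
            if best is None or dist < best.edit_count:
                best = candidate
        if best is not None:
            return best
    return None


def shuffle_seq(seq: str, rng: np.random.Generator) -> str:
    """Uniform random permutation of the bases (multiset preserved)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return rng.permutation(arr).tobytes().decode("ascii")


def stem_score(seq: str, min_stem: int = 3,
               max_error_rate: float = 1.0 / 3.0,
               max_loop: int | None = None) -> int:
    """Stem length of the best palindrome, or ``min_stem - 1`` when none
    qualifies (keeps paired comparisons defined for empty sequences too)."""
    hit = max_approx_palindrome(seq, min_stem=min_stem,
                                max_error_rate=max_error_rate,
                                max_loop=max_loop)
    return hit.stem_length if hit else min_stem - 1


@dataclass
class PalindromeTestResult:
    group: str
    n: int
    mean_native: float
    mean_random: float
    paired_t_p: float
    p_adj: float | None = None
    zero_variance: bool = False


def paired_shuffle_test(
    groups: dict[str, list[str]],
    rng: np.random.Generator,
    min_stem: int = 3,
    max_error_rate: float = 1.0 / 3.0,
    max_loop: int | None = None,
    n_shuffles: int = 1,
    aggregate_labels: tuple[str, ...] = AGGREGATE_LABELS,
) -> list[PalindromeTestResult]:
    """Native-vs-shuffled stem length comparison per group.

    Each sequence is paired with the mean score of ``n_shuffles`` of itself
    (one shuffle by default, matching the paired design). Per-group paired
    t-tests are Benjamini-Hochberg corrected across the family groups;
    aggregate rows (``ALL``, ``nested``, ``non-nested``) keep their raw p.
    """
    results: list[PalindromeTestResult] = []
    for label, seqs in groups.items():
        if len(seqs) < 2:
            raise ValueError(f"group {label!r} needs n >= 2")
        native = np.array(
            [stem_score(s, min_stem, max_error_rate, max_loop) for s in seqs],
            dtype=float,
        )
        random_scores = np.zeros(len(seqs))
        for i, s in enumerate(seqs):
            vals = [
                stem_score(shuffle_seq(s, rng), min_stem, max_error_rate,
                           max_loop)
                for _ in range(n_shuffles)
            ]
            random_scores[i] = float(np.mean(vals))
        diffs = native - random_scores
        zero_var = bool(np.all(diffs == diffs[0]))
        if zero_var and diffs[0] == 0:
            p = 1.0
        else:
            p = float(stats.ttest_rel(native, random_scores).pvalue)
            if math.isnan(p):
                p = 1.0
                zero_var = True
        results.append(
            PalindromeTestResult(
                group=label, n=len(seqs),
                mean_native=float(native.mean()),
                mean_random=float(random_scores.mean()),
                paired_t_p=p, zero_variance=zero_var,
            )
        )
    family_rows = [r for r in results if r.group not in aggregate_labels]
    if family_rows:
        _, p_adj, _, _ = multipletests(
            [r.paired_t_p for r in family_rows], method="fdr_bh"
        )
        for r, q in zip(family_rows, p_adj):
            r.p_adj = float(q)
    for r in results:
        if r.group in aggregate_labels:
            r.p_adj = r.paired_t_p
    return results
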