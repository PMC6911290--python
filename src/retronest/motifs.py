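"""TSD and flanking-sequence motif analysis.

Builds position frequency matrices and information-content profiles (logo
data) over windows assembled from the last bases of the left flank, the TSD
stripe, and the first bases of the right flank; tabulates TSD-length
proportions per family; and compares element GC content with the genome
background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import AnnotatedElement, TsdRecord
from .sequences import gc_fraction, revcomp

logger = logging.getLogger(__name__)

_ALPHABET = "ACGT"


def extract_flanks(
    genome: str, element: AnnotatedElement, w: int = 50
) -> tuple[str, str, bool]:
    """The w bases on each side of an element, outside its TSD copies.

    Requires a TSD call (the duplication length determines where the flank
    starts). Returns ``(left, right, truncated)``; flanks shorter than w at
    contig edges are returned as-is with ``truncated=True``.
    """
    if element.tsd is None:
        raise ValueError(f"{element.id} has no TSD call")
    k = element.tsd.length
    left_end = element.start - k
    right_start = element.end + k
    left = genome[max(0, left_end - w):left_end]
    right = genome[right_start:right_start + w]
    truncated = len(left) < w or len(right) < w
    if element.strand == "-":
        left, right = revcomp(right), revcomp(left)
    return left, right, truncated


def tsd_window(record: TsdRecord, flank: int = 10, strand: str = "+") -> str | None:
    """Aligned logo window: last ``flank`` left-flank bases + TSD + first
    ``flank`` right-flank bases, in element-insertion orientation."""
    left = record.left_flank[-flank:]
    right = record.right_flank[:flank]
    if len(left) < flank or len(right) < flank:
        return None
    window = left + record.seq + right
    if strand == "-":
        window = revcomp(window)
    return window


@dataclass
class PositionFrequencyMatrix:
    """Per-column base counts and information content for one window shape."""

    tsd_length: int
    flank: int
    counts: pd.DataFrame       # index position, columns A C G T
    information: np.ndarray    # bits per column, in [0, 2]
    n_sequences: int

    @property
    def tsd_columns(self) -> slice:
        return slice(self.flank, self.flank + self.tsd_length)


def build_pfm(windows: list[str], tsd_length: int, flank: int = 10,
              small_sample_correction: bool = False) -> PositionFrequencyMatrix:
    """Counts + information content over aligned equal-length windows.

    IC_j = 2 + sum_b p_jb log2 p_jb (uniform background); Ns are excluded
    per column. The optional small-sample correction subtracts the standard
    ``3 / (2 ln2 n_j)`` bias term.
    """
    if not windows:
        raise ValueError("no windows")
    width = 2 * flank + tsd_length
    if any(len(w) != width for w in windows):
        raise ValueError(f"all windows must have length {width}")
    counts = np.zeros((width, 4), dtype=np.int64)
    for w in windows:
        for j, base in enumerate(w.upper()):
            i = _ALPHABET.find(base)
            if i >= 0:
                counts[j, i] += 1
    n_col = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / n_col[:, None]
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    if small_sample_correction:
        ic = ic - 3.0 / (2.0 * np.log(2) * np.maximum(n_col, 1))
    ic = np.clip(ic, 0.0, 2.0)
    frame = pd.DataFrame(counts, columns=list(_ALPHABET),
                         index=pd.RangeIndex(width, name="position"))
    return PositionFrequencyMatrix(
        tsd_length=tsd_length, flank=flank, counts=frame,
        information=ic, n_sequences=len(windows),
    )


def build_logo_data(
    records: list[TsdRecord], flank: int = 10, strands: dict[str, str] | None = None
) -> dict[int, PositionFrequencyMatrix]:
    """One PFM per TSD length k in {4, 5, 6}, from records grouped by k."""
    by_k: dict[int, list[str]] = {}
    strands = strands or {}
    for rec in records:
        window = tsd_window(rec, flank=flank,
                            strand=strands.get(rec.element_id, "+"))
        if window is None:
            logger.info("record %s truncated; skipped from logo", rec.element_id)
            continue
        by_k.setdefault(rec.length, []).append(window)
    out = {}
    for k in sorted(by_k):
        if not by_k[k]:
            continue
        out[k] = build_pfm(by_k[k], tsd_length=k, flank=flank)
    return out


def tsd_length_distribution(
    records: list[TsdRecord], families: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TSD-length spectra by family.

    Returns ``(per_family, per_k)``: row-normalized proportions of each k
    within a family, and column-normalized contributions of each family to a
    given k.
    """
    rows = [(families.get(r.element_id, "unknown"), r.length) for r in records]
    if not rows:
        empty = pd.DataFrame()
        return empty, empty
    df = pd.DataFrame(rows, columns=["family", "k"])
    counts = pd.crosstab(df["family"], df["k"])
    per_family = counts.div(counts.sum(axis=1), axis=0)
    per_k = counts.div(counts.sum(axis=0), axis=1)
    return per_family, per_k


def gc_content(seqs: list[str] | str) -> float:
    """GC fraction over one or many sequences (Ns excluded)."""
    if isinstance(seqs, str):
        seqs = [seqs]
    if not seqs:
        raise ValueError("no sequences")
    return gc_fraction("".join(seqs))


def gc_compare(element_seqs: list[str], genome: str) -> dict[str, float]:
    """Element-set GC minus whole-genome GC, in percentage points."""
    te = gc_content(element_seqs)
    bg = gc_content(genome)
    return {
        "elements_gc": te,
        "genome_gc": bg,
        "difference_points": 100.0 * (te - bg),
    }
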