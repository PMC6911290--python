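"""Nucleosome occupancy prediction from dinucleotide periodicity.

A 147-bp nucleosome footprint bends DNA most easily when flexible WW
(AA/AT/TA/TT) dinucleotides recur in phase with the ~10-bp helical repeat
and rigid SS (CC/CG/GC/GG) dinucleotides sit out of phase. The model scores
every possible footprint start ``i`` with an energy

    E(i) = sum_j w(seq[i+j..i+j+1], j),   w = +-A cos(2 pi j / P)

(+ for WW, - for SS, 0 otherwise, j = 0..F-2), converts the energies to
start probabilities by a Boltzmann softmax, and defines occupancy at a base
as the probability that any footprint covers it. It is an explicit,
self-contained positioning model whose parameters are printed here rather
than trained; the scorer is isolated behind ``occupancy_landscape`` so an
alternative can be plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import AnnotatedElement

_WW = {"AA", "AT", "TA", "TT"}
_SS = {"CC", "CG", "GC", "GG"}


@dataclass
class NucleosomeModelParams:
    footprint: int = 147
    period: float = 10.1
    amplitude: float = 0.2

    def __post_init__(self) -> None:
        if self.footprint <= 1:
            raise ValueError("footprint must be > 1")
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass
class OccupancyProfile:
    """Mean occupancy per relative position around aligned sites."""

    positions: np.ndarray
    mean_occupancy: np.ndarray
    n_sequences: int
    shuffled_control: bool = False


def _dinucleotide_classes(seq: str) -> np.ndarray:
    """+1 for WW, -1 for SS, 0 otherwise (incl. N), per dinucleotide start."""
    s = seq.upper()
    out = np.zeros(max(len(s) - 1, 0), dtype=np.float64)
    for i in range(len(s) - 1):
        di = s[i:i + 2]
        if di in _WW:
            out[i] = 1.0
        elif di in _SS:
            out[i] = -1.0
    return out


def start_probabilities(seq: str, params: NucleosomeModelParams | None = None) -> np.ndarray:
    """Boltzmann probability of a footprint starting at each position."""
    params = params or NucleosomeModelParams()
    F = params.footprint
    if len(seq) < F:
        raise ValueError(f"sequence shorter than footprint ({len(seq)} < {F})")
    cls = _dinucleotide_classes(seq)
    j = np.arange(F - 1)
    w = params.amplitude * np.cos(2.0 * np.pi * j / params.period)
    # E(i) = sum_j cls[i + j] * w[j]: a sliding correlation of cls with w
    energies = np.correlate(cls, w, mode="valid")[: len(seq) - F + 1]
    energies = energies - energies.max()
    p = np.exp(energies)
    return p / p.sum()


def occupancy_landscape(seq: str, params: NucleosomeModelParams | None = None,
                        start_probability: bool = False) -> np.ndarray:
    """Per-base occupancy O(x) = sum of start probabilities covering x.

    With ``start_probability=True`` the raw footprint-start probabilities are
    returned instead (padded with zeros over the last F-1 bases).
    """
    params = params or NucleosomeModelParams()
    p = start_probabilities(seq, params)
    if start_probability:
        return np.concatenate([p, np.zeros(params.footprint - 1)])
    window = np.ones(params.footprint)
    return np.convolve(p, window, mode="full")[: len(seq)]


def average_profile(
    windows: list[str],
    params: NucleosomeModelParams | None = None,
    shuffled_control: bool = False,
    rng: np.random.Generator | None = None,
) -> OccupancyProfile:
    """Positionwise mean occupancy over equal-length windows aligned on the
    insertion cut (assumed at the window midpoint).

    With ``shuffled_control=True`` each window is base-shuffled first, which
    preserves composition but destroys periodic placement.
    """
    if not windows:
        raise ValueError("no usable windows")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("windows must share one length")
    if shuffled_control:
        from .palindromes import shuffle_seq
        rng = np.random.default_rng(rng)
        windows = [shuffle_seq(w, rng) for w in windows]
    acc = np.zeros(width)
    for w in windows:
        acc += occupancy_landscape(w, params)
    half = width // 2
    return OccupancyProfile(
        positions=np.arange(-half, width - half),
        mean_occupancy=acc / len(windows),
        n_sequences=len(windows),
        shuffled_control=shuffled_control,
    )


def site_windows(genome: str, sites: list[int], window: int = 1124) -> list[str]:
    """Contiguous genome windows centered on site coordinates; sites within
    ``window/2`` of a contig edge are dropped."""
    half = window // 2
    out = []
    for site in sites:
        if site - half < 0 or site + (window - half) > len(genome):
            continue
        out.append(genome[site - half:site + (window - half)])
    return out


def element_site_windows(
    genome: str, elements: list[AnnotatedElement], window: int = 1124
) -> list[str]:
    """Pre-insertion target windows around each element's cut (the element
    and one TSD copy are excised, so the window reads as the host did before
    the insertion). Elements without a TSD call or near an edge are dropped."""
    from .palindromes import element_site_window
    half = window // 2
    out = []
    for el in elements:
        w = element_site_window(genome, el, half=half)
        if w is not None and len(w) == window:
            out.append(w)
    return out


def element_body_profile(
    elements: list[AnnotatedElement],
    params: NucleosomeModelParams | None = None,
    n_bins: int = 1000,
) -> OccupancyProfile:
    """Occupancy over normalized element coordinates (fixed bin count).

    Each element's landscape — computed on its contiguous sequence — is
    linearly rescaled to ``n_bins`` positions and averaged.
    """
    params = params or NucleosomeModelParams()
    usable = [el for el in elements
              if el.seq is not None and len(el.seq) >= params.footprint]
    if not usable:
        raise ValueError("no elements with usable sequence")
    acc = np.zeros(n_bins)
    grid = np.linspace(0.0, 1.0, n_bins)
    for el in usable:
        land = occupancy_landscape(el.seq, params)
        x = np.linspace(0.0, 1.0, land.size)
        acc += np.interp(grid, x, land)
    return OccupancyProfile(
        positions=np.arange(n_bins),
        mean_occupancy=acc / len(usable),
        n_sequences=len(usable),
    )
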