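"""Low-level DNA helpers shared across the package.

Sequences are plain upper-case Python strings over ``ACGTN``; numpy is used
internally where per-base vector operations pay off (random genome synthesis,
substitution mutagenesis).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# uint8 byte value -> base index 0..3, 255 for anything else (incl. N)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(n: int, gc: float = 0.5, rng: np.random.Generator | None = None) -> str:
    """i.i.d. random DNA of length ``n`` with the given GC fraction."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc fraction must be in [0,1], got {gc}")
    rng = np.random.default_rng(rng)
    p = [(1.0 - gc) / 2.0, gc / 2.0, gc / 2.0, (1.0 - gc) / 2.0]
    return rng.choice(_BASE_BYTES, size=n, p=p).tobytes().decode("ascii")


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions at per-site probability ``rate``.

    Each hit site is replaced by one of the three other bases uniformly;
    N positions are left untouched. No indels are introduced, so coordinates
    within the sequence are preserved exactly.
    """
    if rate < 0:
        raise ValueError(f"substitution rate must be >= 0, got {rate}")
    if rate == 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    codes = _CODE[arr]
    hit = (rng.random(arr.size) < rate) & (codes != 255)
    n_hit = int(hit.sum())
    if n_hit == 0:
        return seq
    shift = rng.integers(1, 4, size=n_hit).astype(np.uint8)
    codes_hit = (codes[hit] + shift) % 4
    arr[hit] = _DECODE[codes_hit]
    return arr.tobytes().decode("ascii")


def gc_fraction(seq: str) -> float:
    """GC over A+C+G+T (Ns excluded). Raises on sequences with no ACGT base."""
    at = seq.count("A") + seq.count("T") + seq.count("a") + seq.count("t")
    gc = seq.count("G") + seq.count("C") + seq.count("g") + seq.count("c")
    if at + gc == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / (at + gc)


def hamming_identity_pct(a: str, b: str) -> float:
    """Percent identity of two equal-length, gap-free sequences."""
    if len(a) != len(b):
        raise ValueError("hamming identity requires equal lengths")
    if not a:
        raise ValueError("empty sequences")
    matches = sum(x == y for x, y in zip(a, b))
    return 100.0 * matches / len(a)
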