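"""Domain types shared by the simulator and the analysis stages.

Coordinates are 0-based half-open throughout the package; GFF3 input/output
converts to and from the 1-based inclusive convention at the boundary
(:mod:`retronest.io`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

Span = tuple[int, int]

GYPSY = "gypsy"
COPIA = "copia"
UNKNOWN = "unknown"

#: protein domain vocabulary, in no particular order
DOMAIN_NAMES = ("GAG", "AP", "RT", "RH", "INT", "CHR")

#: superfamily-specific POL domain order (integrase after RH in gypsy,
#: before RT in copia)
DOMAIN_ORDER = {
    GYPSY: ("GAG", "AP", "RT", "RH", "INT"),
    COPIA: ("GAG", "AP", "INT", "RT", "RH"),
}


@dataclass
class TsdRecord:
    """An exact target site duplication call plus its 50-bp flanks."""

    element_id: str
    length: int
    seq: str
    left_flank: str = ""
    right_flank: str = ""
    edge: bool = False  # truncated at a contig edge

    def __post_init__(self) -> None:
        if len(self.seq) != self.length:
            raise ValueError("TSD sequence length disagrees with k")


@dataclass
class AnnotatedElement:
    """One LTR retrotransposon occurrence with structural sub-annotations.

    ``regions`` is a complete tiling of ``[start, end)`` in genome
    coordinates: LTRs, protein domains, pbs/ppt, UTRs and hyphenated
    interdomain spacers. For elements fragmented by nesting, the genome-
    coordinate spans are *expanded* (they include the nested insertions),
    while ``seq``/``ltr5_seq``/``ltr3_seq`` hold the contiguous element
    sequence with nested copies excised.
    """

    id: str
    genome_id: str
    start: int
    end: int
    strand: str = "+"
    ltr5: Span | None = None
    ltr3: Span | None = None
    regions: dict[str, Span] = field(default_factory=dict)
    family: str = UNKNOWN
    superfamily: str = UNKNOWN
    tsd: TsdRecord | None = None
    nesting_level: int = 0
    parent_id: str | None = None
    age_mya: float | None = None
    ltr_identity_pct: float | None = None
    detection_round: int | None = None
    seq: str | None = None
    ltr5_seq: str | None = None
    ltr3_seq: str | None = None
    rt_seq: str | None = None

    @property
    def span(self) -> Span:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "AnnotatedElement") -> bool:
        """Strict containment of the other element's span in ours."""
        return (
            self.start <= other.start
            and other.end <= self.end
            and (self.start, self.end) != (other.start, other.end)
        )


@dataclass
class NestedPair:
    """A nested element paired with its immediate (smallest containing) host."""

    nested_id: str
    original_id: str
    insertion_offset: int  # bp from the original element start
    region_label: str | None = None
    identity_delta: float | None = None  # nested minus original LTR identity, points
    same_family: bool | None = None
    nested_family: str = UNKNOWN
    original_family: str = UNKNOWN
    original_superfamily: str = UNKNOWN


@dataclass
class ElementModel:
    """Family template: region layout, consensus sequences, TSD length bias.

    ``layout`` is an ordered list of ``(region_name, mean_length_bp, sd_bp)``
    covering LTR5, pbs, 5UTR, the protein domains in superfamily order with
    interdomain spacers, the 3' noncoding region, ppt and LTR3. ``consensus``
    maps each region name to a DNA sequence at least as long as any realized
    region length; LTR5 and LTR3 share one consensus.
    """

    family: str
    superfamily: str
    layout: list[tuple[str, int, int]]
    consensus: dict[str, str]
    tsd_length_probs: dict[int, float]
    has_chr: bool = False
    gc: float = 0.44

    def __post_init__(self) -> None:
        if self.superfamily not in (GYPSY, COPIA):
            raise ValueError(f"unknown superfamily {self.superfamily!r}")
        total = sum(self.tsd_length_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("tsd_length_probs must sum to 1")
        if any(k not in (4, 5, 6) for k in self.tsd_length_probs):
            raise ValueError("TSD lengths must be 4, 5 or 6")
        if any(mean <= 0 for _, mean, _ in self.layout):
            raise ValueError("region mean lengths must be > 0")
        order = [n for n, _, _ in self.layout if n in DOMAIN_NAMES]
        expected = [d for d in DOMAIN_ORDER[self.superfamily] if d in order]
        if self.has_chr and self.superfamily == GYPSY:
            expected = [d for d in ("GAG", "AP", "RT", "RH", "INT", "CHR") if d in order]
        if order != expected:
            raise ValueError(
                f"{self.family}: domain order {order} violates {self.superfamily} layout"
            )

    @property
    def region_names(self) -> list[str]:
        return [name for name, _, _ in self.layout]

    @property
    def mean_length(self) -> int:
        return sum(mean for _, mean, _ in self.layout)


@dataclass
class SimConfig:
    """Synthetic genome configuration; defaults are the study conditions.

    ``region_preference_weights`` gives the per-region probability mass used
    when a nested insertion chooses where to land inside its host (weights are
    not length-scaled: a weight proportional to region length reproduces the
    uniform-per-bp null). The key ``"*"`` is the fallback for regions not
    listed explicitly.
    """

    genome_length_bp: int = 500_000
    gc_fraction: float = 0.38
    n_elements: int = 60
    nesting_fraction: float = 0.3
    region_preference_weights: dict[str, float] = field(
        default_factory=lambda: {
            "3UTR": 4.0,
            "CHR-ppt": 4.0,
            "RT-RH": 3.0,
            "GAG-AP": 2.0,
            "5UTR": 2.0,
            "LTR5": 0.3,
            "LTR3": 0.3,
            "INT": 0.3,
            "*": 1.0,
        }
    )
    autoinsertion_bias: dict[str, float] = field(default_factory=dict)
    palindrome_bias: float = 0.0
    periodicity_bias: float = 0.0
    tsd_motif_bias: float = 1.0
    age_range_mya: tuple[float, float] = (0.0, 4.0)
    mutation_rate_mu: float = 1.3e-8
    element_gc: float = 0.44
    max_nesting_depth: int = 3
    panel_seed: int = 1729
    rng_seed: int = 0

    def validate(self) -> None:
        if self.genome_length_bp <= 0:
            raise ValueError("genome_length_bp must be positive")
        if self.n_elements < 0:
            raise ValueError("n_elements must be >= 0")
        for name in ("gc_fraction", "nesting_fraction", "palindrome_bias",
                     "periodicity_bias", "tsd_motif_bias", "element_gc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for fam, v in self.autoinsertion_bias.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"autoinsertion_bias[{fam}] must be in [0,1]")
        w = self.region_preference_weights
        if any(x < 0 for x in w.values()):
            raise ValueError("region preference weights must be >= 0")
        if not any(x > 0 for x in w.values()):
            raise ValueError("at least one region preference weight must be > 0")
        lo, hi = self.age_range_mya
        if lo < 0 or hi < lo:
            raise ValueError("age_range_mya must be 0 <= lo <= hi")
        if self.mutation_rate_mu <= 0:
            raise ValueError("mutation_rate_mu must be > 0")
        if self.max_nesting_depth < 1:
            raise ValueError("max_nesting_depth must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range_mya"] = list(self.age_range_mya)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        d = dict(d)
        if "age_range_mya" in d:
            d["age_range_mya"] = tuple(d["age_range_mya"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class GroundTruth:
    """Planted truth for every downstream stage of the pipeline."""

    genome_id: str
    elements: list[AnnotatedElement]
    pairs: list[NestedPair]
    base_genome: str  # pre-insertion genome (after site rewrites, before inserts)

    @property
    def insertion_sites(self) -> list[int]:
        """Element start coordinates (the integration cut) in the final genome."""
        return [el.start for el in self.elements]

    def element(self, element_id: str) -> AnnotatedElement:
        for el in self.elements:
            if el.id == element_id:
                return el
        raise KeyError(element_id)
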