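# Methods

This note documents the models and numerical choices behind `retronest`:
what the synthetic-data generator emulates, how each analysis stage works,
which parameters matter, and where the design was genuinely open.

## Synthetic genomes

**Background sequence.** The host genome is i.i.d. DNA with configurable GC
(default 0.38, a typical plant value). No genes, centromeres or chromatin
are simulated.

**Family panel.** Eighteen element families — nine Ty3/gypsy (Athila, CRM,
Galadriel, Ogre, Phygy, Reina, Retand, Tcn1, Tekay) and nine Ty1/copia
(Ale, Angela, Bryco, Bianca, Ikeros, Ivana, SIRE, TAR, Tork) — are built
procedurally from a fixed seed (`PANEL_SEED = 1729`), so the reference
panel used for classification is reproducible without any bundled data
file. Each family is a region layout (LTR5, pbs, 5'UTR, protein domains
with interdomain spacers, 3' noncoding region, ppt, LTR3) with mean
lengths and SDs, plus an i.i.d. consensus sequence per region at GC 0.44
(elements run a few points GC-richer than plant genome background).
Integrase follows RH in gypsy layouts and precedes RT in copia layouts.
Four gypsy families (Tekay, CRM, Tcn1, Phygy) carry a chromodomain; in the
other gypsy families the 3' noncoding region occupies the slot between INT
and ppt and is labeled `CHR-ppt` in the gypsy region schema. Element
length is ~7.5–9 kb; LTRs average 900 bp. Pairwise RT identities between
panel families are ~50%, far below the 60% classification threshold, which
a build-time test verifies.

**Element synthesis and the molecular clock.** Both LTRs start from one
realized LTR sequence; the whole element then accumulates substitutions at
per-site probability `q = μ · age · 10⁶` (μ default 1.3×10⁻⁸
substitutions/site/year, a common grass calibration; configurable). The
expected pairwise LTR divergence is `2q(1−q) + (2/3)q²` ≈ `2q` for the
ages simulated, which is what the dating stage inverts. **No indels are
introduced anywhere**, so every planted sub-span stays exact — the point
of the generator is to give the detector a ground truth with zero
coordinate ambiguity.

**Insertion process.** Elements are inserted oldest first. Each insertion
cuts the genome, duplicates a sampled 4/5/6-bp target word on both sides
of the element, and shifts/expands all previously planted annotations, so
ground truth is kept in final-genome coordinates. A nested insertion picks
its host uniformly among already-placed (hence older) elements — optionally
biased toward its own family (`autoinsertion_bias`) — then picks a region
of the host with probability proportional to `region_preference_weights`
(not length-scaled: weights proportional to region length reproduce the
uniform-per-bp null), and a uniform position inside that region. Default
weights encode the observed hotspot pattern (3'UTR 4, RT–RH 3, GAG–AP 2,
5'UTR 2, LTRs and INT 0.3, others 1). Cut sites keep ≥10 bp clearance from
every element boundary so a TSD is never split; TSD length probabilities
default to {5: 0.87, 4: 0.11, 6: 0.02}, with Galadriel, Phygy and Bryco
flipped to a 4-bp-dominant spectrum.

**Site biases.** Before each insertion the target site may be rewritten:
with `tsd_motif_bias` (default 1.0) the TSD word is drawn from a
position-specific composition model (AT-rich core for 5/6-bp TSDs, GC-rich
core for 4-bp, T depleted 5' and A depleted 3' of the core); with
`palindrome_bias` the reverse complement of the 5 bp left of the cut is
written right of the target word, planting an inverted repeat with the TSD
as its loop; with `periodicity_bias` WW dinucleotides are written every
10 bp across 147 bp centered on the cut. Rewrites never touch other
elements. Because rewrites precede insertion, the excision-reconstruction
invariant (removing every element plus one TSD copy restores the
pre-insertion genome byte-for-byte) holds exactly when all rewrite biases
are zero; with biases on, the rewritten target bases remain, as they
biologically should.

**What the generator does not emulate** — indels and truncation, solo-LTR
recombination, post-insertion flank mutation (planted TSDs stay exact,
which is why the curation TSD filter retains everything on clean
simulations), nested-age/host-age correlation structure, strand (all
elements are planted on the plus strand; minus-strand handling in the
motif code is unit-tested directly). Passing tests therefore demonstrate
correctness of the bookkeeping and statistics, and detector performance
under substitution-only divergence; they do not certify recall on real
assemblies, where indels and truncated elements dominate the error budget.

## Structural detection

Candidate LTR pairs come from exact 13-mer seeds shared by two positions
at a plausible separation, grouped by diagonal, extended ungapped with an
X-drop rule (+1 match / −2 mismatch, drop 25), and trimmed so that each
repeat end both matches its diagonal partner and starts a locally solid
(≥7 of 8 matching) stretch. Ungapped extension is sufficient because the
mutation model is substitution-only; a gapped extender would be needed for
real data.

**TSD-guided boundary refinement.** Extension ends can wander a few bases
off the true element boundary (chance matches into the flank, chance
mismatch clusters at old LTR edges). Since integrase leaves an exact
duplication, the detector scans boundary shifts up to ±14 bp for an exact
4–6-bp flanking word and scores each hit by diagonal plausibility: inside
the proposed boundary the two LTR copies should agree, just outside they
should not. Among hits within a small cost window, longer words win (a
4-bp word is often the truncation artifact of a 5/6-bp TSD).

**Conflict resolution.** Overlapping candidates are resolved greedily:
TSD-supported candidates first, candidates whose repeat unit is shorter
than a credible LTR (<400 bp by default; a ranking, not a rejection
threshold) demoted, then shorter spans first — the innermost element of a
nest is the smallest, so this realizes innermost-first excision. Two
safeguards handle the hard case of same-family nesting, where the body of
a young copy is a near-perfect repeat of its host's body and spawns
chimeric candidates: (i) an untrusted candidate may not pre-empt ground
claimed by a TSD-supported full-LTR candidate even when the latter is
deferred to a later round; (ii) among overlapping full-LTR candidates of
similar span (ratio > 0.7), those clearly less identical than the best of
their overlap component (by >0.3 points) are dropped for the round — a
cross-element pairing's divergence reflects a *sum* of two ages and can
never beat the youngest true element it overlaps.

**Structural validation.** The pipeline passes `rt_validator(panel)` to
the detector: a candidate is excised only if some panel family's RT
consensus matches its inter-LTR region (normalized edit distance ≤ 0.35)
and that family's pbs/ppt motifs occur in the expected positions just
inside the LTRs. This rejects chimeras whose "interior" is intergenic or
lacks LTR context, and automatically defers hosts whose RT is still split
by an un-excised nested copy. Pure-library users can run the detector
without a validator.

**Recursion.** Detect → excise (element plus one TSD copy, restoring the
pre-insertion state) → repeat until a round finds nothing or `max_rounds`
(default 6) is hit, with every reported coordinate mapped back to the
original genome through an explicit coordinate map; fragmented hosts are
reported as their full pre-fragmentation span. On the generator's
substitution-only genomes with LTR identity ≥95% and up to three nesting
levels, aggregate recovery with span error ≤2 bp is ~96–97% across seeds;
the residual losses are deep same-family nests and occasional boundary
calls 3–7 bp off where a chance duplication mimics a shifted TSD.

**Nested pairs.** An element strictly contained in another pairs with its
immediate (smallest containing) host; chains produce one pair per
containment edge. A `first_level_only` flag instead drops pairs whose
nested element sits deeper than one level, covering the alternative
reading of "first level/floor" counting.

## Curation and classification

Filters run in order: RT-domain requirement → containment pair calling →
TSD filters. A pair is retained when its original element has an exact TSD;
the stricter `pairs_motif` set (used for motif, palindrome and nucleosome
analyses) additionally requires a TSD on the nested element. "Non-nested"
means solitary: neither nested nor hosting. TSD calls are exact-match only
(longest of 6, 5, 4, in that order — preventing a 6-bp TSD reporting as
its 5-bp prefix); no mismatch tolerance is offered because duplications
are created perfect and decay only by later mutation. Superfamily is
called from domain-center order (integrase 3' of RH ⇒ gypsy, 5' of RT ⇒
copia); family is the best global-alignment RT identity against the panel
(edlib NW, identity = 1 − dist/max-length), threshold 60%, ties broken by
panel order. Curation output is independent of input ordering.

## Region-preference statistics

Each pair's insertion offset is assigned to the half-open region of its
original that contains it (a boundary base belongs to the downstream
region; annotation gaps fall back to the nearest boundary with a warning).
Expected counts are computed per original family as
`E_r = (L̄_r / L̄) · N_family` and summed per superfamily, so families with
different layouts (e.g. chromodomain presence) contribute their own
schemas. The global test is Pearson's goodness-of-fit chi-square with
`df = regions − 1` (expectations rescaled to the observed total); regions
with `E_r < 1` are pooled into their adjacent smaller neighbour first. The
per-region follow-up — the "pairwise comparison" — is a 1-df
region-vs-rest chi-square per region, Benjamini–Hochberg adjusted, flagged
at `p_adj < 0.05`. Under the null the global rejection rate is ~5% once
expected counts are comfortably above 1 (the test suite uses N = 2000; at
very small N the chi-square is conservative). The recent/old split uses
the LTR-identity delta Δ = identity(nested) − identity(original):
recent = 0 < Δ ≤ 1 point, old = Δ ≥ 5 points, intermediates excluded.
The superfamily enrichment test is a Pearson chi-square of independence on
the 2×2 nested/non-nested × gypsy/copia table, without continuity
correction by default.

## Dating

LTR identity is computed by Needleman–Wunsch global alignment with
stretcher-like DNA scoring (match +5, mismatch −4, gap open 16, gap extend
4); identity counts gap columns in the denominator. Divergence is the raw
p-distance; `T = d / (2μ·10⁶)` Mya. A Jukes–Cantor option exists but is
off by default — no correction is applied in the workflow this package
models, and the recent/old classification is insensitive to it below ~15%
divergence. Age-group comparison uses Welch's unequal-variance t-test
(zero-variance identical groups return p = 1 by convention). Calibration:
mean estimated age is within 10% of truth at 0.5–4 Mya (200 replicates per
age); the small negative bias at high ages comes from coincident and back
mutations, which the p-distance does not unwind.

## TSD motifs

Logo data are position frequency matrices over windows of the last 10
left-flank bases + TSD + first 10 right-flank bases (flanks taken outside
the duplicated copies; minus-strand records are reverse-complemented into
insertion orientation). Information content per column is
`2 + Σ_b p_b log₂ p_b` bits against a uniform background, Ns excluded per
column, no small-sample correction by default (a flag adds the standard
`3/(2 ln2 · n)` term). TSD-length spectra are reported both row-normalized
(per family) and column-normalized (per length). GC comparisons exclude Ns
and compare the element set against the entire final genome; note that
when elements make up a large fraction of a simulated genome the
difference is diluted accordingly.

## Palindromes

A palindrome hit is (left arm, loop ≥ 0, right arm) with the right arm
aligning to the reverse complement of the left arm within
`floor(stem · max_error_rate)` mismatches+indels; the stem (left-arm
length) is the score, sequences with no qualifying stem ≥ 3 score 2 so
paired comparisons stay defined. The detector fixes the arm and uses
infix/prefix edit-distance alignment for the partner; a hand-rolled
enumeration oracle verifies it exactly on random 20-bp windows. Each
native window is compared against one composition-preserving shuffle of
itself (a paired design; k-shuffle averaging available), with paired
t-tests per group and BH correction across family groups only.

Two conventions are exposed because the scorer being emulated is not fully
specified: the error budget (`1/3`, the package default, vs `0.30`) and
the loop bound (unconstrained by default). On random 20-bp windows at 40%
GC the mean maximal stem is ~6.9 under the defaults and ~5.5 under the
stricter published-table configuration (rate 0.30, loop ≤ 2 bp — TSD-like
short spacers); the acceptance script reports the latter because that is
the configuration whose published randomized baseline (≈5.4) it
reproduces. Conclusions about *relative* native-vs-shuffled enrichment are
stable across both settings.

## Nucleosome occupancy

Footprint starts are scored by
`E(i) = Σ_j w(seq[i+j..i+j+1], j)` with `w = +A·cos(2πj/P)` for WW
(AA/AT/TA/TT), `−A·cos(2πj/P)` for SS (CC/CG/GC/GG), 0 otherwise
(N-containing dinucleotides included as 0), `F = 147`, `P = 10.1`,
`A = 0.2`. Start probabilities are the Boltzmann softmax of `E`; occupancy
at a base is the summed probability of footprints covering it, so
`Σ p(i) = 1` and `O ∈ [0,1]` by construction, and `A = 0` reduces to the
closed-form trapezoid of uniform placement. This is an explicit stand-in
positioning model — its parameters are printed here rather than trained —
and it is isolated behind `occupancy_landscape` so a trained scorer can be
substituted. Profiles average per-base occupancy over 1124-bp windows
aligned on the insertion cut; for planted elements the window is the
reconstructed pre-insertion host sequence (element and one TSD copy
excised). Central-excess summaries compare ±75 bp around the cut against
the window interior, excluding one footprint at each edge where coverage
ramps down mechanically. Element-body profiles rescale each element's
landscape to 1000 bins before averaging. Occupancy (coverage) is reported
by default; raw start probabilities are available via a flag.

## Pipeline

`run_all` derives independent RNG streams per stage from one master seed
(adding a stage never perturbs earlier draws), sorts every table by stable
keys, and writes a manifest with a configuration hash and per-stage
attrition counts; reruns with the same configuration are byte-identical.
The default demonstration problem size — a 500-kb genome with 60 elements
— runs the full pipeline in well under a minute on one CPU; the simulation
sizes used in the test suite (300-kb genomes, 25–60 elements, 10–20
replicates for stochastic properties) were chosen as the smallest at which
the asymptotic statistics above are well behaved.
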