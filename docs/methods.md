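# Methods

This note documents the models implemented in `csbl`, the defaults they use,
what the synthetic-data generators do and do not emulate, and the design
choices made where the underlying protocol description left room.

## 1. Chemistry model (`csbl.chemistry`)

### Geometry and coordinates

A template strand is a 5′→3′ string with a `known_len`-base 5′ region
complementary to the full anchor primer, followed by the unknown tag.
Unknown positions are 1-based; position *p* is template index
`known_len + p`. The bench test template has `known_len = 19` and a 32-base
unknown region whose second position is an ambiguous N in the synthesized
oligo (instantiated to a concrete base, from the seeded RNG, at simulation
time; the decoder's truth accounting treats an N as matching any call).

Anchors are the reverse complement of template bases `1..known_len − offset`
with a 5′ phosphate at the junction; each unit of `offset` removes one base
from the junction end and shifts every scheduled read one position toward
the anchor.

### Cleavage register

Endonuclease V nicks "between the 2nd and 3rd phosphodiester bond" 3′ of a
deoxyinosine — phrasing that admits more than one register. We fix
`bond_index = 2` with the inosine-to-next-base bond counted as bond 1, i.e.
the cut falls between the 1st and 2nd nucleotides 3′ of the inosine. For the
9-mer pools (inosine 3rd from the 5′ end) this retains a 5-base, inosine-free
fragment. This is the *unique* register consistent with the protocol's
printed positions — the standard primer reading 5 at cycle 0 and 10 after
one cycle, and the 4 → 9 → 14 inosine-pool series — a uniqueness the test
suite verifies by brute force over registers 1–4. `bond_index` remains a
parameter for sensitivity analyses.

### Scheduler

`queried_position(offset, cycle, pool) = d − offset + r·cycle`, where *d* is
the query base's distance from the 3′ ligating end and *r* the retained
length of the cycling inosine pools (5 by default). The inosine-free
standard pool is not in the Table of pool geometries; it is modeled as a
9-mer with its query base 5th from the 3′ end — the unique placement that
reads position 5 at cycle 0 — and it rides on the anchor extensions produced
by the inosine cycles. Reads that would fall at positions < 1 probe the
anchor-complement region and are signalled (and dropped from schedule
enumeration). An independent oracle (explicit junction bookkeeping on the
template string, consuming `cleave()` output) confirms the closed form for
offsets 0–8 and cycles 0–5.

### Directionality

In the native 3′→5′ orientation the removed fragment carries the label *and*
the inosine away, so cycling is chemically unbounded (S/N-limited in
practice): `max_informative_cycles` returns infinity. In the 5′→3′
orientation the retained fragment keeps its inosine inside the extended
anchor; the first digestion after that inosine exists re-cleaves at it and
severs the newest extension. The simulation therefore completes exactly two
informative cycles for any single-inosine pool geometry. 5′→3′ mode is
scheduling-only — no signal simulation is attached to it, as no such
experiment exists to calibrate against.

### Sequence conventions

Deoxyinosine is encoded as lowercase `i` (IUPAC has no inosine code); it
pairs with every base in `ligation_compatible`, as do N on either strand.
Templates/primers are read and written as FASTA; schedules as JSON.

## 2. Signal model (`csbl.signal_synth`)

Each (bead, anchor offset, cycle, pool set) yields four channel means, then
`n_pixels = 100` integer pixels per channel ~ round(Normal(mean, pixel_sd))
clipped to the camera's 14-bit range [1, 16383].

Phase state is a per-population expectation model: `in_phase` strands sit at
the current junction; a strand fails to extend with probability
`1 − ligation_efficiency`; failed strands are rescued by the unlabeled
saturation pool with probability `saturation_rescue` (dark that cycle, in
phase the next) or else start *lagging* one junction behind, thereafter
emitting in the channel of the previous position. Emitted signal is
`base_signal · decay_per_cycle^cycle · in_phase · ligation_efficiency`,
passed through a row-stochastic 4×4 crosstalk matrix, plus additive
background. An optional specificity-loss term (`mismatch_slope`,
`mismatch_onset`) sends a bead's signal to a uniformly wrong channel with
probability growing in the query base's distance from the junction, for
reproducing the error ladders of non-cyclic single-ligation protocols.

Defaults (all configurable via JSON): `base_signal 8000`, `decay_per_cycle
0.75`, `ligation_efficiency 0.9`, `saturation_rescue 0.9`, crosstalk 0.94
diagonal / 0.02 bleed, `background 150`, `pixel_sd 120`, `mismatch_slope 0`.
They were chosen so the third cycle retains S/N well above the calling
threshold — mirroring a run in which non-specific signal grows per cycle but
the third cycle still calls cleanly — and so that S/N is non-increasing in
cycle (asserted by tests).

Because real instruments re-tune exposure and gain per cycle, absolute
intensities across cycles are not comparable; the simulator emits raw
intensities and the caller uses only within-image channel ratios.

What this generator does **not** emulate: optics (point-spread functions,
bead segmentation, registration), bead-to-bead brightness variation,
correlated pixel noise, fluorophore-specific spectra, and any mechanism for
the bench protocol's observed 14th-position limit (for which no cause was
established; our noise-free simulations read position 14). Passing tests
therefore demonstrate the *bookkeeping* and *decoding* logic, not
instrument-level fidelity.

## 3. Base calling (`csbl.basecall`)

Channel means are pixel averages. The call is the argmax channel's base
under the map Cy3→A, Cy5→T, FITC→C, TxRed→G; whether a pool letter denotes
the reported base or its complement is untestable from the protocol
description alone, so the map is a config parameter with this default. S/N
is brightest ÷ mean of the other three (the simplest symmetric reading of
"the brightest channel ... and the values of other channels"); `second_max`
is available as an alternative. No-calls: S/N below threshold (default 2.0,
a conservative documented choice) or a tied maximum — ties are never broken
arbitrarily. Duplicate reads of one position keep the higher-S/N call, with
a warning. Consensus is the across-bead majority (ties → gap). FASTQ
qualities are `min(40, round(10·log10(S/N + 1)))`.

## 4. Tag simulation (`csbl.tagsim`)

Defaults are the standard study conditions: tag lengths 13–20, start-to-start
separation uniform on [300, 700] nt ("separated by 300–700 bases" is read as
start-to-start; a gap-based reading would shift separations by one tag
length and is config-switchable), fair-coin strand, error-free tags, and
pair count `ceil(coverage · region_length / (2 · tag_length))` so total tag
bases equal the fold-coverage target (the unsequenced insert does not count
toward coverage). Tag windows containing N are rejected and resampled
(exact-match mapping downstream makes N-tolerance pointless). Both tags are
reported 5′→3′ on their source strand, forward–forward, with plus-strand
window starts as coordinates; the mapper enforces the same convention.
Whether the original simulation drew tag starts uniformly or
fragment-length-weighted is not stated; uniform is assumed.

**Nested mode** anchors minus-strand windows at a fixed right edge so that
the tag at length L+1 is the one-base 3′ extension of the tag at L from the
identical fragment, on either strand, with identical separations. Placement
sets then shrink monotonically in L and tag footprints grow monotonically —
the basis for the exact (non-statistical) monotonicity assertions
downstream.

`synth_genome` plants non-overlapping repeat families on an i.i.d.
GC-controlled background. Each family has one consensus; each copy receives
independent substitutions at a per-family `divergence` rate (0 = exact).
Divergence matters: with *exact* repeats and an *exact* mapper, a pair
trapped in a long repeat is ambiguous at every tag length and uniqueness
barely depends on L; real repeat families are diverged, and longer tags are
likelier to span a discriminating substitution — which is precisely the
mappability-versus-read-length effect the sweep measures.

## 5. Mapping (`csbl.pairmap`)

The index packs every N-free k-mer start (k = tag length, one index per
sweep point) into 2-bit-per-base uint64 keys in a sorted array — exact
hash-index retrieval with two binary searches per lookup (tag and reverse
complement) and vectorized batch queries. Sequences are concatenated with
k N spacers so no window spans two sequences; a reference digest guards
persisted indexes.

Pair placement requires same sequence, same strand, exact matches for both
tags, and separation in the insert range (applied during pairing; both the
orientation and insert checks are exposed as switches). **Uniqueness is
pair-level**: a pair is used iff its joint placement count is exactly 1.
"Tags that mapped to multiple locations were discarded" is ambiguous between
tag- and pair-level filtering; pair-level is chosen because coverage is
computed from mate-paired data and the joint insert constraint is what the
paired library buys you; a tag-level mode (each tag individually unique) is
available behind a flag. Batch mapping classifies pairs with all per-tag hit
counts ≤ 1 vectorized, and joins multi-hit pairs via per-hit binary searches
into the mate's coordinate-sorted hit list — O((c₁+c₂)·log) per pair rather
than the c₁×c₂ cross join. Correctness is pinned to a brute-force
sliding-window oracle on small genomes in the tests.

Coordinates are 0-based half-open internally; BED output follows the BED
convention (0-based, half-open).

## 6. Coverage and the sweep (`csbl.coverage`)

Unique pairs add +1 depth over both tag footprints via a difference-array
accumulation. Percent covered uses the non-N (assembly-resolved) bases as
denominator — ambiguous assembly bases can never be covered by exact
matching, which is why published chromosome-scale numbers plateau below
100% — and the mask is overridable. Depth conservation
(`Σ depth = 2·L·(unique pairs in region)`) is asserted exactly.

`sweep` runs, per tag length: pair count → sampling → index build → mapping
→ accumulation → summary, with per-replicate seeds spawned from the master
seed. In nested mode one fragment set (sized for the coverage target at the
shortest length) is shared across lengths: the per-length coverage target is
then exceeded at longer L, but the fraction-used and percent-covered curves
become exactly monotone rather than monotone in expectation, which is the
property the sweep exists to measure. Independent-resampling mode keeps the
per-length pair counts and is tested with a sign test over replicates.

### Scaled-down sweep conditions

The desk-scale experiment uses a seeded 2 Mb genome at GC 0.41 with ~28%
repeat mass: eighteen 20-copy families of 1.5 kb repeats at 5.5% per-copy
divergence (the mappability-limiting component — at L = 13 the expected
number of copies jointly matching both tags of a trapped pair is ≈ 1,
placing lengths 13–20 in the diminishing-returns regime), four near-identical
2-copy duplications, and 150 exact 100-mers. Tag lengths 13–20 at 10×
coverage (≈ 7.7 × 10⁵ pairs) complete in a few minutes on one CPU. Problem
sizes elsewhere (10 kb oracle genomes, ~10³-pair comparisons, ~10² random
templates) were chosen as the smallest that exercise every code path with
multiplicity.

The published-scale experiment — tags from human chromosome 1 mapped against
the genome, coverage 96% → 97.5% and tags used 57.2% → 85.6% across L =
13..20 — runs through the same `sweep` entry point given the assembly at
`data/human_chr1.fasta`, at a documented ±1.5-percentage-point tolerance
(stochastic and assembly-version-sensitive; the 2011 assembly in use was not
recorded). The repository ships no genome data, so that acceptance test
reports failure until the file is supplied.

## 7. Known limitations

* Exact matching only — no mismatches or indels; no sequencing-error model
  for tags (the simulated tags are error-free by design).
* The phasing model is a population-expectation model, minimal by intent;
  it reproduces the qualitative phenomena (decay, lagging signal, saturation
  rescue) but is not calibrated to any instrument.
* Whole-genome-scale mapping is best-effort: the index is built for
  chromosome-scale references; memory, not correctness, is the constraint.
* No thermodynamics (melting, secondary structure) or ligase kinetics.
* The 14th-position sequencing limit of the bench protocol has no known
  mechanism and is deliberately not modeled.
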