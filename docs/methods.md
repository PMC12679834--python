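# Methods

## Model and assumptions

pseudoscan treats gene loss as an alignment-observable property: an ortholog
is eroded to the extent that its reference exons, placed one by one in the
target genomic region, reveal lesions incompatible with protein coding. The
underlying assumptions are:

* **Orthology of the region.** Each target region is assumed to contain (at
  most) one orthologous copy of the gene. Paralogs or collapsed duplicates in
  the region can attract exons to the wrong locus; overlapping footprints of
  adjacent exons are therefore treated as a duplication signal and the
  lower-identity exon is demoted to absent (logged).
* **Exon-wise alignability.** Exons are placed independently, each against
  the full region; there is no spliced-alignment pass and no progressive
  narrowing of the search window. This keeps each exon's evidence
  independent, at the cost of ignoring colinearity (deviations from exon
  order along the region are logged, not enforced).
* **Canonical splicing.** Donor `GT` (optionally `GC`) and acceptor `AG` are
  the only viable splice signals. Non-canonical but functional sites will be
  reported as splice losses.
* **Single reading frame.** No programmed frameshifts, trans-splicing, or
  selenocysteine recoding; CDS features only.

## Alignment engine

Gotoh three-state affine dynamic programming, semi-global ("fit") policy:
terminal gaps in the exon row — region overhangs — are free; the exon must
align end to end. Gap-state-to-gap-state transitions are allowed in both
directions, which makes scores invariant under joint reverse-complement of
both sequences. A gap of length $L$ costs `gap_open` $+ L\cdot$`gap_extend`.
Ties are broken by a fixed operation order (diagonal > up > left, i.e.
match state over region-row gap over exon-row gap), and the final cell is
the smallest footprint end among co-optimal ends, so every alignment is
bitwise reproducible. `N` never matches anything (scored as mismatch), and
lowercase (soft-masked) input is uppercased with a notice.

Identity is computed over the footprint columns only — the region span
between the first and last aligned exon base — counting internal gap columns
in the denominator, so indels depress identity. A self-alignment is exactly
100.0 under any scheme.

Schemes must satisfy `mismatch > gap_open + gap_extend`; otherwise single
substitutions would be represented as gap pairs and anchoring would break.
The kernel is JIT-compiled (numba); an independent pure-Python DP mirror in
the test suite checks score, identity, footprint and alignment strings
exactly on randomized small instances.

## Scoring battery and selection

Defaults: match/mismatch in {(1,−1), (1,−2), (1,−3), (2,−1), (2,−3), (4,−1)},
gap open −20, gap extend −1 (the EMBOSS-style 10/0.5 pair doubled to stay
integral). The battery spans permissive-to-strict mismatch ratios: permissive
schemes keep eroded exons alignable; strict schemes keep footprints crisp
when the exon is intact. All schemes are configurable (`align.schemes`).

Selection is a two-key lexicographic sort: count of satisfied splice flags
(gene-terminal sides vacuously satisfied, so terminal exons are not
penalized), then identity, then raw score, then earliest footprint start.
Splice viability dominating identity reflects the biology: a placement whose
boundaries sit on intact splice signals is more credible than a slightly
better-matching placement that destroys them.

Both strands of each region are tried; the strand with the greater summed
identity of placed exons is kept for all exons, since mixed-strand placements
are almost always artifacts.

## Absence calls and the identity floor

An exon is absent when its best placement falls below `exon.min_identity`
(default **65%**). The floor is calibrated against the spurious-fit null:
fitting an unrelated ~100 nt sequence into a ~1 kb region, the battery's most
permissive scheme reaches 45–55% identity by chance (short gaps are cheap
relative to the match reward, letting the DP re-phase through random
sequence), while genuinely present exons — even carrying frameshifts or ~5%
divergence — align at ≥80–90%. A floor inside the null band would make
absence calls coin-flips; 65% clears the null with margin and stays far
below real placements. The corollary (a limitation, not a feature): an exon
genuinely present but eroded below ~65% identity is indistinguishable from
absent by this test, and deep-divergence screens should lower the floor and
interpret absence calls cautiously.

## Mutation calling

* **Indels.** Gap runs in the selected alignment; runs with length not
  divisible by 3 are frameshifts, in-frame runs are recorded in the
  per-target JSON but are never events. Anchors are left-normalized against
  the reference exon (VCF-style), so co-optimal gap placements inside repeats
  map to a single CDS coordinate — without this, cross-species sharing of
  "the same" frameshift would depend on traceback luck.
* **Premature stops.** The target coding stream is the concatenation of
  ungapped footprints of placed exons in exon order. Translation starts at
  the first placed exon's phase; inserted bases enter the stream and deleted
  bases leave it, so the reading frame shifts exactly as a ribosome's would.
  Codons overlapping alignment gaps or absent-exon junctions are skipped
  rather than imputed (avoids stop calls from alignment artifacts). Every
  clean stop upstream of the reference terminal stop is reported — including
  stops created downstream of a frameshift (dual reporting; erosion anchors
  on the first lesion, so nothing is double-counted). Stops within
  max(5% of the CDS, 30 nt) of the terminal stop are recorded but flagged
  non-disruptive: slightly early termination is commonly tolerated.
* **Splice losses.** Non-canonical dinucleotides at internal boundaries of
  placed exons, anchored at the exon's CDS edge.
* **Start loss.** A complete non-ATG triplet aligned to CDS 0–2 when exon 0
  is placed. Flagged non-disruptive by default
  (`caller.start_loss_disruptive`): a downstream in-frame ATG often rescues
  translation, so a changed start is weaker evidence than a mid-CDS stop.

## Disrupted fraction and PseudoIndex

$D$ = |union of: positions ≥ first disruptive frame-breaking event
(frameshifts, splice losses); positions ≥ first disruptive premature stop;
positions of absent exons| / CDS length. The union form avoids double
counting and anchors on the earliest lesion, consistent with reading-frame
biology. A disruptive start loss (non-default) disrupts the whole CDS.
Binning: index 0 iff no disruptive event; otherwise
$(0,.05]\to1, (.05,.2]\to2, (.2,.5]\to3, (.5,.85]\to4, (.85,1]\to5$. The
bin edges are explicit configuration (`pseudoindex.bins`); treat them as a
reporting convention, not an inference.

## Tree projection

Leaf = its target's PseudoIndex and mutation-key set (kind, exon, CDS
position); internal node = max of children's indices, intersection of
children's shared sets; unmatched leaves are excluded from both. These are
presentation semantics — a way to read erosion along a tree — not
ancestral-state reconstruction. Mutation identity is exact by default;
`tree.pos_tolerance` allows ±k nt slack for assembly noise (the tolerant
intersection is seeded from the first child's keys and is therefore not
symmetric in the keys it reports, only in whether a lesion is deemed
shared). Trees with a basal polytomy are midpoint-rooted when branch lengths
are present; otherwise the polytomy root is kept (max/intersection remain
well defined).

## Synthetic data

The generator emulates exactly the structure the pipeline reasons about:
random multi-exon genes with ATG start, single terminal stop, no internal
in-frame stop, canonical `GT..AG` introns, uniform-composition flanks; and
per-target regions carrying single injected lesions with exact expected
calls. Defaults for the standard battery: 3 exons of 90–150 nt, introns of
80–150 nt, 120 nt flanks — small enough that the whole recovery suite runs
in tens of seconds, large enough that every exon anchors uniquely. Indel
lesions are placed ≥6 nt from exon edges and stop substitutions in the
25–60% codon band; neutral substitutions are constrained never to create an
in-frame stop or touch start/stop/splice signals, so a "clean" target is
clean by construction. Randomness is keyed per (seed, target, lesion
ordinal): adding a target never changes another target's bytes.

What the generator does **not** emulate — and hence what passing recovery
tests do not show: real intron/exon composition bias, repeats and
low-complexity tracts (beyond what uniform random sequence produces),
assembly gaps and sequencing-error indel profiles, paralogy, and genuine
evolutionary divergence patterns. Results on real genomes depend on the
target region actually being orthologous and reasonably assembled.

### Known failure mode

An indel injected close to an exon edge can be absorbed by shifting the
footprint instead of opening a gap (a handful of chance matches outweigh the
gap penalty under every scheme); the call then surfaces as a splice loss at
the shifted boundary rather than a frameshift. Measured rate under the
standard conditions: ~1–2% of edge-proximal insertions. This is an
information limit of per-exon alignment, not a bookkeeping error — the
lesion is still detected, with a different label.

## Determinism and parallelism

The unit of concurrency is one target region. Results are gathered and
written in input order, the config echoed into outputs excludes execution
knobs (worker count, log level), and no output contains timestamps, so
output bytes are identical for any `--jobs` value and across reruns.
Per-target failures (oversized region, non-nucleotide characters) are soft
skips recorded in the run manifest; only configuration and reference errors
abort a run.

## Problem sizes used in checks

Recovery: 100 random genes × 8 targets (one clean + 7 single-lesion).
Aligner-vs-oracle: 500 random pairs (exon ≤40 nt, region ≤120 nt) × 6
schemes, exact equality. PseudoIndex algebra: hand-computed fractions to
1e-12 plus 1000-draw monotonicity. Tree semantics: 100 random trees against
a direct max/intersection oracle. Determinism: a 20-target run at 1 vs 4
workers plus an independent regeneration, compared byte for byte.
`scripts/acceptance.py` re-runs the recovery and tree checks at 60 genes /
50 trees and prints every number it writes.
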