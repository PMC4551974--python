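# Methods

## Motif model

Composite OCT4–SOX2 elements are modelled as exact degenerate words: an
IUPAC pattern compiled to per-position allowed-base subsets of
{A, C, G, T}.  A window matches at an offset iff every position of the
window lies inside the corresponding subset — no mismatches, no
position-weight scoring, no thresholds.  This is deliberately the
simplest matching semantics consistent with a "word search" and makes
every count exactly reproducible.

Matching conventions:

* **Strands.** Both strands are scanned by default.  Composite elements
  are functional in either orientation, and the original word search does
  not document strandedness, so double-strand scanning is the default and
  a forward-only mode is kept for sensitivity analysis.  A minus-strand
  hit at offset *k* means the reverse complement of the window
  subsequence at *k* matches; the reported `matched_seq` is always the
  forward-strand subsequence.
* **Overlaps.** All overlapping occurrences are reported; deduplication
  is by (peak, motif, offset, strand).
* **Ambiguity in subjects.** A window position holding a non-ACGT base
  can never match (conservative), rather than raising.  Subject input is
  case-insensitive and normalised to upper case.
* **Class disjointness.** Two equal-length patterns are provably
  disjoint iff some position has an empty intersection of allowed sets.
  The Hoxb1-like and Utf1-like words are disjoint at position 14
  ({A,T} vs {G}), so the two classes can never double-count a sequence;
  this is asserted in tests rather than filtered at run time.

The analytic null used for calibration is the i.i.d. background: the
per-offset, per-strand match probability is the product over positions of
the summed probabilities of allowed bases.  For the Hoxb1-like word under
a uniform background this is 6912/4^15 ≈ 6.44×10⁻⁶.

The scanner's fast path encodes sequences as base indices and tests all
offsets against the motif's boolean allowed matrix with a sliding-window
view; tests check it against an independent brute-force position-by-
position oracle.

## Peak windows and background

Peaks follow the BED convention (0-based, half-open) and carry an
absolute summit position (a midpoint fallback exists for summit-less
peak tables).  Each peak contributes one window of `width` bp (default
100, the scale on which composite elements concentrate around summits)
centred on the summit: `[summit − width/2, summit + width/2)`.  Windows
that would cross a chromosome boundary are **skipped with a warning**,
not truncated, so all windows have identical length — required for the
positional histograms.  Both the total occurrence count and the number of
motif-positive windows are reported per class; on windows this narrow the
two rarely differ, and the headline count is total occurrences.

Positional distributions histogram the hit-centre position
(`offset + L//2 − width/2`) relative to the summit in 5-nt bins (binning
is a presentation choice; any divisor of the width is accepted).

Background windows are a seeded sample, uniform over the genome with
chromosomes weighted by length, rejected when they overlap any peak
window, contain a non-ACGT base, or differ from the pooled peak-window GC
fraction by more than `gc_tolerance` (default 0.02).  This is a
re-implementation of the usual GC/length-matched control selection; the
original analysis used an external tool whose exact parameters are
undocumented, so matched sampling is the package's own approximation and
a `gc_tolerance` of 1.0 degrades to plain uniform sampling.

## Peak-to-gene linking and fold-change classes

A peak is assigned to every gene whose TSS lies within `max_distance` of
its summit (default 50 kb, boundary-inclusive, absolute distance, gene
strand ignored), and a gene aggregates all its peaks — one-to-many in
both directions, the least lossy reading.  Peak confidence is a pluggable
predicate defaulting to pass-all, since the upstream "high-confidence"
criterion lives in the peak set itself, not here.  A gene enters the gene
set of every motif class carried by at least one of its assigned peaks;
classes are not mutually exclusive.

Expression is consumed as a normalised **linear-scale** matrix.  Per
condition, the per-gene mean is arithmetic on the linear scale; each mean
is then raised to the background floor (default 5) if below it, and the
ratio of floored means is classed `up` (≥ threshold, default 2),
`down` (≤ 1/threshold) or `unchanged`.  Flooring precedes both the ratio
and the log2 values so that noise below the detection floor can never
manufacture a fold change.  No significance test is applied — the
classification is purely fold-change based, matching the analysis this
package reproduces.

## Synthetic data

The generator emulates the study conditions end to end:

* **Genome** — i.i.d. bases with configurable GC (default 0.5), length
  derived from the peak layout plus a 120-kb peak-free tail.
* **Peaks** — `n_peaks` (default 3,798) non-overlapping 100-bp summit
  windows spaced 100 bp apart; planting counts default to 554/47/26
  Hoxb1/Utf1/Fgf4-like to mirror the full-scale analysis.  Each planted
  window receives one concrete expansion of its class pattern, sampled
  uniformly per position, at a uniform in-window offset and strand.  In
  **strict** mode the genome is first rejection-sampled free of chance
  occurrences and every planted window is re-sampled until scanning it
  (plus a motif-length flank) finds exactly the planted hit — scan counts
  then equal planting counts exactly.  Non-strict mode leaves chance
  occurrences at the analytic i.i.d. rate, which the calibration tests
  verify.
* **TSS table** — a `link_fraction` of genes is placed within 50 kb of a
  motif-bearing summit, the rest in the peak-free tail (hence provably
  unlinked).
* **Expression** — baselines log-uniform in [2⁵, 2¹⁰] (well above the
  floor), planted fold effects drawn from [2.5, 6] (direction random) in
  one non-reference condition for a configured fraction of linked genes,
  multiplicative log-normal noise (σ in natural-log units, default 0.1)
  per sample, replicate counts defaulting to 2/2/3
  (reference/mutant/mutant).  The effect floor of 2.5 keeps planted
  effects strictly away from the 2-fold decision boundary so that
  recovery measures the pipeline, not coin flips at the threshold.

Everything is driven by one `GeneratorConfig` and a single integer seed;
identical configs give byte-identical FASTA/TSV outputs.

What the generator does **not** emulate: ChIP-seq read noise and
peak-caller artefacts, realistic chromatin context or repeat structure,
inter-gene correlation, array saturation, or genes regulated by distal
elements beyond 50 kb.  Passing tests on synthetic data therefore
demonstrate correctness of the computation, not biological completeness
of the 50-kb/2-fold analysis choices.

## Problem sizes and numerical choices

The test suite exercises the scanner at the full 3,798-window scale
(seconds) and uses 15,000 motif-free windows (≥10⁶ scanned offsets per
class) for chance-hit calibration, with agreement required within 3
binomial standard errors.  Fold-change recovery uses 200 genes with 40
planted effects at σ = 0.1 and 3 replicates per condition.  Rejection
sampling budgets (200 attempts per planted window, 50 genome scrub
passes) fail loudly rather than degrade silently.  Ties at the fold
threshold are classified as changed (`ratio ≥ threshold` is `up`),
making the boundary behaviour explicit and symmetric.

## Known limitations

* Background selection approximates, but cannot reproduce, the original
  tool-specific control set; background-dependent numbers are therefore
  comparable in kind, not in byte.
* Whether the original headline counts are total occurrences or
  motif-positive windows is not documented; both are always emitted.
* Reproducing the original genome-scale counts requires the original
  peak coordinates, which are not redistributed here; the package ships
  the machinery plus full-scale synthetic validation instead.
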